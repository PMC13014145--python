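"""UMAP embedding, Leiden community detection and cluster composition.

Both run on PCA scores (standard single-cell practice): Leiden on a
k-nearest-neighbour graph built with Euclidean distances in PC space, UMAP
on the top principal components for visualization only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # contiguous ints 0..C-1, one per cell
    resolution: float
    k_neighbors: int
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def umap_embed(scores: np.ndarray, n_neighbors: int = 15,
               min_dist: float = 0.1, seed: int = 0) -> np.ndarray:
    """2-D UMAP of PC scores; deterministic for a fixed seed."""
    import umap  # deferred: slow import

    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] < 2:
        raise ValueError("need at least two components to embed")
    if scores.shape[0] <= n_neighbors:
        raise ValueError(
            f"{scores.shape[0]} cells <= n_neighbors={n_neighbors}")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    coords = reducer.fit_transform(scores)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("UMAP produced non-finite coordinates")
    return coords


def _knn_graph(scores: np.ndarray, k: int) -> ig.Graph:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=scores.shape[0], edges=sorted(edges), directed=False)
    return g


def leiden_cluster(scores: np.ndarray, k_neighbors: int = 15,
                   resolution: float = 0.5, seed: int = 0
                   ) -> ClusterAssignment:
    """Leiden communities of the kNN graph in PC space (RB modularity)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n <= k_neighbors:
        raise ValueError(f"{n} cells <= k_neighbors={k_neighbors}")
    g = _knn_graph(scores, k_neighbors)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    labels = np.asarray(part.membership, dtype=int)
    # relabel contiguously by decreasing cluster size, deterministic
    order = pd.Series(labels).value_counts(sort=True).index.to_numpy()
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in labels])
    if labels.max() == 0:
        warnings.warn("Leiden found a single cluster")
    return ClusterAssignment(labels, resolution, k_neighbors, seed)


def cluster_composition(assignment: ClusterAssignment, metadata,
                        drugs=None) -> pd.DataFrame:
    """Per (cluster, drug) proportions of resistant/sensitive/unknown cells."""
    drugs = list(drugs if drugs is not None else metadata.drugs)
    if not drugs:
        raise ValueError("no drugs with labels available")
    rows = []
    table = metadata.table
    for c in range(assignment.n_clusters):
        members = assignment.labels == c
        sub = table.iloc[np.flatnonzero(members)]
        for drug in drugs:
            lab = (sub[drug] if drug in table.columns
                   else pd.Series("unknown", index=sub.index))
            n = len(sub)
            rows.append({
                "cluster": c, "drug": drug, "n": n,
                "p_resistant": float((lab == "resistant").mean()),
                "p_sensitive": float((lab == "sensitive").mean()),
                "p_unknown": float((lab == "unknown").mean()),
            })
    return pd.DataFrame(rows)
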