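"""Reading, validating and writing single-cell Raman spectra and cohort metadata.

Spectra travel as a :class:`SpectraMatrix` (cells x wavenumbers on a common,
strictly increasing grid); per-cell annotations travel as a
:class:`CohortMetadata` (sample of origin, passage, treatment, and one
resistance label per drug). Files are plain text: comma-separated spectra
with a ``cell_id`` column followed by wavenumber columns, and tab-separated
metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Bounds of the biological fingerprint window (cm^-1).
FINGERPRINT_LO = 600.0
FINGERPRINT_HI = 1800.0

RESISTANCE_LEVELS = ("resistant", "sensitive", "unknown")

METADATA_BASE_COLUMNS = ("cell_id", "sample_id", "passage", "treatment")


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavenumber grid needs at least two points")
        if not np.all(np.isfinite(vals)):
            raise ValueError("wavenumber grid contains non-finite values")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @classmethod
    def regular(cls, lo: float = FINGERPRINT_LO, hi: float = FINGERPRINT_HI,
                step: float = 1.0) -> "WavenumberGrid":
        """Inclusive regular grid from ``lo`` to ``hi`` with spacing ``step``."""
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    @property
    def step(self) -> float:
        """Nominal (median) spacing."""
        return float(np.median(np.diff(self.values)))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values)


@dataclass
class SpectraMatrix:
    """Cells x wavenumbers intensity matrix with unique cell identifiers."""

    cell_ids: np.ndarray
    grid: WavenumberGrid
    intensities: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.cell_ids, dtype=object)
        X = np.asarray(self.intensities, dtype=float)
        if X.ndim != 2:
            raise ValueError("intensities must be 2-D (cells x wavenumbers)")
        if X.shape[0] != ids.size:
            raise ValueError(
                f"{ids.size} cell ids but {X.shape[0]} intensity rows")
        if X.shape[1] != len(self.grid):
            raise ValueError(
                f"{len(self.grid)} grid points but {X.shape[1]} intensity "
                "columns")
        if ids.size != np.unique(ids).size:
            dupes = pd.Series(ids).value_counts()
            dupes = dupes[dupes > 1].index.tolist()
            raise ValueError(f"duplicate cell ids: {dupes[:5]}")
        bad = ~np.isfinite(X)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite intensity for cell {ids[i]!r} at "
                f"{self.grid.values[j]:g} cm^-1")
        self.cell_ids = ids
        self.intensities = X

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    def select(self, index) -> "SpectraMatrix":
        """Row subset (boolean mask or integer indices)."""
        return SpectraMatrix(self.cell_ids[index], self.grid,
                             self.intensities[index])

    def with_intensities(self, X: np.ndarray,
                         grid: WavenumberGrid | None = None) -> "SpectraMatrix":
        return SpectraMatrix(self.cell_ids, grid or self.grid, X)


@dataclass
class CohortMetadata:
    """Per-cell annotations aligned to a spectra matrix.

    ``table`` is indexed by cell id and carries ``sample_id``, ``passage``,
    ``treatment`` plus one column per drug holding labels from
    ``{resistant, sensitive, unknown}``.
    """

    table: pd.DataFrame
    drugs: tuple = field(default_factory=tuple)

    def __post_init__(self):
        for drug in self.drugs:
            bad = ~self.table[drug].isin(RESISTANCE_LEVELS)
            if bad.any():
                raise ValueError(
                    f"invalid resistance label(s) for drug {drug!r}: "
                    f"{sorted(self.table.loc[bad, drug].unique())}")
            conflicts = (
                self.table.groupby("sample_id")[drug].nunique(dropna=False))
            conflicts = conflicts[conflicts > 1]
            if len(conflicts):
                raise ValueError(
                    f"conflicting {drug!r} labels within sample(s) "
                    f"{conflicts.index.tolist()}")

    def labels_for(self, drug: str) -> pd.Series:
        """Per-cell resistance label for one drug ('unknown' if absent)."""
        if drug not in self.drugs:
            return pd.Series("unknown", index=self.table.index)
        return self.table[drug]

    def sample_label(self, sample_id: str, drug: str) -> str:
        sub = self.table[self.table["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return sub[drug].iloc[0] if drug in self.drugs else "unknown"

    @property
    def samples(self) -> list:
        return sorted(self.table["sample_id"].unique().tolist())

    def loc(self, cell_ids) -> pd.DataFrame:
        return self.table.loc[np.asarray(cell_ids, dtype=object)]


def read_spectra(path, expected_grid: WavenumberGrid | None = None
                 ) -> SpectraMatrix:
    """Read a spectra CSV (header: cell_id, then wavenumbers).

    If ``expected_grid`` differs from the file's grid, spectra are linearly
    interpolated onto it; extrapolation outside the file's range is refused.
    """
    df = pd.read_csv(path, index_col=0)
    try:
        grid = WavenumberGrid(np.array([float(c) for c in df.columns]))
    except ValueError as exc:
        raise ValueError(f"{path}: bad wavenumber header ({exc})") from exc
    ids = df.index.astype(str).to_numpy(dtype=object)
    if ids.size != np.unique(ids).size:
        raise ValueError(f"{path}: duplicate cell ids")
    X = df.to_numpy(dtype=float)
    bad = ~np.isfinite(X)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric/non-finite value for cell {ids[i]!r} "
            f"at column {df.columns[j]}")
    spectra = SpectraMatrix(ids, grid, X)
    if expected_grid is not None and expected_grid != grid:
        spectra = interpolate_to_grid(spectra, expected_grid)
    return spectra


def interpolate_to_grid(spectra: SpectraMatrix,
                        grid: WavenumberGrid) -> SpectraMatrix:
    """Linear interpolation onto ``grid``; extrapolation is an error."""
    src = spectra.grid
    if grid.lo < src.lo or grid.hi > src.hi:
        raise ValueError(
            f"requested grid [{grid.lo:g}, {grid.hi:g}] extends outside the "
            f"data range [{src.lo:g}, {src.hi:g}]; extrapolation refused")
    X = np.empty((spectra.n_cells, len(grid)))
    for i in range(spectra.n_cells):
        X[i] = np.interp(grid.values, src.values, spectra.intensities[i])
    return SpectraMatrix(spectra.cell_ids, grid, X)


def read_metadata(path, spectra: SpectraMatrix,
                  drugs: list | None = None) -> CohortMetadata:
    """Read a metadata TSV and align it to ``spectra``.

    Columns beyond cell_id/sample_id/passage/treatment are treated as per-drug
    resistance labels unless ``drugs`` names them explicitly. Drugs in
    ``drugs`` without a column are filled with 'unknown'.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    missing = [c for c in ("cell_id", "sample_id") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df.set_index("cell_id")
    absent = set(map(str, spectra.cell_ids)) - set(df.index)
    if absent:
        raise ValueError(
            f"{path}: {len(absent)} spectra cells missing from metadata, "
            f"e.g. {sorted(absent)[:5]}")
    df = df.reindex(np.asarray(spectra.cell_ids, dtype=object))
    if "passage" not in df.columns:
        df["passage"] = pd.NA
    if "treatment" not in df.columns:
        df["treatment"] = "untreated"
    label_cols = [c for c in df.columns if c not in
                  ("sample_id", "passage", "treatment")]
    if drugs is None:
        drugs = label_cols
    for drug in drugs:
        if drug not in df.columns:
            df[drug] = "unknown"
        df[drug] = df[drug].fillna("unknown")
    return CohortMetadata(df, tuple(drugs))


def write_spectra(spectra: SpectraMatrix, metadata: CohortMetadata | None,
                  out_dir) -> dict:
    """Write spectra (CSV) and metadata (TSV) under ``out_dir``.

    Intensities are written with 12 significant digits so a read round-trip
    reproduces them to well under 1e-9 relative error.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {"spectra": os.path.join(out_dir, "spectra.csv")}
    cols = [f"{w:.10g}" for w in spectra.grid.values]
    df = pd.DataFrame(spectra.intensities, index=spectra.cell_ids,
                      columns=cols)
    df.index.name = "cell_id"
    df.to_csv(paths["spectra"], float_format="%.12g")
    if metadata is not None:
        paths["metadata"] = os.path.join(out_dir, "metadata.tsv")
        out = metadata.table.copy()
        out.index.name = "cell_id"
        out.to_csv(paths["metadata"], sep="\t")
    return paths
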