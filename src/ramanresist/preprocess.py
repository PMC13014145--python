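"""Spectral preprocessing: crop, despike, baseline correction, normalization,
and variance-targeted PCA.

The canonical pipeline order is crop -> despike -> baseline -> normalize ->
PCA. All per-spectrum steps are stateless row operations, so they can be
applied to a full cohort without information leaking between train and test
splits; only the PCA transform is fitted, and supervised evaluations fit it
per training fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .spectra_io import (FINGERPRINT_HI, FINGERPRINT_LO, SpectraMatrix,
                         WavenumberGrid)


def crop_fingerprint(spectra: SpectraMatrix, lo: float = FINGERPRINT_LO,
                     hi: float = FINGERPRINT_HI) -> SpectraMatrix:
    """Retain wavenumbers with lo <= w <= hi (inclusive, order preserved)."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    mask = (spectra.grid.values >= lo) & (spectra.grid.values <= hi)
    if not mask.any():
        raise ValueError(
            f"window [{lo:g}, {hi:g}] does not overlap grid "
            f"[{spectra.grid.lo:g}, {spectra.grid.hi:g}]")
    return spectra.with_intensities(spectra.intensities[:, mask],
                                    WavenumberGrid(spectra.grid.values[mask]))


def despike(X: np.ndarray, window: int = 5, mad_factor: float = 8.0
            ) -> np.ndarray:
    """Replace isolated cosmic-ray spikes by a local median.

    A point is a spike when it exceeds the local running median by more than
    ``mad_factor`` times the local median absolute deviation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    med = median_filter(X, size=(1, window), mode="nearest")
    mad = median_filter(np.abs(X - med), size=(1, window), mode="nearest")
    floor = 1e-3 * np.abs(X).max(axis=1, keepdims=True) + 1e-12
    spikes = (X - med) > mad_factor * np.maximum(mad, floor)
    out = X.copy()
    out[spikes] = med[spikes]
    return out


def _als_banded(n: int, lam: float) -> np.ndarray:
    """Upper banded form of lam * D2'D2 for a length-n second-difference D2."""
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    A = (lam * (D.T @ D)).todia()
    ab = np.zeros((3, n))
    for off in (0, 1, 2):
        diag = A.diagonal(off)
        ab[2 - off, off:] = diag
    return ab


def asls_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                  n_iter: int = 10) -> np.ndarray:
    """Asymmetric least-squares baseline estimate for one spectrum.

    Iteratively reweighted smooth fit: points above the current baseline
    (peaks) get weight ``p``, points below get ``1 - p``; smoothness is a
    second-difference penalty of strength ``lam``.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input to baseline correction")
    n = y.size
    ab_pen = _als_banded(n, lam)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        ab = ab_pen.copy()
        ab[2] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_correct(spectra: SpectraMatrix, lam: float = 1e5,
                     p: float = 0.01, n_iter: int = 10,
                     despike_first: bool = True) -> SpectraMatrix:
    """Subtract an asymmetric-least-squares baseline from every spectrum."""
    X = spectra.intensities
    if despike_first:
        X = despike(X)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        out[i] = X[i] - asls_baseline(X[i], lam=lam, p=p, n_iter=n_iter)
    return spectra.with_intensities(out)


def normalize(spectra: SpectraMatrix, method: str = "l2") -> SpectraMatrix:
    """Row-wise normalization: unit Euclidean norm or unit area."""
    X = spectra.intensities
    if method == "l2":
        denom = np.linalg.norm(X, axis=1)
    elif method == "area":
        denom = np.clip(X, 0.0, None).sum(axis=1)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    zero = denom == 0
    if zero.any():
        raise ValueError(
            f"cannot normalize all-zero spectra: "
            f"{spectra.cell_ids[zero][:5].tolist()}")
    if method == "area":
        X = np.clip(X, 0.0, None)
    return spectra.with_intensities(X / denom[:, None])


class VarianceTargetPCA(TransformerMixin, BaseEstimator):
    """PCA keeping the smallest number of components reaching a cumulative
    explained-variance target (optionally capped).

    Parameters
    ----------
    variance_target : float in (0, 1], default 0.95
        Smallest k with cumulative explained variance >= target is kept.
    max_components : int or None
        Hard cap on the number of retained components.

    Attributes
    ----------
    components_ : (k, n_features) orthonormal loadings.
    mean_ : (n_features,) training mean removed before projection.
    explained_variance_ratio_ : (k,) per-component variance fractions.
    n_components_ : int
    """

    def __init__(self, variance_target: float = 0.95,
                 max_components: int | None = None):
        self.variance_target = variance_target
        self.max_components = max_components

    def fit(self, X, y=None):
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PCA needs at least two spectra")
        full = PCA(n_components=None, svd_solver="covariance_eigh")
        full.fit(X)
        ratios = full.explained_variance_ratio_
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, self.variance_target - 1e-12) + 1)
        k = min(k, ratios.size)
        if self.max_components is not None:
            k = min(k, int(self.max_components))
        self.components_ = full.components_[:k]
        self.mean_ = full.mean_
        self.explained_variance_ratio_ = ratios[:k]
        self.explained_variance_ = full.explained_variance_[:k]
        self.n_components_ = k
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"grid mismatch: transform fitted on {self.n_features_in_} "
                f"wavenumbers, got {X.shape[1]}")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        check_is_fitted(self, "components_")
        return np.asarray(scores) @ self.components_ + self.mean_


@dataclass
class ReducedSpectra:
    """PCA scores together with the fitted transform."""

    scores: np.ndarray
    transform: VarianceTargetPCA
    grid: WavenumberGrid
    fitted_on: str = ""

    @property
    def loadings(self) -> np.ndarray:
        return self.transform.components_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.transform.explained_variance_ratio_

    @property
    def n_components(self) -> int:
        return self.transform.n_components_


def pca_fit(spectra: SpectraMatrix, variance_target: float = 0.95,
            max_components: int | None = None,
            fitted_on: str = "") -> ReducedSpectra:
    """Fit variance-targeted PCA on (preprocessed) spectra."""
    pca = VarianceTargetPCA(variance_target, max_components)
    scores = pca.fit(spectra.intensities).transform(spectra.intensities)
    return ReducedSpectra(scores, pca, spectra.grid, fitted_on)


def pca_transform(reduced: ReducedSpectra,
                  spectra: SpectraMatrix) -> np.ndarray:
    """Project new spectra through a fitted transform (grid must match)."""
    if spectra.grid != reduced.grid:
        raise ValueError("spectra grid does not match the fitted transform")
    return reduced.transform.transform(spectra.intensities)


class RamanPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless-per-row preprocessing as a sklearn transformer.

    Operates on raw intensity arrays whose columns are ``grid``; crops to the
    fingerprint window, removes spikes, subtracts an asymmetric least-squares
    baseline and normalizes each row. ``fit`` only records the cropped output
    grid; no statistics cross rows, so the same fitted object is leak-free on
    any split.
    """

    def __init__(self, grid: WavenumberGrid | None = None,
                 crop_lo: float = FINGERPRINT_LO,
                 crop_hi: float = FINGERPRINT_HI,
                 lam: float = 1e5, p: float = 0.01, n_iter: int = 10,
                 despike_spectra: bool = True, norm: str = "l2"):
        self.grid = grid
        self.crop_lo = crop_lo
        self.crop_hi = crop_hi
        self.lam = lam
        self.p = p
        self.n_iter = n_iter
        self.despike_spectra = despike_spectra
        self.norm = norm

    def fit(self, X, y=None):
        grid = self.grid or WavenumberGrid.regular()
        mask = (grid.values >= self.crop_lo) & (grid.values <= self.crop_hi)
        if not mask.any():
            raise ValueError("crop window does not overlap the grid")
        self.mask_ = mask
        self.out_grid_ = WavenumberGrid(grid.values[mask])
        self.n_features_in_ = len(grid)
        return self

    def transform(self, X):
        check_is_fitted(self, "mask_")
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self.mask_]
        if self.despike_spectra:
            X = despike(X)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = X[i] - asls_baseline(X[i], self.lam, self.p, self.n_iter)
        if self.norm is not None and self.norm != "none":
            norms = (np.linalg.norm(out, axis=1) if self.norm == "l2"
                     else np.clip(out, 0, None).sum(axis=1))
            out = out / np.where(norms == 0, 1.0, norms)[:, None]
        return out


def preprocess_spectra(spectra: SpectraMatrix, lo=FINGERPRINT_LO,
                       hi=FINGERPRINT_HI, lam=1e5, p=0.01, n_iter=10,
                       norm="l2") -> SpectraMatrix:
    """crop -> despike -> baseline -> normalize on a SpectraMatrix."""
    out = crop_fingerprint(spectra, lo, hi)
    out = baseline_correct(out, lam=lam, p=p, n_iter=n_iter)
    if norm is not None and norm != "none":
        out = normalize(out, method=norm)
    return out
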