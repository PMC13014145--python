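"""Differential Raman "expression": median log2 fold changes, rank-sum
testing with FDR control, highly-variant wavenumber selection and spectral
barcodes.

Fold changes are computed from the ratio of per-group median intensities
(negatives clipped to zero, a small pseudo-intensity added) so the estimate
is invariant to per-cell multiplicative scale; display copies are clipped to
the conventional [-2, +2] color range. Input spectra should be
baseline-corrected; vector normalization is deliberately not required, since
group medians already cancel cell-scale variation while L2 normalization
couples wavenumbers and biases per-band fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .classify import ImportanceCurve
from .spectra_io import SpectraMatrix, WavenumberGrid


@dataclass
class FoldChangeProfile:
    wavenumbers: np.ndarray
    log2fc: np.ndarray
    group: str = ""
    reference: str = ""
    clip: float = 2.0
    below_floor: np.ndarray | None = None

    @property
    def clipped_log2fc(self) -> np.ndarray:
        return np.clip(self.log2fc, -self.clip, self.clip)


def noise_floor_scale(*matrices) -> float:
    """Robust per-cell intensity noise scale of one or more spectra matrices.

    1.4826 x the median over wavenumbers of the per-wavenumber median
    absolute deviation across cells; at band-free wavenumbers this estimates
    the additive measurement noise.
    """
    mads = []
    for X in matrices:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] >= 2:
            med = np.median(X, axis=0)
            mads.append(np.median(np.abs(X - med), axis=0))
    if not mads:
        return 0.0
    return float(1.4826 * np.median(np.concatenate(mads)))


def median_log2_fc(reference: np.ndarray, group: np.ndarray,
                   wavenumbers=None, eps: float | None = None,
                   detection_floor: float | None = None,
                   names=("reference", "group")) -> FoldChangeProfile:
    """Per-wavenumber log2 of the ratio of group medians (group vs reference).

    Negative intensities are clipped to zero before taking medians. ``eps``
    (default: twice the pooled noise-floor scale, never below 1e-4 of the
    global maximum) damps ratios of near-zero medians, and wavenumbers where
    both medians fall below ``detection_floor`` (default: three times the
    noise-floor scale) are reported as 0 and flagged ``below_floor`` —
    fold changes under the measurement noise floor carry no information.
    On noiseless input both guards vanish and the ratio of medians is exact.
    """
    Araw = np.atleast_2d(np.asarray(reference, dtype=float))
    Braw = np.atleast_2d(np.asarray(group, dtype=float))
    if Araw.shape[0] == 0 or Braw.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    sig = noise_floor_scale(Araw, Braw)
    A = np.clip(Araw, 0, None)
    B = np.clip(Braw, 0, None)
    if eps is None:
        eps = max(2.0 * sig, 1e-4 * max(A.max(), B.max(), 1e-300))
    if detection_floor is None:
        detection_floor = 3.0 * sig
    medA = np.median(A, axis=0)
    medB = np.median(B, axis=0)
    fc = np.log2((medB + eps) / (medA + eps))
    below = np.maximum(medA, medB) < detection_floor
    fc[below] = 0.0
    if wavenumbers is None:
        wavenumbers = np.arange(A.shape[1], dtype=float)
    return FoldChangeProfile(np.asarray(wavenumbers, dtype=float), fc,
                             group=names[1], reference=names[0],
                             below_floor=below)


def wilcoxon_per_wavenumber(groupA: np.ndarray, groupB: np.ndarray,
                            wavenumbers=None, fdr_method: str = "fdr_bh"
                            ) -> pd.DataFrame:
    """Two-sided rank-sum test per wavenumber with FDR-adjusted q-values.

    Ties are handled by midranks; exact p-values are used for small tie-free
    groups, the tie-corrected normal approximation otherwise. Wavenumbers
    constant across both groups are flagged degenerate with p = 1. The
    reported statistic is the rank sum of group A in the pooled midranking.
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    nA = A.shape[0]
    if nA < 2 or B.shape[0] < 2:
        raise ValueError("both groups need at least two cells")
    n_w = A.shape[1]
    stat = np.empty(n_w)
    p = np.ones(n_w)
    degenerate = np.zeros(n_w, dtype=bool)
    for j in range(n_w):
        a, b = A[:, j], B[:, j]
        if np.all(a == a[0]) and np.all(b == a[0]):
            degenerate[j] = True
            stat[j] = nA * (nA + B.shape[0] + 1) / 2.0  # midrank sum
            continue
        res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        stat[j] = res.statistic + nA * (nA + 1) / 2.0  # U -> rank sum W
        p[j] = res.pvalue
    q = multipletests(p, method=fdr_method)[1]
    if wavenumbers is None:
        wavenumbers = np.arange(n_w, dtype=float)
    return pd.DataFrame({
        "wavenumber": np.asarray(wavenumbers, dtype=float),
        "statistic": stat, "p": p, "q": q, "degenerate": degenerate})


@dataclass(frozen=True)
class SelectedWavenumber:
    wavenumber: float
    provenance: str  # "importance", "peak", or "importance+peak"
    strength: float


def select_highly_variant(importance: ImportanceCurve | None,
                          mean_spectrum: np.ndarray | None,
                          grid: WavenumberGrid,
                          tests: pd.DataFrame | None = None,
                          k_top: int = 10, q_max: float = 0.05,
                          prominence_frac: float = 0.05,
                          merge_fwhm: float = 15.0) -> list:
    """Union of top-dropoff wavenumbers and significant prominent peaks.

    Peaks are local maxima of the group-mean spectrum with prominence at
    least ``prominence_frac`` of its maximum that also pass the rank-sum FDR
    threshold ``q_max`` (when test results are provided). Selections closer
    than one ``merge_fwhm`` are merged to the strongest member.
    """
    picks: dict[float, SelectedWavenumber] = {}

    def add(w, prov, strength):
        w = float(w)
        if w in picks:
            old = picks[w]
            prov = "+".join(sorted(set(old.provenance.split("+")) | {prov}))
            strength = max(old.strength, strength)
        picks[w] = SelectedWavenumber(w, prov, float(strength))

    if importance is not None and k_top > 0:
        order = np.argsort(importance.dropoff)[::-1][:k_top]
        for i in order:
            if importance.dropoff[i] > 0:
                add(importance.wavenumbers[i], "importance",
                    importance.dropoff[i])
    if mean_spectrum is not None:
        mean_spectrum = np.asarray(mean_spectrum, dtype=float)
        prom = prominence_frac * mean_spectrum.max()
        idx, _ = find_peaks(mean_spectrum, prominence=prom)
        for i in idx:
            w = grid.values[i]
            if tests is not None:
                qs = np.interp(w, tests["wavenumber"], tests["q"])
                if qs > q_max:
                    continue
            add(w, "peak", mean_spectrum[i])
    if not picks:
        raise ValueError(
            "no highly variant wavenumbers selected; relax k_top, q_max or "
            "prominence_frac")
    # merge neighbours within one fwhm to the strongest member
    ordered = sorted(picks.values(), key=lambda s: -s.strength)
    kept: list[SelectedWavenumber] = []
    for cand in ordered:
        near = [k for k in kept if abs(k.wavenumber - cand.wavenumber)
                <= merge_fwhm]
        if near:
            k = near[0]
            merged = "+".join(sorted(set(k.provenance.split("+"))
                                     | set(cand.provenance.split("+"))))
            kept[kept.index(k)] = SelectedWavenumber(k.wavenumber, merged,
                                                     k.strength)
        else:
            kept.append(cand)
    return sorted(kept, key=lambda s: s.wavenumber)


@dataclass
class Barcode:
    """Median log2 fold changes of groups vs a common reference at selected
    highly-variant wavenumbers."""

    table: pd.DataFrame  # rows = groups, columns = wavenumbers
    reference: str
    provenance: dict = field(default_factory=dict)


def build_barcode(spectra: SpectraMatrix, groups, selection,
                  reference_mask=None, reference_name: str = "reference",
                  eps: float | None = None) -> Barcode:
    """Barcode rows = per-group median log2 fold change vs the reference.

    ``groups`` maps group name -> boolean row mask (or index array);
    ``selection`` is a list of SelectedWavenumber (or plain wavenumbers);
    ``reference_mask`` defaults to all cells pooled.
    """
    sel_w = np.array([getattr(s, "wavenumber", s) for s in selection],
                     dtype=float)
    if sel_w.size == 0:
        raise ValueError("selection is empty")
    cols = np.array([int(np.argmin(np.abs(spectra.grid.values - w)))
                     for w in sel_w])
    X = spectra.intensities
    ref = X if reference_mask is None else X[reference_mask]
    if ref.shape[0] == 0:
        raise ValueError("reference group is empty")
    # noise floor from the full matrix, not just the selected (band) columns
    sig = noise_floor_scale(X)
    if eps is None:
        eps = max(2.0 * sig, 1e-4 * max(np.clip(X, 0, None).max(), 1e-300))
    floor = 3.0 * sig
    rows = {}
    for name, mask in groups.items():
        sub = X[mask]
        if sub.shape[0] == 0:
            warnings.warn(f"group {name!r} has no cells; omitted")
            continue
        prof = median_log2_fc(ref[:, cols], sub[:, cols],
                              wavenumbers=sel_w, eps=eps,
                              detection_floor=floor,
                              names=(reference_name, str(name)))
        rows[name] = prof.log2fc
    table = pd.DataFrame(rows, index=sel_w).T
    prov = {float(getattr(s, "wavenumber", s)):
            getattr(s, "provenance", "explicit") for s in selection}
    return Barcode(table, reference_name, prov)


def likelihood_strata(likelihoods: np.ndarray, hi: float = 0.8,
                      lo: float = 0.2) -> dict:
    """Group masks for resistant-like (>hi) and sensitive-like (<lo) cells."""
    lk = np.asarray(likelihoods, dtype=float)
    return {f"likelihood>{hi:g}": lk > hi, f"likelihood<{lo:g}": lk < lo}
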