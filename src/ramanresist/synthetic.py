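"""Synthetic single-cell Raman cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: spectra are sums of biochemical vibrational bands (Voigt/Gaussian/
Lorentzian line shapes at literature band positions for phenylalanine,
nucleic acids, proteins, lipids, melanin, tryptophan and carotenoids), with
per-cell multiplicative amplitude jitter, a global per-cell intensity scale,
a fluorescence-like smooth polynomial background, additive detector noise
and rare single-point cosmic-ray spikes. Treatment response is planted as
per-band log2 intensity shifts carried by the cells of resistant samples
("persister" semantics: the biochemical resistance signature is a property
of the surviving cell population, visible in treated and untreated cells
alike; a switch restricts it to treated cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import voigt_profile as _voigt_norm

from .spectra_io import (CohortMetadata, SpectraMatrix, WavenumberGrid)

import pandas as pd

_FWHM_G = 2.0 * np.sqrt(2.0 * np.log(2.0))  # Gaussian FWHM / sigma
# Approximate Voigt FWHM for equal Gaussian and Lorentzian component FWHM f0:
# fV ~= 0.5346 f0 + sqrt(0.2166 f0^2 + f0^2) = 1.6376 f0.
_VOIGT_EQUAL_SPLIT = 0.5346 + np.sqrt(0.2166 + 1.0)


def voigt_profile(x, center: float, sigma: float, gamma: float,
                  amplitude: float = 1.0) -> np.ndarray:
    """Peak-normalized Voigt line shape.

    Convolution of a Gaussian (sd ``sigma``) and a Lorentzian (HWHM
    ``gamma``), scaled so the value at ``center`` equals ``amplitude``.
    Either width may be zero (pure Lorentzian / pure Gaussian) but not both.
    """
    if sigma < 0 or gamma < 0:
        raise ValueError("sigma and gamma must be nonnegative")
    if sigma == 0 and gamma == 0:
        raise ValueError("sigma and gamma cannot both be zero")
    x = np.asarray(x, dtype=float)
    peak = _voigt_norm(0.0, sigma, gamma)
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError(
            f"degenerate line widths sigma={sigma:g}, gamma={gamma:g}")
    return amplitude * _voigt_norm(x - center, sigma, gamma) / peak


def fwhm_to_sigma_gamma(fwhm: float, shape: str = "voigt"):
    """Translate a nominal FWHM into (sigma, gamma) for a line shape."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if shape == "gaussian":
        return fwhm / _FWHM_G, 0.0
    if shape == "lorentzian":
        return 0.0, fwhm / 2.0
    if shape == "voigt":
        f0 = fwhm / _VOIGT_EQUAL_SPLIT
        return f0 / _FWHM_G, f0 / 2.0
    raise ValueError(f"unknown line shape {shape!r}")


@dataclass(frozen=True)
class Band:
    """One vibrational band: position, width, line shape, assignment."""

    center: float
    fwhm: float = 12.0
    shape: str = "voigt"
    assignment: str = ""

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be positive")

    def render(self, grid: WavenumberGrid) -> np.ndarray:
        """Unit-peak profile of this band on ``grid``."""
        if not (grid.lo <= self.center <= grid.hi):
            raise ValueError(
                f"band center {self.center:g} outside grid "
                f"[{grid.lo:g}, {grid.hi:g}]")
        sigma, gamma = fwhm_to_sigma_gamma(self.fwhm, self.shape)
        return voigt_profile(grid.values, self.center, sigma, gamma)


# Literature fingerprint-band positions (cm^-1) by biochemical assignment.
BAND_ASSIGNMENTS = {
    "phenylalanine": (1003, 1606),
    "nucleic acid": (667, 748, 780, 1306, 1337, 1585),
    "protein": (748, 1126, 1336, 1446, 1585, 1664),
    "lipid": (1306, 1446),
    "melanin": (1385, 1580),
    "tryptophan": (750,),
    "carotenoid": (1156,),
}


def default_band_library() -> dict:
    """Map band center -> Band for every catalogued assignment."""
    lib = {}
    for assignment, centers in BAND_ASSIGNMENTS.items():
        for c in centers:
            if c in lib:
                lib[c] = replace(lib[c],
                                 assignment=f"{lib[c].assignment}/{assignment}")
            else:
                lib[c] = Band(center=float(c), assignment=assignment)
    return lib


@dataclass(frozen=True)
class PhenotypeProfile:
    """Mean spectral identity of one cell phenotype.

    ``amplitudes`` are mean peak heights (a.u.) per band; ``band_cv`` is the
    per-cell coefficient of variation of each band amplitude (lognormal,
    multiplicative).
    """

    name: str
    bands: tuple
    amplitudes: tuple
    band_cv: float = 0.15
    baseline_level: float = 0.0

    def __post_init__(self):
        if len(self.bands) != len(self.amplitudes):
            raise ValueError("one amplitude per band required")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("band amplitudes must be nonnegative")
        if self.band_cv < 0:
            raise ValueError("band_cv must be nonnegative")

    def with_cv(self, cv: float) -> "PhenotypeProfile":
        return replace(self, band_cv=cv)

    def template(self, grid: WavenumberGrid,
                 log2_shifts: dict | None = None) -> np.ndarray:
        """Noiseless mean spectrum, optionally with planted log2 shifts."""
        out = np.zeros(len(grid))
        for band, amp in zip(self.bands, self.amplitudes):
            shift = (log2_shifts or {}).get(band.center, 0.0)
            out += amp * 2.0 ** shift * band.render(grid)
        return out


@dataclass(frozen=True)
class TreatmentEffect:
    """Planted per-band log2 multiplicative intensity shifts for one drug."""

    drug: str
    band_log2_shifts: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(not np.isfinite(s) for s in self.band_log2_shifts.values()):
            raise ValueError("log2 shifts must be finite")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement and background noise configuration (all amplitudes a.u.)."""

    additive_noise_sd: float = 0.02
    baseline_poly_degree: int = 3
    baseline_coeff_sd: float = 0.05
    spike_rate: float = 0.05
    cell_scale_cv: float = 0.2

    def __post_init__(self):
        if min(self.additive_noise_sd, self.baseline_coeff_sd,
               self.spike_rate, self.cell_scale_cv) < 0:
            raise ValueError("noise parameters must be nonnegative")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PatientSpec:
    """One synthetic patient: subpopulation mixture, labels, cell count."""

    patient_id: str
    subpopulations: tuple  # of (PhenotypeProfile, fraction)
    resistance_labels: dict = field(default_factory=dict)
    n_cells: int = 522

    def __post_init__(self):
        fracs = [f for _, f in self.subpopulations]
        if abs(sum(fracs) - 1.0) > 1e-9 or min(fracs) < 0:
            raise ValueError("mixing fractions must be nonnegative, sum 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _lognormal_factor(rng, cv, size):
    """Multiplicative jitter with median 1 and given coefficient of variation."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, s, size=size))


def synth_spectrum(profile: PhenotypeProfile,
                   effect: TreatmentEffect | None,
                   noise: NoiseModel,
                   grid: WavenumberGrid,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw one single-cell spectrum.

    Sum over bands of amplitude x lognormal per-cell jitter x 2^shift x unit
    line shape, times a global cell intensity scale, plus a random smooth
    polynomial background, Gaussian noise and Poisson-count one-point spikes;
    the result is clipped at zero.
    """
    shifts = effect.band_log2_shifts if effect is not None else {}
    jitter = _lognormal_factor(rng, profile.band_cv, len(profile.bands))
    out = np.zeros(len(grid))
    max_band = 0.0
    for band, amp, j in zip(profile.bands, profile.amplitudes, jitter):
        h = amp * j * 2.0 ** shifts.get(band.center, 0.0)
        max_band = max(max_band, h)
        out += h * band.render(grid)
    out *= _lognormal_factor(rng, noise.cell_scale_cv, None)
    if profile.baseline_level or noise.baseline_coeff_sd:
        t = np.linspace(-1.0, 1.0, len(grid))
        coeffs = rng.normal(0.0, noise.baseline_coeff_sd,
                            size=noise.baseline_poly_degree + 1)
        out += profile.baseline_level + np.polyval(coeffs, t) \
            + noise.baseline_coeff_sd  # keep background mostly nonnegative
    if noise.additive_noise_sd:
        out += rng.normal(0.0, noise.additive_noise_sd, size=len(grid))
    if noise.spike_rate:
        n_spikes = rng.poisson(noise.spike_rate)
        if n_spikes:
            pos = rng.integers(0, len(grid), size=n_spikes)
            out[pos] += 10.0 * max(max_band, 1.0)
    return np.clip(out, 0.0, None)


def synth_cohort(patients, treatments, effects, noise, grid, seed,
                 effect_scope: str = "persister"):
    """Generate a cohort of patients with planted resistance signatures.

    Parameters
    ----------
    patients : sequence of PatientSpec
    treatments : sequence of treatment-arm names cells are cycled through
        (``"untreated"`` means no drug exposure).
    effects : mapping drug -> TreatmentEffect. A patient labeled resistant to
        a drug carries that drug's band shifts in all cells
        (``effect_scope="persister"``) or only in cells of that treatment arm
        (``effect_scope="treated_only"``).
    noise : NoiseModel
    grid : WavenumberGrid
    seed : int
    """
    if effect_scope not in ("persister", "treated_only"):
        raise ValueError(f"unknown effect_scope {effect_scope!r}")
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    for t in treatments:
        if t != "untreated" and t not in effects:
            raise ValueError(f"treatment {t!r} has no TreatmentEffect entry")
    rng = np.random.default_rng(seed)
    drugs = sorted(effects)
    rows, cell_ids, meta_rows = [], [], []
    truth = {"seed": int(seed), "effect_scope": effect_scope,
             "effects": {d: dict(effects[d].band_log2_shifts) for d in drugs},
             "patients": {}}
    for pat in patients:
        fracs = np.array([f for _, f in pat.subpopulations])
        sub_idx = rng.choice(len(fracs), size=pat.n_cells, p=fracs)
        arms = [treatments[i % len(treatments)] for i in range(pat.n_cells)]
        resistant_to = [d for d in drugs
                        if pat.resistance_labels.get(d) == "resistant"]
        truth["patients"][pat.patient_id] = {
            "n_cells": int(pat.n_cells),
            "labels": {d: pat.resistance_labels.get(d, "unknown")
                       for d in drugs},
            "subpopulations": [(prof.name, float(f))
                               for prof, f in pat.subpopulations],
            "subpopulation_of_cell": sub_idx.tolist(),
        }
        for i in range(pat.n_cells):
            profile = pat.subpopulations[sub_idx[i]][0]
            shifts = {}
            if effect_scope == "persister":
                active = resistant_to
            else:
                active = [d for d in resistant_to if d == arms[i]]
            for d in active:
                for c, s in effects[d].band_log2_shifts.items():
                    shifts[c] = shifts.get(c, 0.0) + s
            eff = TreatmentEffect("combined", shifts) if shifts else None
            rows.append(synth_spectrum(profile, eff, noise, grid, rng))
            cell_ids.append(f"{pat.patient_id}_c{i:05d}")
            meta = {"sample_id": pat.patient_id,
                    "passage": 0, "treatment": arms[i]}
            for d in drugs:
                meta[d] = pat.resistance_labels.get(d, "unknown")
            meta_rows.append(meta)
    spectra = SpectraMatrix(np.array(cell_ids, dtype=object), grid,
                            np.vstack(rows) if rows else
                            np.empty((0, len(grid))))
    table = pd.DataFrame(meta_rows, index=pd.Index(cell_ids, name="cell_id"))
    metadata = CohortMetadata(table, tuple(drugs))
    return spectra, metadata, truth


# --------------------------------------------------------------------------
# Ready-made study scenarios
# --------------------------------------------------------------------------

DEMO_DRUGS = ("bemcentinib", "cabozantinib", "dabrafenib", "nivolumab",
              "nivolumab+relatlimab")

# Two band sites per drug with |log2 FC| = 1.0, disjoint across drugs.
# Overlapping twin bands (748/750, 1336/1337) are shifted together so the
# observed intensity change at the site is not diluted by an unshifted twin,
# and no signature site sits on the shoulder of a strong unshifted band.
DEMO_EFFECTS = {
    "bemcentinib": TreatmentEffect(
        "bemcentinib", {1003.0: 1.0, 1336.0: -1.0, 1337.0: -1.0}),
    "cabozantinib": TreatmentEffect(
        "cabozantinib", {748.0: 1.0, 750.0: 1.0, 1446.0: -1.0}),
    "dabrafenib": TreatmentEffect("dabrafenib",
                                  {780.0: 1.0, 1664.0: 1.0}),
    "nivolumab": TreatmentEffect("nivolumab",
                                 {1126.0: -1.0, 1606.0: 1.0}),
    "nivolumab+relatlimab": TreatmentEffect("nivolumab+relatlimab",
                                            {667.0: 1.0, 1306.0: -1.0}),
}

# 9 patients x 5 drugs. The matrix is chosen so the per-drug prediction task
# is well posed under leave-one-patient-out training: 4-5 resistant patients
# per drug; pairwise column agreement between 3 and 6 (no two drugs share
# near-identical or near-complementary response patterns); on every
# 8-patient training subset no other drug's column (or its complement)
# coincides with the target column, otherwise another drug's planted
# signature would be a perfect confounder of the target label; and every
# patient is, in full label-vector Hamming distance, on average closer to its
# true class than to the other class for every drug (a nearest-cluster rule
# on co-signatures cannot systematically invert the call).
DEMO_LABEL_MATRIX = {
    "PAT-01": "SSSSS", "PAT-02": "RRRSS", "PAT-03": "RRSRR",
    "PAT-04": "SSRSR", "PAT-05": "SRSSR", "PAT-06": "SRSRR",
    "PAT-07": "RSSRS", "PAT-08": "RSRRR", "PAT-09": "RRRSS",
}


def _profile(name, amp_by_center, cv=0.15):
    lib = default_band_library()
    bands, amps = [], []
    for c, band in sorted(lib.items()):
        bands.append(band)
        amps.append(amp_by_center.get(c, 0.0))
    return PhenotypeProfile(name, tuple(bands), tuple(amps), band_cv=cv)


def melanoma_profile(cv=0.15) -> PhenotypeProfile:
    """Melanin-rich tumor-cell archetype.

    Band sites that carry planted treatment signatures are kept at
    comparable amplitude so no drug's signature is intrinsically fainter
    than another's.
    """
    return _profile("melanoma", {
        667: 0.85, 748: 0.85, 750: 0.3, 780: 0.8, 1003: 1.0, 1126: 0.85,
        1156: 0.3, 1306: 0.85, 1336: 0.6, 1337: 0.6, 1385: 0.9, 1446: 0.9,
        1580: 0.9, 1585: 0.5, 1606: 0.85, 1664: 0.8}, cv)


def immune_profile(cv=0.15) -> PhenotypeProfile:
    """Immune-cell archetype: strong tryptophan/nucleic-acid signal."""
    return _profile("immune", {
        667: 0.8, 748: 0.9, 750: 0.9, 780: 0.9, 1003: 0.8, 1126: 0.7,
        1156: 0.1, 1306: 0.7, 1336: 0.8, 1337: 0.8, 1385: 0.1, 1446: 0.6,
        1580: 0.1, 1585: 0.8, 1606: 0.6, 1664: 0.7}, cv)


def fibroblast_profile(cv=0.15) -> PhenotypeProfile:
    """Stromal archetype: protein/lipid-dominated, little pigment."""
    return _profile("fibroblast", {
        667: 0.5, 748: 0.6, 750: 0.4, 780: 0.6, 1003: 0.9, 1126: 0.8,
        1156: 0.2, 1306: 0.9, 1336: 0.5, 1337: 0.5, 1385: 0.05, 1446: 1.0,
        1580: 0.05, 1585: 0.4, 1606: 0.7, 1664: 1.0}, cv)


def two_class_cohort(n_per_class=1000, band_center=1003.0, log2_shift=1.0,
                     noise: NoiseModel | None = None, seed=0,
                     grid: WavenumberGrid | None = None):
    """Two phenotype classes differing by one planted band shift.

    Returns (SpectraMatrix, labels array, truth dict). Class "shifted"
    carries ``log2_shift`` at ``band_center``; class "base" does not.
    """
    grid = grid or WavenumberGrid.regular()
    noise = NoiseModel() if noise is None else noise
    profile = melanoma_profile()
    effect = TreatmentEffect("planted", {float(band_center): log2_shift})
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i in range(n_per_class):
        rows.append(synth_spectrum(profile, None, noise, grid, rng))
        labels.append("base")
    for i in range(n_per_class):
        rows.append(synth_spectrum(profile, effect, noise, grid, rng))
        labels.append("shifted")
    ids = np.array([f"c{i:05d}" for i in range(2 * n_per_class)],
                   dtype=object)
    spectra = SpectraMatrix(ids, grid, np.vstack(rows))
    truth = {"band_center": float(band_center),
             "log2_shift": float(log2_shift), "seed": int(seed)}
    return spectra, np.array(labels, dtype=object), truth


def demo_cohort(seed=0, mean_cells=522, min_cells=96, max_cells=1512,
                noise: NoiseModel | None = None,
                grid: WavenumberGrid | None = None,
                effects: dict | None = None,
                cells_scale: float = 1.0):
    """The documented 9-patient x 5-drug demonstration cohort.

    Per-patient cell counts are drawn around ``mean_cells`` and clamped to
    [min_cells, max_cells]; each patient is a random mixture of tumor,
    immune and stromal archetypes; resistance labels follow a fixed,
    per-drug-balanced matrix and drive planted two-band signatures.
    ``cells_scale`` shrinks the cohort proportionally for fast runs.
    """
    grid = grid or WavenumberGrid.regular()
    noise = NoiseModel() if noise is None else noise
    effects = DEMO_EFFECTS if effects is None else effects
    rng = np.random.default_rng([seed, 9001])
    profiles = (melanoma_profile(), immune_profile(), fibroblast_profile())
    patients = []
    for pid, code in DEMO_LABEL_MATRIX.items():
        labels = {d: ("resistant" if c == "R" else "sensitive")
                  for d, c in zip(DEMO_DRUGS, code)}
        n = int(np.clip(round(rng.normal(mean_cells, 300)),
                        min_cells, max_cells))
        n = max(int(round(n * cells_scale)), 20)
        # identical expected composition across patients: tumor-immune-stroma
        # heterogeneity lives within each patient (per-cell mixture draws),
        # not between patients, matching the observation that cell-type
        # clusters are largely independent of patient origin
        subs = tuple(zip(profiles, (0.6, 0.2, 0.2)))
        patients.append(PatientSpec(pid, subs, labels, n))
    return synth_cohort(patients, ("untreated",) + tuple(DEMO_DRUGS),
                        effects, noise, grid, seed)
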