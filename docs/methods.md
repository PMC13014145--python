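# Methods

`ramanresist` implements a single-cell Raman phenotyping and drug-resistance
determination pipeline together with a synthetic cohort generator that
provides ground truth for validating it. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Synthetic spectra model

A single-cell spectrum on the fingerprint grid (600–1800 cm⁻¹, 1 cm⁻¹
spacing by default; the spacing is a convention, not a measured instrument
property) is generated as

```
I(w) = s · Σ_b  A_b · J_b · 2^{δ_b} · V_b(w)  +  B(w) + ε(w) + spikes,
```

where

- `V_b` is a peak-normalized Voigt line shape (Gaussian ⊗ Lorentzian;
  `scipy.special.voigt_profile` rescaled so the value at the band center
  equals 1). Peak normalization means band "amplitude" is peak height, the
  quantity read off heatmaps. Default width 12 cm⁻¹ FWHM, split equally
  between the Gaussian and Lorentzian components (a typical condensed-phase
  linewidth, not a fitted value).
- Band centers come from standard biochemical assignments: phenylalanine
  1003/1606, nucleic acids 667/748/780/1306/1337/1585, protein
  748/1126/1336/1446/1585/1664, lipid 1306/1446, melanin 1385/1580,
  tryptophan 750, carotenoid 1156 cm⁻¹.
- `A_b` is the phenotype profile's mean amplitude, `J_b` a per-cell,
  per-band lognormal jitter with median 1 (CV 0.15 by default), and `s` a
  per-cell global intensity scale, lognormal with median 1 (CV 0.2) —
  cells vary in size and optical coupling.
- `δ_b` is the planted treatment effect in log2 units. Effects attach to
  the cells of resistant-labeled samples ("persister" semantics: the
  surviving population carries the signature whether or not a given cell
  was in the treated aliquot; a switch restricts effects to treated arms).
- `B(w)` is a random degree-3 polynomial emulating fluorescence background
  (coefficient sd 0.05), `ε` Gaussian detector noise (sd 0.02), and spikes
  are Poisson-count single-point cosmic-ray artifacts (rate 0.05/spectrum,
  amplitude 10× the largest band).

With noise switched off the generator is exact: a planted shift δ
multiplies the band's contribution by 2^δ, and because the jitters have
median 1, group medians recover planted amplitudes without bias.

### The demonstration cohort

`demo_cohort` builds 9 patients × 5 treatment regimes (bemcentinib,
cabozantinib, dabrafenib, nivolumab, nivolumab+relatlimab). Cell counts are
drawn around a mean of 522 and clamped to [96, 1512]. Each patient is a
0.6/0.2/0.2 mixture of tumor / immune / stromal archetypes; the expected
composition is identical across patients, so tumor heterogeneity lives
*within* a patient and composition is not a patient fingerprint (cell-type
structure largely independent of sample origin, as observed in real
cohorts). Each drug's resistance signature is ±1.0 log2 shifts at two
disjoint band sites, with overlapping twin bands (748/750, 1336/1337)
shifted together so no signature is diluted by an unshifted neighbor, and
profile amplitudes at signature sites kept comparable so no drug is
intrinsically fainter.

The 9×5 resistance label matrix is a designed object, not a random draw.
With only 8 training patients per leave-one-out fit, other drugs' planted
signatures are potential confounders of the target label, so the matrix
satisfies: 4–5 resistant patients per drug; pairwise column agreement
between 3 and 6 (no two drugs nearly identical or complementary); on every
8-patient subset no other column or its complement coincides with the
target column; and each patient's full label vector is on average closer in
Hamming distance to its true class than to the other class, for every drug.
Without these properties the patient-level prediction task is unidentifiable
regardless of classifier.

## Preprocessing

Pipeline order: crop to 600–1800 cm⁻¹ (inclusive) → despike → baseline →
normalize → (PCA where used). All per-spectrum steps are row-local, so a
fitted `RamanPreprocessor` is leak-free across any train/test split.

- **Despiking:** a point is replaced by the local running median when it
  exceeds it by 8× the local MAD (window 5). One-point spikes are removed;
  12 cm⁻¹ bands are untouched.
- **Baseline:** asymmetric least squares — iteratively reweighted smooth
  fit with a second-difference penalty (`lam` 1e5) and asymmetry `p` 0.01,
  10 iterations, solved per spectrum with a banded Cholesky factorization.
  Output is invariant to constant offsets and preserves isolated peak
  heights to within ~5%.
- **Normalization:** unit Euclidean norm by default (area mode available).
  Note that vector normalization couples wavenumbers: doubling one band
  rescales every other one by a few percent. Classification is insensitive
  to this; fold-change estimation is not (below).
- **PCA:** `VarianceTargetPCA` keeps the smallest number of components
  whose cumulative explained variance reaches the target (0.95 default),
  optionally capped (50 components feed UMAP). Mean-centering only, no
  z-scoring. Backed by the exact covariance eigendecomposition solver;
  loadings are orthonormal to 1e-8 and match a brute-force
  eigendecomposition up to sign.

## Phenotype classification and wavenumber importance

`cross_validate` runs stratified k-fold (default 5) with the full
PCA-plus-random-forest pipeline refit inside each training fold, class
weights inversely proportional to training-fold class frequencies, 500
trees with the sqrt feature rule by default, and a pooled confusion matrix.
Evaluation-scale scenarios in the acceptance suite use 200 trees; accuracy
is tree-count-saturated well below that on these cohorts.

Wavenumber importance is perturbation-based: for each evaluation wavenumber
(every 2 cm⁻¹ by default), every *test* spectrum receives an additive Voigt
bump (FWHM 15 cm⁻¹) at that position, scaled per spectrum to one standard
deviation of its intensities, applied in pre-PCA space; the importance is
the mean drop in held-out accuracy across folds (negative values reported,
not clipped). An additive bump remains meaningful after normalization; a
masking (zeroing) mode is available. Because the PCA projection is linear,
the bump is projected once per (fold, wavenumber) and added in score space,
and all perturbed predictions are evaluated in one batched forest call.

## Differential intensity analysis

Fold changes are `log2((median_B + ε) / (median_A + ε))` per wavenumber,
negatives clipped to zero before the medians. Two guards make this
meaningful on noisy spectra:

- ε defaults to **2× the noise-floor scale** σ̂ = 1.4826 × median over
  wavenumbers of the per-wavenumber MAD across cells (never below 1e-4 of
  the global maximum). At band-free wavenumbers σ̂ estimates the additive
  measurement noise.
- Wavenumbers where **both** group medians fall below 3σ̂ report a fold
  change of 0 and a `below_floor` flag: a ratio of two quantities below the
  detection limit carries no information, and without this rule sampling
  noise of near-zero medians produces |log2FC| > 2 artifacts.

On noiseless input σ̂ = 0 and the estimator reduces to the exact ratio of
medians. Fold changes are computed on baseline-corrected but
*unnormalized* intensities: group medians already cancel per-cell scale
(median-1 jitter), whereas L2 normalization would bias a planted +1.0 shift
down by up to 0.15 depending on the band's share of spectral energy.
Swapping group and reference negates the result exactly.

Per-wavenumber two-sided rank-sum tests use midranks, exact null
distributions for small tie-free groups and the tie-corrected normal
approximation otherwise; Benjamini–Hochberg q-values are computed across
wavenumbers within a contrast. Highly variant wavenumbers are the union of
top-importance positions and prominent mean-spectrum peaks (prominence ≥5%
of maximum) passing q ≤ 0.05, merged within one perturbation FWHM to the
strongest member, with provenance recorded. Barcodes are rows of median
log2 fold changes vs a common reference at those wavenumbers; rows can be
samples, Leiden clusters, or resistance-likelihood strata (>0.8 / <0.2).

## Embedding and clustering

Leiden community detection runs on an unweighted kNN graph (k=15,
Euclidean in PC space) with the RB-configuration objective at resolution
0.5; labels are relabeled contiguously by decreasing size. UMAP (top 50
PCs, n_neighbors 15, min_dist 0.1, fixed seed) is exploratory only; no
quantitative claim rests on embedding geometry. For small test cohorts
(hundreds of cells) the planted-partition check uses k=30, since k=15
over-fragments sparse graphs.

## Two-stage resistance determination

Per drug: (1) a single-spectrum classifier is trained on all spectra of
samples with known response, each spectrum inheriting its sample's label;
(2) a patient's spectra are resampled into mini patients — 25,000 subsets
of 50 spectra drawn with replacement — each subset is called resistant
when its mean per-spectrum resistance probability strictly exceeds 0.5, and
the patient's resistance likelihood is the fraction of resistant mini
patients. The patient label is resistant iff likelihood > cutoff (default
0.5; a tie falls to sensitive). Cutoffs can be re-optimized per drug by
balanced-accuracy grid search (step 0.01, ties toward 0.5) on training
patients only. With subset size 1 the likelihood is computed exactly as the
fraction of spectra above threshold. Subset size 50 is a design default
(unstated in the source architecture): it smooths likelihoods for patients
as small as 96 spectra while letting minority subpopulations shift the
subset distribution.

The default single-spectrum classifier is an ensemble of **decision
stumps** (depth-1 trees, 200 of them, 200 candidate wavenumbers per split,
30% bootstrap subsamples) on the full preprocessed fingerprint, not on PC
scores. The reason is patient-level generalization: a drug's resistance
signature is an additive per-band shift shared by every resistant sample,
so single-wavenumber marginal voters transfer across patients, whereas
deeper trees — and especially trees over principal components, which mix
band sites into patient-cluster directions — memorize sample-specific band
*combinations* and classify held-out patients by co-signature similarity,
confidently and sometimes wrongly. On the demonstration cohort the stump
ensemble resolves all 45 leave-one-patient-out determinations; PCA-based
forests of any depth and rank plateau near 80%. The PCA front end remains
available (`ClassifierSpec(use_pca=True)`).

Leave-one-patient-out evaluation retrains preprocessing-to-forest per held
patient; pairs whose training pool lacks both classes are marked not
evaluable and excluded from the accuracy denominator. Mini-patient seeds
derive deterministically from the global seed and a CRC of (patient, drug),
so reruns are byte-identical.

## Problem sizes in the validation scenarios

The acceptance suite and `scripts/acceptance.py` use: 2 × 1000 spectra for
the planted-band scenario (200-tree forests); 100 replicates of 25,000 mini
patients for the aggregation oracle; 600 null wavenumbers at 50 or 20
cells/group (60 replicates for FDR); the full-size demonstration cohort
(~4,400–4,700 cells) for leave-one-patient-out determination, and a
0.25-scaled, effect-free copy (60-tree stumps) for the chance-level null
harness.

## What the synthetic benchmarks do not show

The generator emulates band structure, multiplicative cell variation,
smooth background, detector noise and spikes. It does not model wavelength
calibration drift, detector nonlinearity, resonance effects of pigments,
batch/passage drift, label noise in clinical response, or biochemistry in
which resistance signatures overlap across drugs or interact with cell
type. Passing these benchmarks demonstrates that the implementation
recovers signal it is designed to recover under the stated statistical
assumptions — not that equivalent accuracy is attainable on real clinical
spectra, where the published analog of the cohort determination task is
substantially harder.

## Known limitations

- ALS baselines bulge slightly into the flanks of strong bands, depressing
  adjacent valleys; the differential module's detection floor absorbs this,
  but per-cell corrected intensities in deep valleys should not be
  interpreted quantitatively.
- Binary resistance labels only; no graded response, no survival modeling.
- Mini-patient aggregation amplifies any systematic bias of the
  single-spectrum classifier: likelihoods saturate at 0/1, so a patient
  whose spectra are mildly but consistently misscored is called with
  unwarranted confidence. The mini-patient distribution summary (quantiles)
  is retained in every call for inspection.
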