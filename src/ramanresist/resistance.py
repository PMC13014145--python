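"""Two-stage patient resistance determination.

Stage one trains, per drug, a single-spectrum random-forest classifier on
spectra of samples with known response, every spectrum inheriting its
sample's label (by default a depth-limited forest on the full preprocessed
fingerprint; a variance-targeted PCA front end is available). Stage two resamples a patient's
spectra into many "mini patients" (default 25,000 subsets of 50 spectra,
with replacement), calls each subset resistant when its mean per-spectrum
resistance probability exceeds a threshold (default 0.5), and reports the
fraction of resistant mini patients as the patient's resistance likelihood.
The patient is labeled resistant when the likelihood strictly exceeds the
decision cutoff (default 0.5; ties fall to sensitive); cutoffs can be
re-optimized per drug on training patients by balanced-accuracy grid search.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd

from .classify import ClassifierSpec, SpectralPhenotypeClassifier
from .spectra_io import CohortMetadata, SpectraMatrix

RESISTANT, SENSITIVE = "resistant", "sensitive"

#: Default single-spectrum classifier for resistance models: an ensemble of
#: decision stumps (depth 1) with wide feature sampling on the full
#: preprocessed fingerprint. A drug's resistance signature is an additive
#: per-band intensity shift shared by every resistant sample, so marginal
#: single-wavenumber voters generalize across patients; deeper trees (and
#: principal-component inputs, which mix band sites into patient-cluster
#: directions) let the forest encode sample-specific band combinations that
#: do not transfer to held-out patients. PCA reduction remains available via
#: ``use_pca=True``.
RESISTANCE_CLASSIFIER_SPEC = ClassifierSpec(
    n_trees=200, use_pca=False, max_depth=1, max_features=200,
    max_samples=0.3)


@dataclass(frozen=True)
class MiniPatientConfig:
    """Mini-patient resampling configuration."""

    n_mini: int = 25_000
    subset_size: int = 50
    sampling: str = "with_replacement"
    aggregation: str = "mean_probability"
    spectrum_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_mini < 1:
            raise ValueError("n_mini must be >= 1")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if self.sampling not in ("with_replacement", "without_replacement"):
            raise ValueError(f"unknown sampling {self.sampling!r}")
        if self.aggregation not in ("mean_probability", "majority_vote"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class PatientCall:
    patient_id: str
    drug: str
    likelihood: float
    label: str
    n_spectra: int
    distribution: dict = field(default_factory=dict)
    decision_cutoff: float = 0.5


@dataclass
class ResistanceModel:
    """Per-drug fitted classifier plus aggregation config and cutoff."""

    drug: str
    classifier: SpectralPhenotypeClassifier
    config: MiniPatientConfig
    decision_cutoff: float = 0.5
    training_patients: tuple = ()

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ResistanceModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold a ResistanceModel")
        return model


def train_resistance_model(spectra: SpectraMatrix, metadata: CohortMetadata,
                           drug: str,
                           spec: ClassifierSpec = RESISTANCE_CLASSIFIER_SPEC,
                           config: MiniPatientConfig = MiniPatientConfig(),
                           exclude_patients=()) -> ResistanceModel:
    """Fit the single-spectrum resistance classifier for one drug.

    Only spectra from samples labeled resistant or sensitive are used;
    sample labels are broadcast to all of the sample's spectra. PCA and the
    forest see training spectra only.
    """
    labels = metadata.labels_for(drug).to_numpy()
    sample = metadata.table["sample_id"].to_numpy()
    usable = np.isin(labels, (RESISTANT, SENSITIVE)) & \
        ~np.isin(sample, list(exclude_patients))
    if not usable.any():
        raise ValueError(f"no labeled training spectra for {drug!r}")
    y = labels[usable]
    present = set(y)
    if len(present) < 2:
        raise ValueError(
            f"training set for {drug!r} has a single class {present}")
    clf = SpectralPhenotypeClassifier.from_spec(spec)
    clf.fit(spectra.intensities[usable], y)
    return ResistanceModel(drug, clf, config,
                           training_patients=tuple(
                               sorted(set(sample[usable]))))


def spectrum_probabilities(model: ResistanceModel,
                           spectra: SpectraMatrix | np.ndarray) -> np.ndarray:
    """Per-spectrum probability of the resistant class."""
    X = (spectra.intensities if isinstance(spectra, SpectraMatrix)
         else np.asarray(spectra, dtype=float))
    proba = model.classifier.predict_proba(X)
    idx = int(np.flatnonzero(model.classifier.classes_ == RESISTANT)[0])
    return proba[:, idx]


def patient_likelihood(probabilities, config: MiniPatientConfig
                       ) -> tuple[float, dict]:
    """Monte-Carlo mini-patient resistance likelihood.

    Draws ``n_mini`` subsets of ``subset_size`` spectra, aggregates each
    subset (mean probability, or majority vote over per-spectrum calls) and
    calls it resistant when the aggregate strictly exceeds
    ``spectrum_threshold``. Returns (likelihood, distribution summary).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one spectrum probability")
    n = p.size
    if config.subset_size == 1:
        # degenerate aggregation: every subset is one spectrum, so the
        # likelihood is exactly the fraction of spectra above threshold
        calls = p > config.spectrum_threshold
        return float(calls.mean()), _summary(p)
    rng = np.random.default_rng(config.seed)
    if config.sampling == "with_replacement":
        idx = rng.integers(0, n, size=(config.n_mini, config.subset_size))
    else:
        if config.subset_size > n:
            raise ValueError(
                f"subset_size={config.subset_size} > {n} spectra under "
                "without_replacement sampling")
        idx = np.empty((config.n_mini, config.subset_size), dtype=int)
        for i in range(config.n_mini):
            idx[i] = rng.choice(n, size=config.subset_size, replace=False)
    draws = p[idx]
    if config.aggregation == "mean_probability":
        agg = draws.mean(axis=1)
    else:  # majority_vote: fraction of per-spectrum resistant calls
        agg = (draws > config.spectrum_threshold).mean(axis=1)
        calls = agg > 0.5
        likelihood = float(calls.mean())
        return likelihood, _summary(agg)
    calls = agg > config.spectrum_threshold
    return float(calls.mean()), _summary(agg)


def _summary(agg: np.ndarray) -> dict:
    qs = np.quantile(agg, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {"mean": float(agg.mean()), "q05": float(qs[0]),
            "q25": float(qs[1]), "median": float(qs[2]),
            "q75": float(qs[3]), "q95": float(qs[4])}


def determine_resistance(model: ResistanceModel, spectra: SpectraMatrix,
                         patient_id: str,
                         allow_training_patient: bool = False) -> PatientCall:
    """Patient-level call: resistant iff likelihood > cutoff (tie: sensitive)."""
    if patient_id in model.training_patients and not allow_training_patient:
        raise ValueError(
            f"{patient_id!r} was in the training set for {model.drug!r}; "
            "pass allow_training_patient=True to override")
    probs = spectrum_probabilities(model, spectra)
    likelihood, dist = patient_likelihood(probs, model.config)
    label = RESISTANT if likelihood > model.decision_cutoff else SENSITIVE
    return PatientCall(patient_id, model.drug, likelihood, label,
                       int(probs.size), dist, model.decision_cutoff)


def optimize_cutoffs(training_calls: dict) -> dict:
    """Per-drug decision cutoff maximizing balanced accuracy.

    ``training_calls`` maps drug -> list of (likelihood, true label). The
    grid is {0.00, 0.01, ..., 1.00}; ties are broken toward 0.5 (then toward
    the smaller cutoff). Degenerate single-class inputs keep 0.5 with a
    warning.
    """
    grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    out = {}
    for drug, calls in training_calls.items():
        lk = np.array([c[0] for c in calls], dtype=float)
        yt = np.array([c[1] for c in calls], dtype=object)
        if not ((yt == RESISTANT).any() and (yt == SENSITIVE).any()):
            warnings.warn(
                f"{drug}: single-class training calls; cutoff stays 0.5")
            out[drug] = 0.5
            continue
        res, sen = yt == RESISTANT, yt == SENSITIVE
        bal = np.empty(grid.size)
        for i, c in enumerate(grid):
            pred_res = lk > c
            tpr = pred_res[res].mean()
            tnr = (~pred_res[sen]).mean()
            bal[i] = 0.5 * (tpr + tnr)
        best = bal.max()
        cands = grid[bal >= best - 1e-12]
        cut = float(cands[np.lexsort((cands, np.abs(cands - 0.5)))[0]])
        if best <= 0.5:
            warnings.warn(
                f"{drug}: optimal balanced accuracy {best:.2f} <= 0.5; "
                "labels may be inverted")
        out[drug] = cut
    return out


@dataclass
class CohortEvaluation:
    calls: pd.DataFrame  # patient, drug, n_spectra, likelihood, cutoff,
    #                      label, true_label, evaluable, correct
    accuracy: float
    per_drug_accuracy: dict


def evaluate_cohort(spectra: SpectraMatrix, metadata: CohortMetadata,
                    drugs=None, protocol: str = "leave_one_patient_out",
                    spec: ClassifierSpec = RESISTANCE_CLASSIFIER_SPEC,
                    config: MiniPatientConfig = MiniPatientConfig(),
                    decision_cutoff: float = 0.5,
                    test_patients=None,
                    probability_stub=None) -> CohortEvaluation:
    """Determination matrix over (patient, drug) pairs.

    ``leave_one_patient_out`` retrains per held-out patient on all other
    labeled patients; ``fixed_split`` trains once on all patients not in
    ``test_patients``. Pairs without both classes in the training pool are
    marked not evaluable and excluded from the accuracy denominator.
    ``probability_stub`` (callable (n, rng) -> probabilities) replaces the
    fitted classifier for null-harness checks.
    """
    drugs = list(drugs if drugs is not None else metadata.drugs)
    sample = metadata.table["sample_id"].to_numpy()
    patients = sorted(set(sample))
    if protocol == "leave_one_patient_out":
        eval_pairs = [(p, tuple(q for q in patients if q != p))
                      for p in patients]
    elif protocol == "fixed_split":
        if not test_patients:
            raise ValueError("fixed_split needs test_patients")
        train = tuple(p for p in patients if p not in set(test_patients))
        eval_pairs = [(p, train) for p in test_patients]
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    rows = []
    stub_rng = np.random.default_rng(config.seed + 1)
    for patient, train_patients in eval_pairs:
        pmask = sample == patient
        psub = spectra.select(pmask)
        for di, drug in enumerate(drugs):
            true = metadata.sample_label(patient, drug)
            labels = metadata.labels_for(drug).to_numpy()
            tmask = np.isin(sample, train_patients) & \
                np.isin(labels, (RESISTANT, SENSITIVE))
            classes = set(labels[tmask])
            row = {"patient": patient, "drug": drug,
                   "n_spectra": int(pmask.sum()), "cutoff": decision_cutoff,
                   "true_label": true}
            if len(classes) < 2:
                warnings.warn(
                    f"({patient}, {drug}): training pool has classes "
                    f"{classes}; not evaluable")
                row.update({"likelihood": np.nan, "label": "not_evaluable",
                            "evaluable": False, "correct": np.nan})
                rows.append(row)
                continue
            pair_tag = zlib.crc32(f"{patient}|{drug}".encode())
            cfg = replace(config, seed=int(
                (config.seed * 1009 + pair_tag) % (2**31 - 1)))
            if probability_stub is not None:
                probs = np.asarray(
                    probability_stub(int(pmask.sum()), stub_rng), dtype=float)
                likelihood, dist = patient_likelihood(probs, cfg)
                label = RESISTANT if likelihood > decision_cutoff \
                    else SENSITIVE
                call = PatientCall(patient, drug, likelihood, label,
                                   int(pmask.sum()), dist, decision_cutoff)
            else:
                model = train_resistance_model(
                    spectra, metadata, drug, spec=spec, config=cfg,
                    exclude_patients=(patient,))
                model.decision_cutoff = decision_cutoff
                call = determine_resistance(model, psub, patient)
            evaluable = true in (RESISTANT, SENSITIVE)
            row.update({"likelihood": call.likelihood, "label": call.label,
                        "evaluable": evaluable,
                        "correct": (call.label == true) if evaluable
                        else np.nan})
            rows.append(row)
    calls = pd.DataFrame(rows)
    ev = calls[calls["evaluable"] == True]  # noqa: E712
    accuracy = float(ev["correct"].mean()) if len(ev) else float("nan")
    per_drug = {d: float(g["correct"].mean())
                for d, g in ev.groupby("drug")}
    return CohortEvaluation(calls, accuracy, per_drug)
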