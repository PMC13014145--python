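import itertools

import numpy as np
import pandas as pd
import pytest

from ramanresist.resistance import (MiniPatientConfig, ResistanceModel,
                                    determine_resistance, evaluate_cohort,
                                    optimize_cutoffs, patient_likelihood,
                                    spectrum_probabilities,
                                    train_resistance_model)
from ramanresist.classify import ClassifierSpec
from ramanresist.preprocess import preprocess_spectra
from ramanresist.spectra_io import CohortMetadata, SpectraMatrix
from ramanresist.synthetic import (NoiseModel, PatientSpec, TreatmentEffect,
                                   melanoma_profile, synth_cohort)

FAST_SPEC = ClassifierSpec(n_trees=60, use_pca=False, max_depth=1,
                           max_features=100, max_samples=0.5, seed=0)


def exact_subset_likelihood(probs, subset_size, threshold=0.5):
    """Oracle: exact resistant-call probability by enumerating all ordered
    subsets drawn with replacement."""
    n = len(probs)
    hits = 0
    for combo in itertools.product(range(n), repeat=subset_size):
        if np.mean([probs[i] for i in combo]) > threshold:
            hits += 1
    return hits / n ** subset_size


@pytest.fixture(scope="module")
def small_cohort(coarse_grid):
    """4 patients, one drug, strong planted signature, preprocessed."""
    prof = melanoma_profile(cv=0.1)
    labels = {"P1": "resistant", "P2": "resistant",
              "P3": "sensitive", "P4": "sensitive"}
    patients = [PatientSpec(p, ((prof, 1.0),), {"dab": lab}, 60)
                for p, lab in labels.items()]
    effects = {"dab": TreatmentEffect("dab", {1003.0: 1.0, 1446.0: -1.0})}
    noise = NoiseModel(additive_noise_sd=0.02, baseline_poly_degree=2,
                       baseline_coeff_sd=0.02, spike_rate=0.0,
                       cell_scale_cv=0.1)
    spectra, meta, _ = synth_cohort(patients, ("untreated",), effects,
                                    noise, coarse_grid, seed=42)
    return preprocess_spectra(spectra), meta


class TestPatientLikelihood:
    def test_exact_enumeration_small_case(self):
        # (0.9, 0.9, 0.1), subsets of 3 with replacement, mean > 0.5:
        # of the 27 equally likely ordered triples, the 7 containing the
        # 0.1 spectrum at least twice have mean <= 0.5, so 20/27
        probs = [0.9, 0.9, 0.1]
        exact = exact_subset_likelihood(probs, 3)
        assert exact == pytest.approx(20 / 27, abs=1e-12)

    def test_monte_carlo_matches_enumeration(self):
        probs = np.array([0.9, 0.9, 0.1])
        exact = 20 / 27
        cfg = MiniPatientConfig(n_mini=25_000, subset_size=3, seed=5)
        lk, _ = patient_likelihood(probs, cfg)
        assert abs(lk - exact) <= 3 * np.sqrt(exact * (1 - exact) / 25_000)

    def test_all_certain_probabilities_give_unit_likelihood(self):
        lk, _ = patient_likelihood(np.ones(10), MiniPatientConfig(seed=1))
        assert lk == 1.0

    def test_subset_size_one_is_exact_fraction(self):
        probs = np.array([0.9, 0.6, 0.4, 0.2, 0.55])
        cfg = MiniPatientConfig(n_mini=100, subset_size=1, seed=2)
        lk, _ = patient_likelihood(probs, cfg)
        assert lk == pytest.approx(3 / 5, abs=1e-15)

    def test_monotone_in_probabilities_under_shared_subsets(self):
        rng = np.random.default_rng(7)
        p = rng.random(40)
        cfg = MiniPatientConfig(n_mini=2000, subset_size=10, seed=9)
        lo, _ = patient_likelihood(p, cfg)
        hi, _ = patient_likelihood(np.clip(p + 0.05, 0, 1), cfg)
        assert hi >= lo

    def test_without_replacement_subset_too_large_rejected(self):
        cfg = MiniPatientConfig(n_mini=10, subset_size=5,
                                sampling="without_replacement", seed=0)
        with pytest.raises(ValueError):
            patient_likelihood(np.array([0.5, 0.5]), cfg)


class TestOptimizeCutoffs:
    def test_plateau_tie_broken_toward_half(self):
        calls = {"dab": [(0.9, "resistant"), (0.8, "resistant"),
                         (0.2, "sensitive"), (0.3, "sensitive")]}
        assert optimize_cutoffs(calls)["dab"] == 0.5

    def test_inverted_labels_warns_and_caps_balanced_accuracy(self):
        calls = {"dab": [(0.1, "resistant"), (0.2, "resistant"),
                         (0.8, "sensitive"), (0.9, "sensitive")]}
        with pytest.warns(UserWarning, match="inverted"):
            out = optimize_cutoffs(calls)
        assert 0.0 <= out["dab"] <= 1.0

    def test_single_pair_perfectly_split(self):
        calls = {"dab": [(0.6, "resistant"), (0.4, "sensitive")]}
        assert optimize_cutoffs(calls)["dab"] == 0.5

    def test_single_class_keeps_default_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            out = optimize_cutoffs({"dab": [(0.9, "resistant")]})
        assert out["dab"] == 0.5


class TestResistanceModel:
    def test_training_and_probabilities_in_range(self, small_cohort):
        pre, meta = small_cohort
        model = train_resistance_model(pre, meta, "dab", spec=FAST_SPEC)
        probs = spectrum_probabilities(model, pre)
        assert probs.min() >= 0.0 and probs.max() <= 1.0
        assert model.training_patients == ("P1", "P2", "P3", "P4")

    def test_save_load_prediction_identical(self, small_cohort, tmp_path):
        pre, meta = small_cohort
        model = train_resistance_model(pre, meta, "dab", spec=FAST_SPEC)
        path = tmp_path / "model.joblib"
        model.save(path)
        back = ResistanceModel.load(path)
        np.testing.assert_allclose(spectrum_probabilities(model, pre),
                                   spectrum_probabilities(back, pre),
                                   atol=1e-12)

    def test_row_permutation_permutes_probabilities(self, small_cohort):
        pre, meta = small_cohort
        model = train_resistance_model(pre, meta, "dab", spec=FAST_SPEC)
        probs = spectrum_probabilities(model, pre)
        perm = np.random.default_rng(0).permutation(pre.n_cells)
        np.testing.assert_allclose(
            spectrum_probabilities(model, pre.select(perm)), probs[perm],
            atol=1e-15)

    def test_single_class_training_rejected(self, small_cohort):
        pre, meta = small_cohort
        with pytest.raises(ValueError, match="single class"):
            train_resistance_model(pre, meta, "dab", spec=FAST_SPEC,
                                   exclude_patients=("P3", "P4"))

    def test_holdout_exclusion_equals_training_without_patient(
            self, small_cohort):
        # leakage oracle: excluding P1 must equal training on a matrix that
        # never contained P1
        pre, meta = small_cohort
        excl = train_resistance_model(pre, meta, "dab", spec=FAST_SPEC,
                                      exclude_patients=("P1",))
        keep = meta.table["sample_id"].to_numpy() != "P1"
        sub = pre.select(keep)
        sub_meta = CohortMetadata(meta.table.loc[keep], meta.drugs)
        ref = train_resistance_model(sub, sub_meta, "dab", spec=FAST_SPEC)
        p1 = pre.select(~keep)
        np.testing.assert_allclose(spectrum_probabilities(excl, p1),
                                   spectrum_probabilities(ref, p1),
                                   atol=1e-12)


class TestDetermineResistance:
    def test_separable_patients_called_correctly(self, small_cohort):
        pre, meta = small_cohort
        sample = meta.table["sample_id"].to_numpy()
        cfg = MiniPatientConfig(n_mini=2000, subset_size=20, seed=3)
        model = train_resistance_model(pre, meta, "dab", spec=FAST_SPEC,
                                       config=cfg,
                                       exclude_patients=("P1", "P4"))
        res = determine_resistance(model, pre.select(sample == "P1"), "P1")
        sen = determine_resistance(model, pre.select(sample == "P4"), "P4")
        assert res.label == "resistant" and res.likelihood > 0.8
        assert sen.label == "sensitive" and sen.likelihood < 0.2

    def test_training_patient_requires_override(self, small_cohort):
        pre, meta = small_cohort
        model = train_resistance_model(pre, meta, "dab", spec=FAST_SPEC)
        sample = meta.table["sample_id"].to_numpy()
        with pytest.raises(ValueError, match="training set"):
            determine_resistance(model, pre.select(sample == "P1"), "P1")
        call = determine_resistance(model, pre.select(sample == "P1"), "P1",
                                    allow_training_patient=True)
        assert call.patient_id == "P1"

    def test_tie_at_cutoff_is_sensitive(self):
        from ramanresist.resistance import RESISTANT, PatientCall
        lk = 0.5
        label = RESISTANT if lk > 0.5 else "sensitive"
        call = PatientCall("P", "dab", lk, label, 10)
        assert call.label == "sensitive"


class TestEvaluateCohort:
    def test_separable_cohort_fully_recovered(self, small_cohort):
        pre, meta = small_cohort
        cfg = MiniPatientConfig(n_mini=2000, subset_size=20, seed=4)
        res = evaluate_cohort(pre, meta, spec=FAST_SPEC, config=cfg)
        assert res.accuracy == 1.0
        assert res.calls.shape[0] == 4

    def test_coin_flip_stub_scores_at_chance(self, small_cohort):
        pre, meta = small_cohort
        cfg = MiniPatientConfig(n_mini=500, subset_size=1, seed=8)
        accs = []
        for rep in range(40):
            res = evaluate_cohort(
                pre, meta, spec=FAST_SPEC,
                config=MiniPatientConfig(n_mini=500, subset_size=1,
                                         seed=rep),
                probability_stub=lambda n, rng: rng.random(n))
            accs.append(res.accuracy)
        mean_acc = np.mean(accs)
        # 160 coin-flip determinations in total
        assert abs(mean_acc - 0.5) < 2.576 * np.sqrt(0.25 / 160)

    def test_unknown_labels_not_evaluable(self, coarse_grid, small_cohort):
        pre, meta = small_cohort
        table = meta.table.copy()
        table.loc[table["sample_id"] == "P4", "dab"] = "unknown"
        meta2 = CohortMetadata(table, meta.drugs)
        cfg = MiniPatientConfig(n_mini=200, subset_size=10, seed=5)
        with pytest.warns(UserWarning, match="not evaluable"):
            res = evaluate_cohort(pre, meta2, spec=FAST_SPEC, config=cfg)
        row = res.calls[res.calls.patient == "P4"].iloc[0]
        assert not row.evaluable
        # holding out P3 leaves no labeled sensitive patient, so that pair
        # is not evaluable either
        row3 = res.calls[res.calls.patient == "P3"].iloc[0]
        assert row3.label == "not_evaluable"
        ev = res.calls[res.calls.evaluable]
        assert len(ev) == 2
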