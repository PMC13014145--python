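import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ramanresist.spectra_io import WavenumberGrid
from ramanresist.synthetic import (Band, NoiseModel, PatientSpec,
                                   PhenotypeProfile, TreatmentEffect,
                                   demo_cohort, melanoma_profile,
                                   synth_cohort, synth_spectrum,
                                   two_class_cohort, voigt_profile)

from conftest import single_band_profile


class TestVoigtProfile:
    _width = st.one_of(st.just(0.0), st.floats(0.05, 10.0))

    @given(center=st.floats(700, 1700), sigma=_width, gamma=_width,
           amp=st.floats(0.01, 100.0), d=st.floats(0.1, 50.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_peak_symmetry_and_decay_properties(self, center, sigma, gamma,
                                                amp, d):
        if sigma == 0.0 and gamma == 0.0:
            return
        x = np.array([center - d, center, center + d])
        v = voigt_profile(x, center, sigma, gamma, amp)
        assert v[1] == pytest.approx(amp, rel=1e-9)   # peak-normalized
        assert v[0] == pytest.approx(v[2], rel=1e-9)  # symmetric
        # decays off center (a pure-Gaussian far tail may underflow to 0)
        assert 0 <= v[0] < v[1]

    def test_gaussian_limit(self):
        x = np.array([0.0, 2.0, -2.0])
        v = voigt_profile(x, 0.0, sigma=2.0, gamma=0.0, amplitude=3.0)
        assert v[0] == pytest.approx(3.0, rel=1e-12)
        assert v[1] == pytest.approx(3.0 * np.exp(-0.5), rel=1e-9)

    def test_symmetry_about_center(self):
        d = np.linspace(0.1, 30, 40)
        left = voigt_profile(1003 - d, 1003, 2.0, 3.0)
        right = voigt_profile(1003 + d, 1003, 2.0, 3.0)
        np.testing.assert_allclose(left, right, rtol=1e-12)

    def test_matches_numerical_convolution(self):
        # independent oracle: quadrature of the Gaussian (x) Lorentzian
        # convolution integral, then peak-normalized
        sigma, gamma = 2.0, 2.0

        def conv(x):
            f = lambda t: (np.exp(-t * t / (2 * sigma ** 2))
                           * gamma / (gamma ** 2 + (x - t) ** 2))
            val, _ = quad(f, -np.inf, np.inf, limit=200)
            return val

        xs = np.array([0.0, 1.0, 3.0, 7.0, 15.0])
        oracle = np.array([conv(x) for x in xs])
        oracle /= oracle[0]
        mine = voigt_profile(xs, 0.0, sigma, gamma)
        np.testing.assert_allclose(mine, oracle, rtol=1e-6)

    def test_both_widths_zero_rejected(self):
        with pytest.raises(ValueError):
            voigt_profile(np.array([0.0]), 0.0, 0.0, 0.0)


class TestSynthSpectrum:
    def test_noiseless_single_band_peaks_at_center(self, grid):
        prof = single_band_profile(center=1003.0)
        rng = np.random.default_rng(0)
        spec = synth_spectrum(prof, None, NoiseModel.silent(), grid, rng)
        assert grid.values[np.argmax(spec)] == 1003.0

    def test_plus_one_log2_shift_doubles_band_exactly(self, grid):
        prof = single_band_profile(center=1003.0)
        rng = np.random.default_rng(0)
        base = synth_spectrum(prof, None, NoiseModel.silent(), grid, rng)
        shifted = synth_spectrum(
            prof, TreatmentEffect("d", {1003.0: 1.0}),
            NoiseModel.silent(), grid, rng)
        i = np.argmin(np.abs(grid.values - 1003))
        assert shifted[i] == pytest.approx(2.0 * base[i], rel=1e-12)

    def test_additive_noise_averages_to_template(self, coarse_grid):
        # mean over draws converges to the noiseless template when the
        # multiplicative jitters are off
        prof = single_band_profile(center=1003.0, cv=0.0)
        noise = NoiseModel(additive_noise_sd=0.05, baseline_poly_degree=0,
                           baseline_coeff_sd=0.0, spike_rate=0.0,
                           cell_scale_cv=0.0)
        rng = np.random.default_rng(1)
        draws = np.vstack([synth_spectrum(prof, None, noise, coarse_grid, rng)
                           for _ in range(1000)])
        template = prof.template(coarse_grid)
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        # clipping at 0 biases the mean upward where the template is ~0
        strong = template > 0.2
        resid = np.abs(draws.mean(axis=0)[strong] - template[strong])
        assert np.all(resid < 4 * se[strong])

    def test_median_unaffected_by_lognormal_jitter(self, coarse_grid):
        prof = single_band_profile(center=1003.0, cv=0.3)
        noise = NoiseModel.silent()
        rng = np.random.default_rng(2)
        draws = np.vstack([synth_spectrum(prof, None, noise, coarse_grid, rng)
                           for _ in range(2000)])
        i = np.argmin(np.abs(coarse_grid.values - 1003))
        assert np.median(draws[:, i]) == pytest.approx(1.0, rel=0.05)


class TestSynthCohort:
    def two_patients(self):
        prof = melanoma_profile()
        return [
            PatientSpec("P1", ((prof, 1.0),),
                        {"dabrafenib": "resistant"}, n_cells=100),
            PatientSpec("P2", ((prof, 1.0),),
                        {"dabrafenib": "sensitive"}, n_cells=100),
        ]

    def test_bookkeeping_and_determinism(self, coarse_grid):
        effects = {"dabrafenib": TreatmentEffect("dabrafenib", {780.0: 1.0})}
        a = synth_cohort(self.two_patients(), ("untreated",), effects,
                         NoiseModel(), coarse_grid, seed=5)
        b = synth_cohort(self.two_patients(), ("untreated",), effects,
                         NoiseModel(), coarse_grid, seed=5)
        assert a[0].n_cells == 200
        np.testing.assert_array_equal(a[0].intensities, b[0].intensities)
        assert a[1].sample_label("P1", "dabrafenib") == "resistant"

    def test_persister_scope_shifts_only_resistant_patients(self, coarse_grid):
        prof = single_band_profile(center=780.0, cv=0.0)
        patients = [
            PatientSpec("R", ((prof, 1.0),), {"d": "resistant"}, 10),
            PatientSpec("S", ((prof, 1.0),), {"d": "sensitive"}, 10)]
        effects = {"d": TreatmentEffect("d", {780.0: 1.0})}
        spectra, meta, _ = synth_cohort(patients, ("untreated", "d"),
                                        effects, NoiseModel.silent(),
                                        coarse_grid, seed=0)
        i = np.argmin(np.abs(coarse_grid.values - 780))
        res = spectra.intensities[meta.table["sample_id"] == "R", i]
        sen = spectra.intensities[meta.table["sample_id"] == "S", i]
        assert np.allclose(res, 2.0) and np.allclose(sen, 1.0)

    def test_treated_only_scope_restricts_to_treatment_arm(self, coarse_grid):
        prof = single_band_profile(center=780.0, cv=0.0)
        patients = [PatientSpec("R", ((prof, 1.0),), {"d": "resistant"}, 10)]
        effects = {"d": TreatmentEffect("d", {780.0: 1.0})}
        spectra, meta, _ = synth_cohort(patients, ("untreated", "d"),
                                        effects, NoiseModel.silent(),
                                        coarse_grid, seed=0,
                                        effect_scope="treated_only")
        i = np.argmin(np.abs(coarse_grid.values - 780))
        treated = meta.table["treatment"] == "d"
        assert np.allclose(spectra.intensities[treated.to_numpy(), i], 2.0)
        assert np.allclose(spectra.intensities[~treated.to_numpy(), i], 1.0)

    def test_mixture_fractions_within_binomial_ci(self, coarse_grid):
        p1 = melanoma_profile()
        p2 = single_band_profile(center=780.0)
        pat = PatientSpec("P", ((p1, 0.7), (p2, 0.3)), {}, n_cells=2000)
        _, _, truth = synth_cohort([pat], ("untreated",), {}, NoiseModel(),
                                   coarse_grid, seed=9)
        frac = np.mean(np.array(
            truth["patients"]["P"]["subpopulation_of_cell"]) == 0)
        ci = 2.576 * np.sqrt(0.7 * 0.3 / 2000)
        assert abs(frac - 0.7) < ci


class TestDemoCohort:
    def test_counts_labels_and_determinism(self):
        s1, m1, t1 = demo_cohort(seed=4, cells_scale=0.1)
        s2, m2, t2 = demo_cohort(seed=4, cells_scale=0.1)
        np.testing.assert_array_equal(s1.intensities, s2.intensities)
        assert len(t1["patients"]) == 9
        assert len(m1.drugs) == 5
        for pid, rec in t1["patients"].items():
            assert set(rec["labels"].values()) <= {"resistant", "sensitive"}

    def test_patient_cell_counts_within_study_bounds(self):
        _, _, truth = demo_cohort(seed=11, cells_scale=1.0, )
        counts = [rec["n_cells"] for rec in truth["patients"].values()]
        assert min(counts) >= 96 and max(counts) <= 1512

    def test_two_class_cohort_shapes(self):
        spectra, y, truth = two_class_cohort(n_per_class=20, seed=0)
        assert spectra.n_cells == 40
        assert (y == "shifted").sum() == 20
        assert truth["band_center"] == 1003.0
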