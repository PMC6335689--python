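import numpy as np
import pytest

import hepregen as h
from hepregen.calibration import HEIGHT_M_BY_SEX


class TestAllometricScaling:
    def test_body_mass_arithmetic(self):
        assert h.body_mass_from_bmi(22.0, 1.72) == pytest.approx(65084.8)
        assert h.body_mass_from_bmi(22.0, 1.58) == pytest.approx(54920.8)
        assert h.body_mass_from_bmi(22.0, 1.0) == pytest.approx(22000.0)
        with pytest.raises(ValueError):
            h.body_mass_from_bmi(-1.0, 1.7)

    def test_metabolic_load_forms(self):
        # exponent base: unit mass returns the prefactor
        assert h.metabolic_load_young(1.0) == pytest.approx(23.409)
        assert h.metabolic_load_cook(1.0) == pytest.approx(47.315)
        # frozen scalar evaluations at a 70 kg adult
        assert h.metabolic_load_young(70000.0) == pytest.approx(6.2755, abs=2e-3)
        assert h.metabolic_load_cook(70000.0) == pytest.approx(6.1769, abs=2e-3)
        assert h.COOK_HUMAN_K_G == 6.5675e-4

    def test_load_decreasing_in_mass_and_forms_agree(self):
        masses = np.linspace(50000.0, 80000.0, 31)
        young = np.array([h.metabolic_load_young(m) for m in masses])
        cook = np.array([h.metabolic_load_cook(m) for m in masses])
        assert np.all(np.diff(young) < 0)
        assert np.max(np.abs(young - cook) / young) < 0.10

    def test_series_body_mass_uses_sex_average_height(self):
        s = h.PatientSeries(
            times=np.array([30.0, 400.0, 900.0]),
            volume_fraction=np.array([0.5, 0.8, 0.95]),
            resection_fraction=0.5,
            bmi=22.0,
            sex="F",
        )
        assert s.body_mass_g() == pytest.approx(
            1000 * 22.0 * HEIGHT_M_BY_SEX["F"] ** 2
        )


class TestResidualError:
    def test_self_consistency_on_noiseless_series(self, ref):
        s = h.generate_patient_series(ref, 0.5, np.geomspace(14, 900, 6), noise_sd=0.0)
        assert h.residual_error(ref, s) < 1e-8

    def test_quadratic_response_to_single_outlier(self, ref):
        s = h.generate_patient_series(ref, 0.5, np.geomspace(14, 900, 6), noise_sd=0.0)
        bumped = h.PatientSeries(
            times=s.times,
            volume_fraction=s.volume_fraction + np.array([0, 0, 0.1, 0, 0, 0]),
            resection_fraction=s.resection_fraction,
        )
        assert h.residual_error(ref, bumped) == pytest.approx(0.01, abs=1e-6)

    def test_failed_simulation_returns_sentinel(self, ref):
        s = h.PatientSeries(
            times=np.array([10.0, 100.0, 800.0]),
            volume_fraction=np.array([0.5, 0.6, 0.9]),
            resection_fraction=0.5,
        )
        crazy = ref.replace(V_JAK=1e308)
        assert h.residual_error(crazy, s) >= 1e5


@pytest.fixture(scope="module")
def noisy_series(ref):
    return h.generate_patient_series(
        ref, 0.6, np.geomspace(14, 912.5, 6), noise_sd=0.05, seed=42
    )


class TestFitParameters:
    def test_noiseless_round_trip_recovers_identifiable_parameters(self, ref):
        """Truth jittered in (M, k_G); an unpenalized fit from the reference
        recovers both within 10%."""
        truth = ref.replace(M=ref.M * 1.6, k_G=ref.k_G * 0.6)
        s = h.generate_patient_series(truth, 0.6, np.geomspace(14, 912.5, 7), noise_sd=0.0)
        fr = h.fit_parameters(
            s, ref, free=("M", "k_G", "beta_ap"), lam=0.0,
            n_starts=1, n_screen=0, max_nfev=60,
        )
        assert fr.params.M == pytest.approx(truth.M, rel=0.10)
        assert fr.params.k_G == pytest.approx(truth.k_G, rel=0.10)
        assert fr.sse < 1e-4

    def test_huge_penalty_returns_initial_vector(self, ref, noisy_series):
        fr = h.fit_parameters(
            noisy_series, ref, free=("M", "k_G", "beta_ap"), lam=1e6,
            n_starts=1, n_screen=0, max_nfev=20,
        )
        for factor in fr.scale_factors.values():
            assert factor == pytest.approx(1.0, abs=1e-3)

    def test_unpenalized_fit_reaches_lower_sse(self, ref, noisy_series):
        kw = dict(free=("M", "k_G", "beta_ap"), n_starts=1, n_screen=0, max_nfev=40)
        free_fit = h.fit_parameters(noisy_series, ref, lam=0.0, **kw)
        penalized = h.fit_parameters(noisy_series, ref, lam=1e-3, **kw)
        assert free_fit.sse <= penalized.sse + 1e-9

    def test_multiparameter_fit_beats_load_only_scaling(self, ref, noisy_series):
        """Nested-model property: freeing the significant subset can only
        improve on adjusting the metabolic load alone."""
        kw = dict(lam=0.0, n_starts=1, n_screen=0, max_nfev=40)
        m_only = h.fit_parameters(noisy_series, ref, free=("M",), **kw)
        multi = h.fit_parameters(
            noisy_series, ref, free=h.SIGNIFICANT_PARAMS, **kw
        )
        assert multi.sse <= m_only.sse + 1e-9

    def test_bounds_must_contain_init(self, ref, noisy_series):
        with pytest.raises(ValueError):
            h.fit_parameters(
                noisy_series, ref, free=("M",), bounds={"M": (ref.M * 2, ref.M * 4)}
            )

    def test_rat_init_rescales_load_downward(self, rat, ref):
        """Species translation direction: fitting human-timescale series from
        the rodent baseline pulls the metabolic load down (the robustly
        identifiable direction) and leaves the apoptosis midpoint no lower."""
        rng = np.random.default_rng(9)
        down = 0
        n_rep = 3
        for i in range(n_rep):
            s = h.generate_patient_series(
                ref, float(rng.uniform(0.4, 0.7)), np.geomspace(14, 912.5, 6),
                noise_sd=0.05, seed=int(rng.integers(2**31)),
            )
            fr = h.fit_parameters(
                s, rat, free=h.SIGNIFICANT_PARAMS, n_starts=2, n_screen=8,
                seed=i, max_nfev=40,
            )
            if fr.params.M < rat.M:
                down += 1
            assert fr.params.theta_ap >= rat.theta_ap * 0.999
        assert down == n_rep
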