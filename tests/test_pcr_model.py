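"""The Bayesian logistic pCR model: predictors, oracle likelihood, sampler."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.special import expit

from platformtrial import time_machine as tm
from platformtrial.pcr_model import (
    ModelConfig,
    ModelParams,
    _derive_rates,
    _Prepared,
    ftv_log_ratio,
    impute_pending,
    linear_predictor,
    log_posterior,
    sample_posterior,
)
from platformtrial.trial_data import evaluability_filter

CFG = tm.TimeMachineConfig()
ANALYSIS_DAY = 1000


def example_params(n_bins=11, seed=0):
    rng = np.random.default_rng(seed)
    free = CFG.free_recent_bins
    dm = np.r_[np.zeros(free), rng.normal(0, 0.2, n_bins - free)]
    dp = np.r_[np.zeros(free), rng.normal(0, 0.2, n_bins - free)]
    return ModelParams(
        baseline=rng.normal(0, 0.5, 4),
        arm_effects={"experimental": rng.normal(0, 0.5, 4)},
        delta_minus=tm.DeltaField(False, dm, 0.004, free),
        delta_plus=tm.DeltaField(True, dp, 0.004, free),
        tau_sq=0.004,
        impute=rng.normal(0, 0.5, 2),
    )


class TestLinearPredictor:
    def test_zero_params_give_even_odds(self, make_patient):
        params = example_params()
        params.baseline[:] = 0
        params.arm_effects["experimental"][:] = 0
        params.delta_minus.delta[:] = 0
        params.delta_plus.delta[:] = 0
        p = make_patient(rand_day=900, arm_id="experimental", hr=True)
        eta = linear_predictor(params, p, ANALYSIS_DAY)
        assert eta == 0.0
        assert expit(eta) == 0.5

    def test_recent_control_patient_has_no_offset(self, make_patient):
        params = example_params()
        p = make_patient(rand_day=ANALYSIS_DAY - 200, hr=True, mp2=True)
        x = np.array([1.0, 1.0, 0.0, 1.0])
        assert linear_predictor(params, p, ANALYSIS_DAY) == pytest.approx(
            float(x @ params.baseline)
        )

    def test_arm_contrast_is_pure_treatment_effect(self, make_patient):
        params = example_params()
        shared = dict(rand_day=300, hr=True, her2=False, mp2=True)
        ctl = make_patient(arm_id="control", **shared)
        exp = make_patient(arm_id="experimental", **shared)
        diff = linear_predictor(params, exp, ANALYSIS_DAY) - linear_predictor(
            params, ctl, ANALYSIS_DAY
        )
        x = np.array([1.0, 1.0, 0.0, 1.0])
        assert diff == pytest.approx(float(x @ params.arm_effects["experimental"]))

    def test_her2_stratum_selects_delta_field(self, make_patient):
        params = example_params()
        neg = make_patient(rand_day=300, her2=False)
        pos = make_patient(rand_day=300, her2=True)
        t = tm.bin_index(ANALYSIS_DAY - 300, CFG)
        base_neg = linear_predictor(params, neg, ANALYSIS_DAY)
        base_pos = linear_predictor(params, pos, ANALYSIS_DAY)
        x_neg = np.array([1.0, 0, 0, 0])
        x_pos = np.array([1.0, 0, 1.0, 0])
        assert base_neg - float(x_neg @ params.baseline) == pytest.approx(
            params.delta_minus.value(t))
        assert base_pos - float(x_pos @ params.baseline) == pytest.approx(
            params.delta_plus.value(t))


class TestLogPosteriorOracle:
    def test_matches_brute_force_on_twelve_patients(
        self, twelve_patient_fixture, arms
    ):
        from _oracles import brute_force_log_posterior

        model_cfg = ModelConfig()
        params = example_params()
        got = log_posterior(
            params, twelve_patient_fixture, arms, ANALYSIS_DAY, CFG, model_cfg
        )
        want = brute_force_log_posterior(
            params, twelve_patient_fixture, ANALYSIS_DAY, CFG, model_cfg
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_label_symmetry(self, twelve_patient_fixture, arms):
        """Flipping all outcomes and negating all location parameters leaves
        the log-posterior invariant."""
        model_cfg = ModelConfig()
        params = example_params()
        flipped_pats = [
            p if p.pcr is None else replace(p, pcr=1 - p.pcr)
            for p in twelve_patient_fixture
        ]
        neg = ModelParams(
            baseline=-params.baseline,
            arm_effects={k: -v for k, v in params.arm_effects.items()},
            delta_minus=tm.DeltaField(
                False, -params.delta_minus.delta, params.tau_sq),
            delta_plus=tm.DeltaField(True, -params.delta_plus.delta, params.tau_sq),
            tau_sq=params.tau_sq,
            impute=-params.impute,
        )
        a = log_posterior(params, twelve_patient_fixture, arms, ANALYSIS_DAY,
                          CFG, model_cfg)
        b = log_posterior(neg, flipped_pats, arms, ANALYSIS_DAY, CFG, model_cfg)
        assert a == pytest.approx(b, abs=1e-9)


class TestImputation:
    def test_log_ratio_requires_post_baseline_scan(self, make_patient):
        assert ftv_log_ratio(make_patient(ftv=((0, 10.0),))) is None
        assert ftv_log_ratio(
            make_patient(ftv=((0, 10.0), (84, 5.0)))
        ) == pytest.approx(math.log(0.5))

    def test_zero_volume_floored_with_warning(self, make_patient):
        p = make_patient(ftv=((0, 10.0), (84, 0.0)))
        with pytest.warns(UserWarning, match="floored"):
            lr = ftv_log_ratio(p)
        assert np.isfinite(lr) and lr < -10

    def test_null_submodel_reduces_to_model_rate(self, make_patient, rng):
        params = example_params()
        params.impute[:] = 0.0
        p = make_patient(rand_day=900, pcr=None, ftv=((900, 20.0), (984, 5.0)))
        eta = linear_predictor(params, p, ANALYSIS_DAY)
        draws = [
            impute_pending(params, p, ANALYSIS_DAY, rng) for _ in range(4000)
        ]
        assert np.mean(draws) == pytest.approx(expit(eta), abs=0.03)

    def test_shrunk_tumor_raises_imputed_probability(self, make_patient, rng):
        params = example_params()
        params.impute[:] = (0.0, -1.5)  # negative link: shrinkage ~ response
        shrunk = make_patient(rand_day=900, pcr=None, ftv=((900, 30.0), (984, 1.0)))
        stable = make_patient(rand_day=900, pcr=None, ftv=((900, 30.0), (984, 29.0)))
        eta = linear_predictor(params, shrunk, ANALYSIS_DAY)
        freq_shrunk = np.mean([
            impute_pending(params, shrunk, ANALYSIS_DAY, rng, z_stats=(0.0, 1.0))
            for _ in range(3000)
        ])
        freq_stable = np.mean([
            impute_pending(params, stable, ANALYSIS_DAY, rng, z_stats=(0.0, 1.0))
            for _ in range(3000)
        ])
        assert freq_shrunk > expit(eta) > freq_stable


class TestSampler:
    def test_no_data_returns_prior(self, arms):
        draws = sample_posterior([], arms, 100,
                                 model_cfg=ModelConfig(n_draws=1500), seed=4)
        assert draws.diagnostics["status"] == "prior"
        g = draws.arm_effects["experimental"][:, 0]
        assert abs(g.mean()) < 0.25
        assert 1.7 < g.std() < 2.3

    def test_seed_determinism(self, twelve_patient_fixture, arms):
        mc = ModelConfig(n_warmup=50, n_draws=50)
        a = sample_posterior(twelve_patient_fixture, arms, ANALYSIS_DAY,
                             model_cfg=mc, seed=9)
        b = sample_posterior(twelve_patient_fixture, arms, ANALYSIS_DAY,
                             model_cfg=mc, seed=9)
        assert np.array_equal(a.baseline, b.baseline)
        assert np.array_equal(a.tau_sq, b.tau_sq)
        for k in a.rates:
            assert np.array_equal(a.rates[k], b.rates[k], equal_nan=True)

    def test_recent_delta_draws_are_exactly_zero(self, twelve_patient_fixture, arms):
        mc = ModelConfig(n_warmup=50, n_draws=50)
        d = sample_posterior(twelve_patient_fixture, arms, ANALYSIS_DAY,
                             model_cfg=mc, seed=9)
        assert np.all(d.delta_minus[:, :4] == 0.0)
        assert np.all(d.delta_plus[:, :4] == 0.0)

    def test_imputation_slope_recovered_from_simulated_ftv(self):
        """At an interim with pending surgeries, the posterior for the FTV
        slope must find the negative shrinkage-response link the generator
        planted."""
        from platformtrial.synthetic_trial import scenario_presets, simulate_trial

        sc = scenario_presets()["ganetespib_like"]
        sc.seed = 31
        patients, _ = simulate_trial(sc)
        evaluable, audit = evaluability_filter(patients)
        draws = sample_posterior(
            evaluable, sc.arms, analysis_day=400,
            model_cfg=ModelConfig(n_warmup=300, n_draws=600), seed=17,
        )
        w1 = draws.impute[:, 1]
        assert w1.mean() < -0.3
        assert np.quantile(w1, 0.95) < 0.0


class TestDerivedRates:
    def _stub_prep(self, patients, arms):
        return _Prepared(patients, arms, ANALYSIS_DAY, CFG, ModelConfig())

    def test_rates_invariant_to_patient_order(self, twelve_patient_fixture, arms, rng):
        from platformtrial.trial_data import default_signature_catalogue

        sigs = default_signature_catalogue()
        S = 40
        baseline = rng.normal(0, 0.5, (S, 4))
        gammas = {"experimental": rng.normal(0, 0.5, (S, 4))}
        fwd = _derive_rates(self._stub_prep(twelve_patient_fixture, arms),
                            sigs, baseline, gammas)
        shuffled = list(twelve_patient_fixture)
        rng.shuffle(shuffled)
        rev = _derive_rates(self._stub_prep(shuffled, arms), sigs, baseline, gammas)
        for key in fwd:
            assert np.allclose(fwd[key], rev[key], atol=1e-12, equal_nan=True)

    def test_rates_lie_in_unit_interval(self, twelve_patient_fixture, arms):
        mc = ModelConfig(n_warmup=100, n_draws=100)
        d = sample_posterior(twelve_patient_fixture, arms, ANALYSIS_DAY,
                             model_cfg=mc, seed=2)
        for key, r in d.rates.items():
            r = r[~np.isnan(r)]
            assert np.all((r > 0) & (r < 1))
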