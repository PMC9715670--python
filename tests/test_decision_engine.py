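"""Superiority, phase-3 predictive probability, randomization, decisions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platformtrial.decision_engine import (
    DecisionConfig,
    evaluate_arm,
    phase3_power,
    pred_prob_phase3,
    prob_superiority,
    randomization_probs,
)
from platformtrial.pcr_model import PosteriorDraws
from platformtrial.trial_data import ALL_SUBTYPES, ArmSpec, Subtype

CFG = DecisionConfig()


def stub_draws(rate_pairs):
    """PosteriorDraws with only the rate dictionary populated.

    ``rate_pairs`` maps signature -> (arm draws, control draws).
    """
    rates = {}
    for sig, (pe, pc) in rate_pairs.items():
        rates[("experimental", sig)] = np.asarray(pe, dtype=float)
        rates[("control", sig)] = np.asarray(pc, dtype=float)
    S = len(next(iter(rates.values())))
    return PosteriorDraws(
        baseline=np.zeros((S, 4)),
        arm_effects={"experimental": np.zeros((S, 4))},
        delta_minus=np.zeros((S, 5)),
        delta_plus=np.zeros((S, 5)),
        tau_sq=np.full((S, 2), 0.001),
        impute=np.zeros((S, 2)),
        rates=rates,
        control_arm_id="control",
        signature_names=list(rate_pairs),
        diagnostics={"status": "ok"},
    )


class TestProbSuperiority:
    def test_strict_dominance(self):
        d = stub_draws({"all": ([0.3, 0.4], [0.2, 0.2])})
        assert prob_superiority(d, "experimental", "all") == 1.0

    def test_half_dominance(self):
        d = stub_draws({"all": ([0.1, 0.3], [0.2, 0.2])})
        assert prob_superiority(d, "experimental", "all") == 0.5

    def test_symmetric_distributions_give_half(self, rng):
        pe = rng.beta(4, 10, 4000)
        pc = rng.beta(4, 10, 4000)
        d = stub_draws({"all": (pe, pc)})
        assert prob_superiority(d, "experimental", "all") == pytest.approx(0.5, abs=0.03)

    def test_superiority_inferiority_tie_partition(self, rng):
        pe = np.round(rng.beta(4, 10, 2000), 2)
        pc = np.round(rng.beta(4, 10, 2000), 2)
        d = stub_draws({"all": (pe, pc)})
        sup = prob_superiority(d, "experimental", "all")
        inf = float(np.mean(pc > pe))
        tie = float(np.mean(pe == pc))
        assert sup + inf + tie == pytest.approx(1.0, abs=1e-12)


class TestPhase3:
    def test_null_rates_give_alpha(self):
        p = phase3_power(np.array([0.2]), np.array([0.2]), 150, 0.025)
        assert p[0] == pytest.approx(0.025, abs=0.005)

    def test_overwhelming_effect_gives_one(self):
        p = phase3_power(np.array([0.5]), np.array([0.1]), 150, 0.025)
        assert p[0] == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_rates_no_nan(self):
        p = phase3_power(np.array([0.0, 1.0, 1.0]), np.array([0.0, 1.0, 0.0]),
                         150, 0.025)
        assert np.all(np.isfinite(p))
        assert p[0] == pytest.approx(0.0, abs=1e-12)  # both arms all failures
        assert p[1] == pytest.approx(0.0, abs=1e-12)  # identical perfect arms
        assert p[2] == pytest.approx(1.0, abs=1e-9)   # 1.0 vs 0.0

    def test_z_statistic_matches_statsmodels_cells(self, rng):
        """Spot-check the rejection grid against the standard pooled
        two-proportion z-test implementation."""
        from statsmodels.stats.proportion import proportions_ztest

        from platformtrial.decision_engine import _reject_matrix

        n = 60
        R = _reject_matrix(n, 0.025)
        from scipy.stats import norm as snorm

        crit = snorm.ppf(0.975)
        for _ in range(30):
            xe, xc = rng.integers(0, n + 1, 2)
            if xe + xc in (0, 2 * n):
                continue
            z, _ = proportions_ztest([xe, xc], [n, n], alternative="larger")
            assert R[xe, xc] == float(z > crit)

    def test_pred_prob_is_posterior_average(self):
        d = stub_draws({"all": ([0.5, 0.2], [0.1, 0.2])})
        got = pred_prob_phase3(d, "experimental", "all", CFG)
        want = 0.5 * (
            phase3_power(np.array([0.5]), np.array([0.1]), 150, 0.025)[0]
            + phase3_power(np.array([0.2]), np.array([0.2]), 150, 0.025)[0]
        )
        assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_in_effect_size(self, rng):
        pc = rng.beta(5, 20, 300)
        base = np.clip(pc + 0.05, 0, 1)
        better = np.clip(pc + 0.15, 0, 1)
        d1 = stub_draws({"all": (base, pc)})
        d2 = stub_draws({"all": (better, pc)})
        assert pred_prob_phase3(d2, "experimental", "all", CFG) > pred_prob_phase3(
            d1, "experimental", "all", CFG
        )


class TestRandomization:
    def _arms(self, *exp_specs):
        arms = [ArmSpec("control", is_control=True)]
        for arm_id, subtypes in exp_specs:
            arms.append(
                ArmSpec(arm_id, is_control=False,
                        eligible_subtypes=frozenset(subtypes))
            )
        return arms

    def test_single_arm_gets_eighty_percent(self):
        arms = self._arms(("exp", ALL_SUBTYPES))
        for w in (0.1, 0.5, 0.99):
            probs = randomization_probs({"exp": w}, ALL_SUBTYPES[0], arms, CFG)
            assert probs == {"control": pytest.approx(0.2),
                             "exp": pytest.approx(0.8)}

    def test_two_arm_arithmetic(self):
        arms = self._arms(("a", ALL_SUBTYPES), ("b", ALL_SUBTYPES))
        probs = randomization_probs({"a": 0.6, "b": 0.3}, ALL_SUBTYPES[0], arms, CFG)
        assert probs["control"] == pytest.approx(0.2)
        assert probs["a"] == pytest.approx(0.8 * 0.6 / 0.9)
        assert probs["b"] == pytest.approx(0.8 * 0.3 / 0.9)

    def test_ineligible_subtype_goes_all_control(self):
        her2neg = frozenset(s for s in ALL_SUBTYPES if not s.her2)
        arms = self._arms(("ganetespib", her2neg))
        her2pos = Subtype(hr=False, her2=True, mp2=False)
        probs = randomization_probs({"ganetespib": 0.9}, her2pos, arms, CFG)
        assert probs == {"control": 1.0}

    def test_weight_floor_keeps_arms_alive(self):
        arms = self._arms(("a", ALL_SUBTYPES), ("b", ALL_SUBTYPES))
        probs = randomization_probs({"a": 0.0, "b": 0.8}, ALL_SUBTYPES[0], arms, CFG)
        assert probs["a"] > 0.0
        assert probs["a"] == pytest.approx(0.8 * 0.01 / 0.81)

    @given(
        ws=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=5),
    )
    @settings(max_examples=60, deadline=None)
    def test_sums_to_one_and_order_invariant(self, ws):
        exp_specs = [(f"arm{i}", ALL_SUBTYPES) for i in range(len(ws))]
        arms = self._arms(*exp_specs)
        weights = {f"arm{i}": w for i, w in enumerate(ws)}
        probs = randomization_probs(weights, ALL_SUBTYPES[0], arms, CFG)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        rev = randomization_probs(weights, ALL_SUBTYPES[0],
                                  [arms[0]] + list(reversed(arms[1:])), CFG)
        assert {k: pytest.approx(v) for k, v in rev.items()} == probs


class TestEvaluateArm:
    def test_graduation_fires_on_any_signature(self):
        action, grads = evaluate_arm({"TN": 0.90, "HER2-": 0.40}, 50, 115, CFG)
        assert action == "graduate"
        assert grads == ["TN"]

    def test_published_probabilities_do_not_graduate(self):
        """The published predictive probabilities (0.47/0.72/0.19) with the
        arm at its accrual cap stop for max accrual, not graduation."""
        pred = {"HER2-": 0.47, "HR-/HER2-": 0.72, "HR+/HER2-": 0.19}
        action, grads = evaluate_arm(pred, 115, 115, CFG)
        assert action == "max_accrual_reached"
        assert grads == []

    def test_all_below_ten_percent_is_futile(self):
        pred = {"HER2-": 0.05, "HR-/HER2-": 0.04, "HR+/HER2-": 0.09}
        action, _ = evaluate_arm(pred, 40, 115, CFG)
        assert action == "futile"

    def test_continue_otherwise(self):
        action, _ = evaluate_arm({"TN": 0.5}, 40, 115, CFG)
        assert action == "continue"

    def test_precedence_graduate_over_cap(self):
        action, grads = evaluate_arm({"TN": 0.9}, 115, 115, CFG)
        assert action == "graduate" and grads == ["TN"]

    def test_min_signature_enrollment_gate(self):
        cfg = DecisionConfig(min_signature_n=20)
        action, _ = evaluate_arm({"TN": 0.9}, 10, 115, cfg, signature_n={"TN": 10})
        assert action == "continue"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            DecisionConfig(graduation_threshold=0.05, futility_threshold=0.10)
        with pytest.raises(ValueError):
            DecisionConfig(phase3_n=301)
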