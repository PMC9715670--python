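"""Calendar-bin arithmetic and the second-order NDLM drift prior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platformtrial.time_machine import (
    DeltaField,
    TimeMachineConfig,
    bin_index,
    ndlm_prior,
    offset_for,
    sample_ndlm_forward,
    sample_tau_sq,
    second_differences,
)

CFG = TimeMachineConfig()


class TestBinIndex:
    @pytest.mark.parametrize(
        "days,expected",
        [(750, 9), (0, 1), (1, 1), (90, 1), (91, 2), (180, 2), (181, 3)],
    )
    def test_worked_examples_and_boundaries(self, days, expected):
        assert bin_index(days, CFG) == expected

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            bin_index(-1, CFG)

    @given(days=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=200, deadline=None)
    def test_bin_contains_its_day(self, days):
        t = bin_index(days, CFG)
        assert t >= 1
        assert CFG.bin_width * (t - 1) < max(days, 1) <= CFG.bin_width * t


class TestNdlmPrior:
    def test_level_anchor_marginal(self):
        prior = ndlm_prior(5, tau_sq=0.01, cfg=CFG)
        assert prior.dim == 1
        assert prior.mean[0] == pytest.approx(0.0)
        assert prior.covariance()[0, 0] == pytest.approx(CFG.tau0_sq)

    def test_slope_anchor_adds_independent_variance(self):
        prior = ndlm_prior(6, tau_sq=0.01, cfg=CFG)
        cov = prior.covariance()
        assert cov[1, 1] == pytest.approx(CFG.tau0_sq + CFG.tau1_sq)

    def test_degenerate_no_free_bins(self):
        assert ndlm_prior(4, 0.01, CFG).dim == 0
        assert ndlm_prior(2, 0.01, CFG).dim == 0

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            ndlm_prior(9, 0.0, CFG)

    def test_covariance_matches_forward_simulation_oracle(self, rng):
        """Banded precision vs a Monte-Carlo simulation of the recursion."""
        n_draws = 100_000
        sims = sample_ndlm_forward(9, 0.01, CFG, rng, size=n_draws)
        emp = np.cov(sims.T)
        exact = ndlm_prior(9, 0.01, CFG).covariance()
        # 3-sigma elementwise MC tolerance for a sample covariance.
        tol = 3 * np.sqrt(
            (np.outer(np.diag(exact), np.diag(exact)) + exact**2) / n_draws
        )
        assert np.all(np.abs(emp - exact) < tol)

    def test_logpdf_matches_increment_decomposition(self, rng):
        """The banded-Cholesky density equals the product of the stated
        increment densities (unit-Jacobian transform)."""
        from scipy.stats import norm as snorm

        prior = ndlm_prior(10, 0.004, CFG)
        x = rng.normal(0, 0.05, prior.dim)
        lp_inc = snorm.logpdf(x[0], CFG.mu0, np.sqrt(CFG.tau0_sq))
        lp_inc += snorm.logpdf(x[1] - x[0], CFG.mu1, np.sqrt(CFG.tau1_sq))
        for j in range(2, prior.dim):
            lp_inc += snorm.logpdf(x[j] - 2 * x[j - 1] + x[j - 2], 0, np.sqrt(0.004))
        assert prior.logpdf(x) == pytest.approx(lp_inc, abs=1e-10)

    def test_variance_grows_into_the_past(self):
        cov = ndlm_prior(12, 0.01, CFG).covariance()
        v = np.diag(cov)
        assert np.all(np.diff(v) > 0)

    def test_tight_anchors_pin_level_and_slope(self):
        tight = TimeMachineConfig(tau0_sq=1e-12, tau1_sq=1e-12)
        cov = ndlm_prior(8, 0.01, tight).covariance()
        assert cov[0, 0] < 1e-11
        assert cov[1, 1] < 1e-10

    def test_posterior_matches_kalman_smoother(self, rng):
        """Linear-Gaussian update equivalence: banded-precision posterior vs
        an independently coded Kalman filter + RTS smoother on the
        local-linear state space."""
        n_bins, tau_sq = 11, 0.02
        m = n_bins - CFG.free_recent_bins
        obs_sd = 0.3
        y = rng.normal(0.1, 0.2, m)

        prior = ndlm_prior(n_bins, tau_sq, CFG)
        obs_prec = np.full(m, 1 / obs_sd**2)
        mean_b, cov_b = prior.posterior(obs_prec, obs_prec * y)

        # State (level, slope): x_{t+1} = F x_t + (0, w), w ~ N(0, tau_sq).
        F = np.array([[1.0, 1.0], [0.0, 1.0]])
        Q = np.array([[0.0, 0.0], [0.0, tau_sq]])
        H = np.array([[1.0, 0.0]])
        mu = np.array([CFG.mu0, CFG.mu1])
        P = np.diag([CFG.tau0_sq, CFG.tau1_sq])
        means_f, covs_f, means_p, covs_p = [], [], [], []
        for t in range(m):
            if t > 0:
                mu, P = F @ mu, F @ P @ F.T + Q
            means_p.append(mu.copy()); covs_p.append(P.copy())
            S = H @ P @ H.T + obs_sd**2
            K = P @ H.T / S
            mu = mu + (K * (y[t] - H @ mu)).ravel()
            P = P - K @ H @ P
            means_f.append(mu.copy()); covs_f.append(P.copy())
        mean_s = [None] * m
        cov_s = [None] * m
        mean_s[-1], cov_s[-1] = means_f[-1], covs_f[-1]
        for t in range(m - 2, -1, -1):
            G = covs_f[t] @ F.T @ np.linalg.inv(covs_p[t + 1])
            mean_s[t] = means_f[t] + G @ (mean_s[t + 1] - means_p[t + 1])
            cov_s[t] = covs_f[t] + G @ (cov_s[t + 1] - covs_p[t + 1]) @ G.T

        kal_mean = np.array([ms[0] for ms in mean_s])
        kal_var = np.array([cs[0, 0] for cs in cov_s])
        assert np.allclose(mean_b, kal_mean, atol=1e-9)
        assert np.allclose(np.diag(cov_b), kal_var, atol=1e-9)


class TestTauSquared:
    def _field(self, free_values):
        free = CFG.free_recent_bins
        return DeltaField(False, np.r_[np.zeros(free), free_values], 0.01, free)

    def test_conjugate_update_zero_sum_of_squares(self, rng):
        # Linear free offsets => all second differences zero; k = 4.
        field = self._field(np.linspace(0.0, 0.5, 6))
        assert second_differences(field) == pytest.approx(np.zeros(4), abs=1e-12)
        draws = np.array([sample_tau_sq(field, CFG, rng) for _ in range(100_000)])
        # IG(alpha + 2, beta) = IG(3, 0.001): mean beta/(shape-1) = 0.0005.
        assert np.mean(draws) == pytest.approx(0.0005, rel=0.05)

    def test_no_second_difference_gives_prior_draw(self, rng):
        field = self._field(np.array([0.1, 0.2]))
        draws = np.array([sample_tau_sq(field, CFG, rng) for _ in range(50_000)])
        # Prior IG(1, 0.001) has no finite mean; check the median instead:
        # median = beta / gamma-median(1) = 0.001 / ln 2.
        assert np.median(draws) == pytest.approx(0.001 / np.log(2), rel=0.05)

    def test_conjugate_update_matches_closed_form_mean(self, rng):
        # Free offsets with k = 2 and sum of squared second diffs 0.02.
        field = self._field(np.array([0.0, 0.0, 0.1, 0.1]))
        d = second_differences(field)
        assert d @ d == pytest.approx(0.02)
        draws = np.array([sample_tau_sq(field, CFG, rng) for _ in range(200_000)])
        # IG(2, 0.011): mean = 0.011; heavy-tailed, so allow a loose band.
        assert np.mean(draws) == pytest.approx(0.011, rel=0.25)
        assert np.median(draws) == pytest.approx(
            0.011 / 1.678, rel=0.05
        )  # scale / gamma(2) median


class TestOffsets:
    def test_worked_example_her2_positive_bin9(self, make_patient):
        fields = (
            DeltaField(False, np.r_[np.zeros(4), 0.1 * np.arange(1, 6)], 0.01),
            DeltaField(True, np.r_[np.zeros(4), 0.2 * np.arange(1, 6)], 0.01),
        )
        p = make_patient(rand_day=250, her2=True)
        # randomized 750 days before the analysis day => bin 9
        assert offset_for(p, 1000, fields, CFG) == pytest.approx(fields[1].value(9))
        assert fields[1].value(9) == pytest.approx(1.0)

    def test_recent_bins_have_zero_offset(self, make_patient):
        fields = (
            DeltaField(False, np.r_[np.zeros(4), np.ones(5)], 0.01),
            DeltaField(True, np.r_[np.zeros(4), np.ones(5)], 0.01),
        )
        p = make_patient(rand_day=970)
        assert offset_for(p, 1000, fields, CFG) == 0.0

    def test_stratification_contract(self, make_patient):
        fields = (
            DeltaField(False, np.r_[np.zeros(4), [0.3]], 0.01),
            DeltaField(True, np.r_[np.zeros(4), [-0.4]], 0.01),
        )
        neg = make_patient(rand_day=0, her2=False)
        pos = make_patient(rand_day=0, her2=True)
        assert offset_for(neg, 400, fields, CFG) == pytest.approx(0.3)
        assert offset_for(pos, 400, fields, CFG) == pytest.approx(-0.4)

    def test_nonzero_recent_delta_rejected(self):
        with pytest.raises(ValueError):
            DeltaField(False, np.array([0.1, 0, 0, 0, 0.2]), 0.01)

    def test_future_randomization_rejected(self, make_patient):
        fields = (
            DeltaField(False, np.zeros(5), 0.01),
            DeltaField(True, np.zeros(5), 0.01),
        )
        with pytest.raises(ValueError):
            offset_for(make_patient(rand_day=500), 400, fields, CFG)
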