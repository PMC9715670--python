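"""Covariate-adjusted Bayesian logistic model of pCR with calendar drift.

The probability that patient i achieves pCR is modelled on the log-odds
scale as

    eta_i = beta . x_i  +  1[arm_i != control] * (gamma_{arm_i} . x_i)
            + delta_{h_i}(t_i)

where x_i = (1, HR, HER2, MP2) with 0/1 coding, gamma_a are the per-arm
treatment effects (main effect plus HR/HER2/MP effect modifiers), t_i is the
patient's 90-day calendar bin counted back from the analysis day and
delta_h(t) the HER2-stratified time-machine offset (see
:mod:`platformtrial.time_machine`).  Regression coefficients get weakly
informative N(0, 2^2) priors; the drift field gets the NDLM prior with its
conjugate inverse-gamma innovation variance.

Patients whose surgery is still pending at an interim analysis are handled
with multiple imputation inside the sampler: their outcome is redrawn every
sweep from Bernoulli(ilogit(w0 + w1 z_i + eta_i)), with z_i the standardized
log functional-tumor-volume (FTV) ratio of the latest MRI to baseline, and
the imputation coefficients (w0, w1) are updated against the completers that
have both an observed outcome and FTV — a modularized (cut) imputation
submodel standing in for the trial's full longitudinal model.

Posterior sampling is a seed-deterministic adaptive Metropolis-within-Gibbs:
a joint adaptive random-walk block for the regression coefficients, one
block per HER2 stratum for the free drift offsets, a conjugate Gibbs draw
for tau^2 and a small block for (w0, w1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import invgamma, norm

from . import time_machine as tm
from .trial_data import (
    ALL_SUBTYPES,
    ArmSpec,
    PatientRecord,
    Signature,
    control_arm,
    default_signature_catalogue,
    signature_members,
    subtype_signature,
)

__all__ = [
    "ModelConfig",
    "ModelParams",
    "PosteriorDraws",
    "linear_predictor",
    "ftv_log_ratio",
    "impute_pending",
    "log_posterior",
    "sample_posterior",
]

_FTV_FLOOR = 1e-6


@dataclass(frozen=True)
class ModelConfig:
    """Priors, sampler sizes and structural switches."""

    prior_sd: float = 2.0           # N(0, sd^2) on all regression coefficients
    impute_prior_sd: float = 2.0    # N(0, sd^2) on (w0, w1)
    n_warmup: int = 500
    n_draws: int = 1000
    use_time_machine: bool = True   # ablation switch: False pins all delta at 0
    drift_on_treatment_only: bool = False  # alternative reading: delta enters
                                           # only experimental-arm predictors
    per_subtype_arm_effects: bool = False  # 8-cell arm effects instead of
                                           # main-effects modification
    ess_warn: float = 50.0
    adapt_target: float = 0.3

    def __post_init__(self) -> None:
        if self.prior_sd <= 0 or self.impute_prior_sd <= 0:
            raise ValueError("prior sds must be positive")
        if self.n_draws <= 0 or self.n_warmup < 0:
            raise ValueError("draw counts invalid")


@dataclass
class ModelParams:
    """One point in parameter space."""

    baseline: np.ndarray                      # (4,) intercept, HR, HER2, MP2
    arm_effects: dict[str, np.ndarray]        # arm_id -> (4,) or (8,)
    delta_minus: tm.DeltaField
    delta_plus: tm.DeltaField
    tau_sq: float
    impute: np.ndarray = field(default_factory=lambda: np.zeros(2))  # (w0, w1)

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.impute = np.asarray(self.impute, dtype=float)
        if not np.all(np.isfinite(self.baseline)):
            raise ValueError("baseline coefficients must be finite")


def _covariates(p: PatientRecord) -> np.ndarray:
    return np.array([1.0, float(p.hr), float(p.her2), float(p.mp2)])


def _arm_covariates(p: PatientRecord, per_subtype: bool) -> np.ndarray:
    if not per_subtype:
        return _covariates(p)
    x = np.zeros(len(ALL_SUBTYPES))
    x[ALL_SUBTYPES.index(p.subtype)] = 1.0
    return x


def linear_predictor(
    params: ModelParams,
    patient: PatientRecord,
    analysis_day: int,
    control_arm_id: str = "control",
    cfg: Optional[tm.TimeMachineConfig] = None,
    model_cfg: Optional[ModelConfig] = None,
) -> float:
    """Log-odds of pCR for one patient at one parameter point."""
    cfg = cfg or tm.TimeMachineConfig()
    model_cfg = model_cfg or ModelConfig()
    eta = float(_covariates(patient) @ params.baseline)
    is_experimental = patient.arm_id != control_arm_id
    if is_experimental:
        gamma = params.arm_effects[patient.arm_id]
        eta += float(_arm_covariates(patient, model_cfg.per_subtype_arm_effects) @ gamma)
    if model_cfg.use_time_machine and (is_experimental or not model_cfg.drift_on_treatment_only):
        eta += tm.offset_for(patient, analysis_day, (params.delta_minus, params.delta_plus), cfg)
    return eta


def ftv_log_ratio(patient: PatientRecord) -> Optional[float]:
    """log(FTV_latest / FTV_baseline), or None without a post-baseline scan.

    Zero volumes are floored (complete radiologic response gives a large
    negative ratio rather than -inf) with a logged warning.
    """
    if len(patient.ftv) < 2:
        return None
    base = patient.ftv[0][1]
    last = patient.ftv[-1][1]
    if base <= 0 or last <= 0:
        warnings.warn(
            f"patient {patient.patient_id}: nonpositive FTV floored at {_FTV_FLOOR}",
            stacklevel=2,
        )
    return math.log(max(last, _FTV_FLOOR) / max(base, _FTV_FLOOR))


def impute_pending(
    params: ModelParams,
    patient: PatientRecord,
    analysis_day: int,
    rng: np.random.Generator,
    z_stats: tuple[float, float] = (0.0, 1.0),
    control_arm_id: str = "control",
    cfg: Optional[tm.TimeMachineConfig] = None,
    model_cfg: Optional[ModelConfig] = None,
) -> int:
    """Draw a pending patient's pCR from the imputation submodel.

    With at least one post-baseline FTV assessment the draw is
    Bernoulli(ilogit(w0 + w1 z + eta)); without FTV it falls back to the
    patient's model rate ilogit(eta).  ``z_stats`` are the (mean, sd) of the
    completers' log FTV ratios used for standardization.
    """
    eta = linear_predictor(params, patient, analysis_day, control_arm_id, cfg, model_cfg)
    lr = ftv_log_ratio(patient)
    if lr is not None:
        mu, sd = z_stats
        z = (lr - mu) / max(sd, 1e-12)
        eta = eta + params.impute[0] + params.impute[1] * z
    return int(rng.random() < expit(eta))


# --------------------------------------------------------------------------
# Prepared design arrays
# --------------------------------------------------------------------------

class _Prepared:
    """Vectorized design for the sampler and the exact log-posterior."""

    def __init__(
        self,
        patients: Sequence[PatientRecord],
        arms: Sequence[ArmSpec],
        analysis_day: int,
        tm_cfg: tm.TimeMachineConfig,
        model_cfg: ModelConfig,
    ):
        self.patients = list(patients)
        self.analysis_day = analysis_day
        self.control_id = control_arm(arms).arm_id
        self.exp_arm_ids = sorted(a.arm_id for a in arms if not a.is_control)
        n = len(self.patients)
        self.n = n
        self.p_arm = len(ALL_SUBTYPES) if model_cfg.per_subtype_arm_effects else 4
        self.X = np.array([_covariates(p) for p in self.patients]).reshape(n, 4)
        self.A = np.array(
            [_arm_covariates(p, model_cfg.per_subtype_arm_effects) for p in self.patients]
        ).reshape(n, self.p_arm)
        arm_index = {a: k for k, a in enumerate(self.exp_arm_ids)}
        self.arm_codes = np.array(
            [-1 if p.arm_id == self.control_id else arm_index[p.arm_id] for p in self.patients],
            dtype=int,
        )
        for p in self.patients:
            if p.arm_id != self.control_id and p.arm_id not in arm_index:
                raise ValueError(f"patient {p.patient_id}: unregistered arm {p.arm_id!r}")
        self.her2 = np.array([p.her2 for p in self.patients], dtype=bool)
        self.bins = np.array(
            [tm.bin_index(analysis_day - p.rand_day, tm_cfg) for p in self.patients],
            dtype=int,
        ) if n else np.zeros(0, dtype=int)
        self.n_bins = int(self.bins.max()) if n else tm_cfg.free_recent_bins
        self.y_obs = np.array(
            [-1 if p.pcr is None else int(p.pcr) for p in self.patients], dtype=int
        )
        self.pending = self.y_obs < 0

        lrs = np.array(
            [np.nan if (lr := ftv_log_ratio(p)) is None else lr for p in self.patients]
        ) if n else np.zeros(0)
        self.has_z = ~np.isnan(lrs) if n else np.zeros(0, dtype=bool)
        comp = self.has_z & ~self.pending
        if comp.sum() >= 2 and np.std(lrs[comp]) > 0:
            self.z_stats = (float(np.mean(lrs[comp])), float(np.std(lrs[comp])))
        else:
            self.z_stats = (0.0, 1.0)
        self.z = (lrs - self.z_stats[0]) / self.z_stats[1]
        self.z[~self.has_z] = 0.0
        self.completer_z = comp

        # Drift applies to everyone under the shared-drift reading, or to
        # experimental patients only under the alternative reading.
        if model_cfg.drift_on_treatment_only:
            self.drift_mask = (self.arm_codes >= 0).astype(float)
        else:
            self.drift_mask = np.ones(n)
        if not model_cfg.use_time_machine:
            self.drift_mask = np.zeros(n)

    def delta_offsets(self, d_minus: np.ndarray, d_plus: np.ndarray) -> np.ndarray:
        """Per-patient drift offset given full delta vectors (bin 1..n_bins)."""
        if self.n == 0:
            return np.zeros(0)
        out = np.where(self.her2, d_plus[self.bins - 1], d_minus[self.bins - 1])
        return out * self.drift_mask

    def eta_reg(self, baseline: np.ndarray, gammas: np.ndarray) -> np.ndarray:
        """Regression part of eta; gammas has shape (n_exp_arms, p_arm)."""
        eta = self.X @ baseline
        exp_mask = self.arm_codes >= 0
        if exp_mask.any():
            eta[exp_mask] += np.einsum(
                "ij,ij->i", self.A[exp_mask], gammas[self.arm_codes[exp_mask]]
            )
        return eta


def _bern_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    return float(-np.sum(np.logaddexp(0.0, np.where(y == 1, -eta, eta))))


# --------------------------------------------------------------------------
# Exact log-posterior (the quantity the sampler blocks jointly target)
# --------------------------------------------------------------------------

def log_posterior(
    params: ModelParams,
    patients: Sequence[PatientRecord],
    arms: Sequence[ArmSpec],
    analysis_day: int,
    tm_cfg: Optional[tm.TimeMachineConfig] = None,
    model_cfg: Optional[ModelConfig] = None,
    y: Optional[np.ndarray] = None,
) -> float:
    """Joint log-posterior density (up to a constant) at one parameter point.

    Sums the Bernoulli-logistic likelihood over patients with a resolved
    outcome (observed, or imputed via ``y``), the Gaussian priors on all
    regression and imputation coefficients, the NDLM prior on the free drift
    offsets of both HER2 strata, the inverse-gamma prior on tau^2, and the
    imputation-submodel likelihood over completers with FTV.
    """
    tm_cfg = tm_cfg or tm.TimeMachineConfig()
    model_cfg = model_cfg or ModelConfig()
    prep = _Prepared(patients, arms, analysis_day, tm_cfg, model_cfg)
    if y is None:
        y = prep.y_obs
    y = np.asarray(y)

    gammas = np.array(
        [params.arm_effects[a] for a in prep.exp_arm_ids]
    ).reshape(len(prep.exp_arm_ids), -1)
    eta = prep.eta_reg(params.baseline, gammas) + prep.delta_offsets(
        params.delta_minus.delta, params.delta_plus.delta
    )

    resolved = y >= 0
    lp = _bern_loglik(y[resolved], eta[resolved])

    # Imputation submodel over completers with FTV.
    cz = prep.completer_z
    if cz.any():
        eta_w = eta[cz] + params.impute[0] + params.impute[1] * prep.z[cz]
        lp += _bern_loglik(y[cz], eta_w)

    sd = model_cfg.prior_sd
    lp += float(np.sum(norm.logpdf(params.baseline, 0.0, sd)))
    lp += float(np.sum(norm.logpdf(gammas, 0.0, sd)))
    lp += float(np.sum(norm.logpdf(params.impute, 0.0, model_cfg.impute_prior_sd)))

    if model_cfg.use_time_machine:
        prior = tm.ndlm_prior(params.delta_minus.n_bins, params.tau_sq, tm_cfg)
        lp += prior.logpdf(params.delta_minus.free_values)
        prior_p = tm.ndlm_prior(params.delta_plus.n_bins, params.tau_sq, tm_cfg)
        lp += prior_p.logpdf(params.delta_plus.free_values)
        lp += float(invgamma.logpdf(params.tau_sq, tm_cfg.ig_alpha, scale=tm_cfg.ig_beta))
    return lp


# --------------------------------------------------------------------------
# Posterior draws container
# --------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Sampled parameters plus derived per-signature pCR-rate draws."""

    baseline: np.ndarray                       # (S, 4)
    arm_effects: dict[str, np.ndarray]         # arm_id -> (S, p_arm)
    delta_minus: np.ndarray                    # (S, n_bins)
    delta_plus: np.ndarray                     # (S, n_bins)
    tau_sq: np.ndarray                         # (S, 2): (HER2-, HER2+) columns,
                                               # identical when tau is shared
    impute: np.ndarray                         # (S, 2)
    rates: dict[tuple[str, str], np.ndarray]   # (arm_id, signature) -> (S,)
    control_arm_id: str
    signature_names: list[str]
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return int(self.baseline.shape[0])

    def rate_draws(self, arm_id: str, signature: str) -> np.ndarray:
        return self.rates[(arm_id, signature)]

    def to_frame(self):
        """Flat per-draw parameter table (one column per scalar parameter)."""
        import pandas as pd

        cols = {f"baseline_{n}": self.baseline[:, j]
                for j, n in enumerate(["intercept", "hr", "her2", "mp2"])}
        for a, g in self.arm_effects.items():
            for j in range(g.shape[1]):
                cols[f"arm_{a}_{j}"] = g[:, j]
        for j in range(self.delta_minus.shape[1]):
            cols[f"delta_minus_{j + 1}"] = self.delta_minus[:, j]
            cols[f"delta_plus_{j + 1}"] = self.delta_plus[:, j]
        cols["tau_sq_minus"] = self.tau_sq[:, 0]
        cols["tau_sq_plus"] = self.tau_sq[:, 1]
        cols["w0"] = self.impute[:, 0]
        cols["w1"] = self.impute[:, 1]
        return pd.DataFrame(cols)


def _derive_rates(
    prep: _Prepared,
    signatures: Sequence[Signature],
    baseline: np.ndarray,
    gammas: dict[str, np.ndarray],
) -> dict[tuple[str, str], np.ndarray]:
    """Present-day per-signature rate draws.

    For each (arm, signature), the rate is the mean of ilogit(eta) over the
    empirical covariate distribution of all enrolled patients in the
    signature, at drift offset 0 (the "now" of the analysis), with the arm
    set counterfactually to the target arm.  Invariant to patient order.
    """
    S = baseline.shape[0]
    rates: dict[tuple[str, str], np.ndarray] = {}
    for sig in signatures:
        members = signature_members(sig, prep.patients)
        if not members:
            empty = np.full(S, np.nan)
            rates[(prep.control_id, sig.name)] = empty
            for a in prep.exp_arm_ids:
                rates[(a, sig.name)] = empty
            continue
        Xg = np.array([_covariates(p) for p in members])
        Ag = np.array([
            _arm_covariates(p, per_subtype=(prep.p_arm == len(ALL_SUBTYPES)))
            for p in members
        ])
        eta0 = Xg @ baseline.T                     # (ng, S)
        rates[(prep.control_id, sig.name)] = expit(eta0).mean(axis=0)
        for a in prep.exp_arm_ids:
            rates[(a, sig.name)] = expit(eta0 + Ag @ gammas[a].T).mean(axis=0)
    return rates


# --------------------------------------------------------------------------
# Adaptive random-walk Metropolis block
# --------------------------------------------------------------------------

def _laplace_regression(
    prep: _Prepared, y: np.ndarray, offsets: np.ndarray, sd2: float,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Penalized IRLS: posterior mode and inverse Hessian of the regression
    block (ridge precision 1/sd2), at fixed drift offsets and outcomes."""
    n = prep.n
    K = len(prep.exp_arm_ids)
    p = 4 + K * prep.p_arm
    Z = np.zeros((n, p))
    Z[:, :4] = prep.X
    for k in range(K):
        rows = prep.arm_codes == k
        Z[rows, 4 + k * prep.p_arm: 4 + (k + 1) * prep.p_arm] = prep.A[rows]
    resolved = y >= 0
    Zr, yr, offr = Z[resolved], y[resolved], offsets[resolved]
    theta = np.zeros(p)
    for _ in range(max_iter):
        mu = expit(Zr @ theta + offr)
        grad = Zr.T @ (yr - mu) - theta / sd2
        W = np.clip(mu * (1 - mu), 1e-6, None)
        H = Zr.T @ (W[:, None] * Zr) + np.eye(p) / sd2
        step = np.linalg.solve(H, grad)
        theta = theta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    mu = expit(Zr @ theta + offr)
    W = np.clip(mu * (1 - mu), 1e-6, None)
    H = Zr.T @ (W[:, None] * Zr) + np.eye(p) / sd2
    return theta, np.linalg.inv(H)


class _GaussianProposal:
    """Frozen multivariate normal for independence Metropolis steps."""

    def __init__(self, mean: np.ndarray, cov: np.ndarray, inflate: float = 1.3):
        self.mean = mean
        cov = inflate * 0.5 * (cov + cov.T)
        self.chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(mean)))
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(self.chol))))
        self.dim = len(mean)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return self.mean + self.chol @ rng.standard_normal(self.dim)

    def logpdf(self, x: np.ndarray) -> float:
        u = np.linalg.solve(self.chol, x - self.mean)
        return -0.5 * (u @ u) - 0.5 * self._logdet - 0.5 * self.dim * math.log(2 * math.pi)


class _AdaptiveRW:
    """Haario-style adaptive random walk, frozen after warmup."""

    def __init__(self, dim: int, target: float, init_scale: float = 0.2,
                 adapt_cov: bool = True):
        self.dim = dim
        self.target = target
        self.adapt_cov = adapt_cov
        self.log_scale = math.log(init_scale / math.sqrt(max(dim, 1)))
        self.mean = np.zeros(dim)
        self.cov = np.eye(dim)
        self.chol = np.eye(dim)
        self.count = 0
        self.n_accept = 0
        self.n_prop = 0

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return x + math.exp(self.log_scale) * (self.chol @ rng.standard_normal(self.dim))

    def adapt(self, x: np.ndarray, acc_prob: float) -> None:
        self.count += 1
        g = (self.count + 10) ** -0.6
        self.log_scale += g * (acc_prob - self.target)
        if not self.adapt_cov:
            return
        d = x - self.mean
        self.mean += g * d
        self.cov += g * (np.outer(d, d) - self.cov)
        if self.count % 25 == 0:
            try:
                self.chol = np.linalg.cholesky(self.cov + 1e-8 * np.eye(self.dim))
            except np.linalg.LinAlgError:  # pragma: no cover - safety net
                self.chol = np.eye(self.dim)

    @property
    def accept_rate(self) -> float:
        return self.n_accept / max(self.n_prop, 1)


# --------------------------------------------------------------------------
# Sampler
# --------------------------------------------------------------------------

def _prior_draws(
    prep: _Prepared,
    signatures: Sequence[Signature],
    tm_cfg: tm.TimeMachineConfig,
    model_cfg: ModelConfig,
    rng: np.random.Generator,
) -> PosteriorDraws:
    """Direct prior sampling for the no-data degenerate case."""
    S = model_cfg.n_draws
    K = len(prep.exp_arm_ids)
    baseline = rng.normal(0, model_cfg.prior_sd, (S, 4))
    gammas = {a: rng.normal(0, model_cfg.prior_sd, (S, prep.p_arm)) for a in prep.exp_arm_ids}
    tau = invgamma.rvs(tm_cfg.ig_alpha, scale=tm_cfg.ig_beta, size=S, random_state=rng)
    nb = prep.n_bins
    free = tm_cfg.free_recent_bins
    dm = np.zeros((S, nb))
    dp = np.zeros((S, nb))
    for s in range(S):
        dm[s, free:] = tm.sample_ndlm_forward(nb, tau[s], tm_cfg, rng)[0]
        dp[s, free:] = tm.sample_ndlm_forward(nb, tau[s], tm_cfg, rng)[0]
    w = rng.normal(0, model_cfg.impute_prior_sd, (S, 2))
    rates = _derive_rates(prep, signatures, baseline, gammas) if prep.n else {}
    return PosteriorDraws(
        baseline=baseline, arm_effects=gammas, delta_minus=dm, delta_plus=dp,
        tau_sq=np.column_stack([tau, tau]), impute=w, rates=rates,
        control_arm_id=prep.control_id,
        signature_names=[s.name for s in signatures],
        diagnostics={"status": "prior", "note": "no data; prior returned", "n_exp_arms": K},
    )


def sample_posterior(
    patients: Sequence[PatientRecord],
    arms: Sequence[ArmSpec],
    analysis_day: int,
    tm_cfg: Optional[tm.TimeMachineConfig] = None,
    model_cfg: Optional[ModelConfig] = None,
    signatures: Optional[Sequence[Signature]] = None,
    include_subtype_signatures: bool = True,
    seed: int = 0,
) -> PosteriorDraws:
    """MCMC over the joint posterior; deterministic given ``seed``.

    Patients must have passed the evaluability filter (pending outcomes are
    allowed and multiply imputed).  Derived per-signature rate draws are
    computed for the supplied catalogue (default: the ten-signature
    catalogue) plus, optionally, the eight singleton subtypes used by the
    adaptive randomizer.
    """
    tm_cfg = tm_cfg or tm.TimeMachineConfig()
    model_cfg = model_cfg or ModelConfig()
    if signatures is None:
        signatures = default_signature_catalogue()
    signatures = list(signatures)
    if include_subtype_signatures:
        have = {s.name for s in signatures}
        signatures += [
            subtype_signature(s) for s in ALL_SUBTYPES if s.label not in have
        ]

    rng = np.random.default_rng(seed)
    prep = _Prepared(patients, arms, analysis_day, tm_cfg, model_cfg)

    n_control = int(np.sum(prep.arm_codes < 0))
    n_exp = prep.n - n_control
    if prep.n == 0 or n_control == 0 or n_exp == 0:
        if prep.n > 0:
            warnings.warn("a study arm is empty; returning prior draws")
        return _prior_draws(prep, signatures, tm_cfg, model_cfg, rng)

    free = tm_cfg.free_recent_bins
    nb = prep.n_bins
    m = max(nb - free, 0) if model_cfg.use_time_machine else 0
    K = len(prep.exp_arm_ids)
    p_reg = 4 + K * prep.p_arm
    sd2 = model_cfg.prior_sd ** 2
    wsd2 = model_cfg.impute_prior_sd ** 2

    # State.  The drift field uses a non-centered parameterization: per
    # stratum a vector u of standardized innovations with iid N(0,1) prior,
    # mapped to offsets by the NDLM recursion at scales (tau0, tau1, tau).
    # This avoids the funnel that pins tau^2 (and hence delta) near zero
    # under the tight inverse-gamma prior; tau^2 moves by an
    # ancillarity-sufficiency interweaving step (conjugate Gibbs given delta,
    # then a log-scale MH step given u).
    theta = np.zeros(p_reg)                  # baseline + stacked gammas
    u = {False: np.zeros(m), True: np.zeros(m)}
    tau0 = 0.01 if m else tm_cfg.ig_beta / (tm_cfg.ig_alpha + 1)
    tau = {False: tau0, True: tau0}          # equal whenever shared_tau
    w = np.zeros(2)
    y = prep.y_obs.copy()
    y[prep.pending] = 0  # placeholder; imputed before first use

    sd0 = math.sqrt(tm_cfg.tau0_sq)
    sd1 = math.sqrt(tm_cfg.tau1_sq)

    def _free_from_u(uv: np.ndarray, tau: float) -> np.ndarray:
        d = np.empty(m)
        if m == 0:
            return d
        st = math.sqrt(tau)
        d[0] = tm_cfg.mu0 + sd0 * uv[0]
        if m >= 2:
            d[1] = d[0] + tm_cfg.mu1 + sd1 * uv[1]
        for j in range(2, m):
            d[j] = 2 * d[j - 1] - d[j - 2] + st * uv[j]
        return d

    def _u_from_free(d: np.ndarray, tau: float) -> np.ndarray:
        uv = np.empty(m)
        if m == 0:
            return uv
        st = math.sqrt(tau)
        uv[0] = (d[0] - tm_cfg.mu0) / sd0
        if m >= 2:
            uv[1] = (d[1] - d[0] - tm_cfg.mu1) / sd1
        for j in range(2, m):
            uv[j] = (d[j] - 2 * d[j - 1] + d[j - 2]) / st
        return uv

    def full_delta(stratum: bool) -> np.ndarray:
        d = np.zeros(nb)
        if m:
            d[free:] = _free_from_u(u[stratum], tau[stratum])
        return d

    def _ig_logpdf(x: float) -> float:
        return -(tm_cfg.ig_alpha + 1) * math.log(x) - tm_cfg.ig_beta / x

    def split(thv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return thv[:4], thv[4:].reshape(K, prep.p_arm)

    def eta_of(thv: np.ndarray, dm_vec: np.ndarray, dp_vec: np.ndarray) -> np.ndarray:
        b, g = split(thv)
        eta = prep.eta_reg(b, g)
        if model_cfg.use_time_machine:
            off = np.where(prep.her2, dp_vec[prep.bins - 1], dm_vec[prep.bins - 1])
            eta = eta + off * prep.drift_mask
        return eta

    # Pre-size storage.
    S = model_cfg.n_draws
    out_theta = np.empty((S, p_reg))
    out_dm = np.zeros((S, nb))
    out_dp = np.zeros((S, nb))
    out_tau = np.empty((S, 2))
    out_w = np.empty((S, 2))

    rw_reg = _AdaptiveRW(p_reg, model_cfg.adapt_target, adapt_cov=False)
    rw_d = {
        s: _AdaptiveRW(m, model_cfg.adapt_target, init_scale=0.8, adapt_cov=False)
        for s in (False, True)
    }
    rw_w = _AdaptiveRW(2, model_cfg.adapt_target)

    cz = prep.completer_z
    z_cz = prep.z[cz]
    y_cz = prep.y_obs[cz]
    pend_idx = np.flatnonzero(prep.pending)
    has_z_pend = prep.has_z[prep.pending]
    z_pend = prep.z[prep.pending]

    def reg_logprior(thv: np.ndarray) -> float:
        return float(-0.5 * (thv @ thv) / sd2)

    def w_loglik(wv: np.ndarray, eta: np.ndarray) -> float:
        lp = float(-0.5 * (wv @ wv) / wsd2)
        if cz.any():
            lp += _bern_loglik(y_cz, eta[cz] + wv[0] + wv[1] * z_cz)
        return lp

    dm_vec = full_delta(False)
    dp_vec = full_delta(True)

    # Laplace approximation of the regression block: used both as the
    # preconditioner of the random-walk proposals and as an independence
    # proposal alternated with them (both are valid MH kernels; the
    # alternation fixes the slow mixing of a bare random walk).
    map_theta, lap_cov = _laplace_regression(
        prep, prep.y_obs, np.zeros(prep.n), sd2
    )
    theta = map_theta.copy()
    indep = _GaussianProposal(map_theta, lap_cov)
    rw_reg.chol = np.linalg.cholesky(lap_cov + 1e-10 * np.eye(p_reg))
    rw_reg.log_scale = math.log(2.38 / math.sqrt(p_reg))
    # u-space innovations are a priori iid N(0,1): identity preconditioner.

    eta = eta_of(theta, dm_vec, dp_vec)
    ll_main = _bern_loglik(y, eta)

    total = model_cfg.n_warmup + S
    for it in range(total):
        warm = it < model_cfg.n_warmup

        # 1. Multiple imputation of pending outcomes.
        if pend_idx.size:
            eta_p = eta[pend_idx].copy()
            eta_p[has_z_pend] += w[0] + w[1] * z_pend[has_z_pend]
            y[pend_idx] = (rng.random(pend_idx.size) < expit(eta_p)).astype(int)
            ll_main = _bern_loglik(y, eta)

        # 2. Regression block: alternate independence-from-Laplace and
        # preconditioned random-walk Metropolis.
        use_indep = it % 2 == 0
        if use_indep:
            prop = indep.draw(rng)
        else:
            prop = rw_reg.propose(theta, rng)
        eta_prop = eta_of(prop, dm_vec, dp_vec)
        ll_prop = _bern_loglik(y, eta_prop)
        log_acc = (ll_prop + reg_logprior(prop)) - (ll_main + reg_logprior(theta))
        if use_indep:
            log_acc += indep.logpdf(theta) - indep.logpdf(prop)
        acc_prob = min(1.0, math.exp(min(log_acc, 0.0)))
        rw_reg.n_prop += 1
        if rng.random() < acc_prob:
            theta, eta, ll_main = prop, eta_prop, ll_prop
            rw_reg.n_accept += 1
        if warm and not use_indep:
            rw_reg.adapt(theta, acc_prob)

        # 3. Drift innovation blocks per HER2 stratum (non-centered).
        if m:
            for stratum in (False, True):
                cur = u[stratum]
                prop_u = rw_d[stratum].propose(cur, rng)
                u[stratum] = prop_u
                dm_vec, dp_vec = full_delta(False), full_delta(True)
                eta_prop = eta_of(theta, dm_vec, dp_vec)
                ll_prop = _bern_loglik(y, eta_prop)
                log_acc = (ll_prop - 0.5 * (prop_u @ prop_u)) - (
                    ll_main - 0.5 * (cur @ cur)
                )
                acc_prob = min(1.0, math.exp(min(log_acc, 0.0)))
                rw_d[stratum].n_prop += 1
                if rng.random() < acc_prob:
                    eta, ll_main = eta_prop, ll_prop
                    rw_d[stratum].n_accept += 1
                else:
                    u[stratum] = cur
                    dm_vec, dp_vec = full_delta(False), full_delta(True)
                if warm:
                    rw_d[stratum].adapt(u[stratum], acc_prob)

            # 4a. Centered (sufficiency) step: conjugate tau^2 given delta,
            # then refresh u so delta is unchanged.
            f_minus = tm.DeltaField(False, dm_vec, tau[False], free)
            f_plus = tm.DeltaField(True, dp_vec, tau[True], free)
            if tm_cfg.shared_tau:
                t_new = tm.sample_tau_sq([f_minus, f_plus], tm_cfg, rng)
                tau = {False: t_new, True: t_new}
            else:
                tau = {
                    False: tm.sample_tau_sq(f_minus, tm_cfg, rng),
                    True: tm.sample_tau_sq(f_plus, tm_cfg, rng),
                }
            u[False] = _u_from_free(dm_vec[free:], tau[False])
            u[True] = _u_from_free(dp_vec[free:], tau[True])

            # 4b. Ancillarity step: log-scale MH on tau^2 at fixed u
            # (delta rescales with the proposal).
            strata_groups = [(False, True)] if tm_cfg.shared_tau else [(False,), (True,)]
            for group in strata_groups:
                tau_cur = tau[group[0]]
                tau_prop = tau_cur * math.exp(0.5 * rng.standard_normal())
                tau_old = dict(tau)
                for s in group:
                    tau[s] = tau_prop
                dm_p, dp_p = full_delta(False), full_delta(True)
                eta_prop = eta_of(theta, dm_p, dp_p)
                ll_prop = _bern_loglik(y, eta_prop)
                log_acc = (
                    ll_prop + _ig_logpdf(tau_prop) + math.log(tau_prop)
                ) - (ll_main + _ig_logpdf(tau_cur) + math.log(tau_cur))
                if rng.random() < math.exp(min(log_acc, 0.0)):
                    dm_vec, dp_vec, eta, ll_main = dm_p, dp_p, eta_prop, ll_prop
                else:
                    tau = tau_old
                    dm_vec, dp_vec = full_delta(False), full_delta(True)

        # 5. Imputation coefficients.
        if cz.any():
            prop_w = rw_w.propose(w, rng)
            log_acc = w_loglik(prop_w, eta) - w_loglik(w, eta)
            acc_prob = min(1.0, math.exp(min(log_acc, 0.0)))
            rw_w.n_prop += 1
            if rng.random() < acc_prob:
                w = prop_w
                rw_w.n_accept += 1
            if warm:
                rw_w.adapt(w, acc_prob)
        else:
            w = rng.normal(0.0, model_cfg.impute_prior_sd, 2)

        if not warm:
            s = it - model_cfg.n_warmup
            out_theta[s] = theta
            out_dm[s] = dm_vec
            out_dp[s] = dp_vec
            out_tau[s, 0] = tau[False]
            out_tau[s, 1] = tau[True]
            out_w[s] = w

    baseline = out_theta[:, :4]
    gammas = {
        a: out_theta[:, 4 + k * prep.p_arm: 4 + (k + 1) * prep.p_arm]
        for k, a in enumerate(prep.exp_arm_ids)
    }
    rates = _derive_rates(prep, signatures, baseline, gammas)

    diagnostics = _diagnose(baseline, gammas, rw_reg, rw_d if m else {}, rw_w, model_cfg)
    return PosteriorDraws(
        baseline=baseline,
        arm_effects=gammas,
        delta_minus=out_dm,
        delta_plus=out_dp,
        tau_sq=out_tau,
        impute=out_w,
        rates=rates,
        control_arm_id=prep.control_id,
        signature_names=[s.name for s in signatures],
        diagnostics=diagnostics,
    )


def _diagnose(baseline, gammas, rw_reg, rw_d, rw_w, model_cfg: ModelConfig) -> dict:
    """Acceptance rates and effective sample sizes, with a warn status."""
    import arviz as az

    acc = {"regression": rw_reg.accept_rate, "impute": rw_w.accept_rate}
    for s, blk in rw_d.items():
        acc[f"delta_{'plus' if s else 'minus'}"] = blk.accept_rate
    ess = {"baseline_intercept": float(az.ess(np.asarray(baseline[:, 0])))}
    for a, g in gammas.items():
        ess[f"arm_{a}_main"] = float(az.ess(np.asarray(g[:, 0])))
    warnings_list = []
    if min(ess.values()) < model_cfg.ess_warn:
        warnings_list.append(f"low effective sample size (min {min(ess.values()):.0f})")
    for name, a in acc.items():
        if not 0.05 <= a <= 0.8:
            warnings_list.append(f"{name} acceptance rate {a:.2f} outside [0.05, 0.80]")
    return {
        "status": "warn" if warnings_list else "ok",
        "acceptance": acc,
        "ess": ess,
        "warnings": warnings_list,
    }
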