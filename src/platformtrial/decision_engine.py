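"""Signature-level decisions: superiority, phase-3 prediction, randomization.

An experimental arm *graduates* when its predictive probability of success
in a hypothetical subtype-specific 300-patient 1:1 confirmatory phase 3
trial reaches 85% in any signature; it is dropped for futility when that
probability is below 10% in all signatures; otherwise it continues until a
predefined maximum accrual.  "Success" in phase 3 is read as a one-sided
pooled two-proportion z-test at alpha = 0.025 (the conventional reading; a
config point, since the protocol does not define it).

Adaptive randomization assigns a fixed 20% of patients to control; the
remaining mass is split across the experimental arms open to the patient's
subtype in proportion to the current probability that each arm's pCR rate
beats control within that subtype (floored at 0.01 so no arm is starved).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import binom, norm

from .pcr_model import PosteriorDraws
from .trial_data import ArmSpec, Signature, Subtype, control_arm

__all__ = [
    "DecisionConfig",
    "DecisionReport",
    "prob_superiority",
    "phase3_power",
    "pred_prob_phase3",
    "randomization_probs",
    "evaluate_arm",
    "build_decision_report",
]


@dataclass(frozen=True)
class DecisionConfig:
    graduation_threshold: float = 0.85
    futility_threshold: float = 0.10
    phase3_n: int = 300           # total, 1:1
    phase3_alpha: float = 0.025   # one-sided
    control_share: float = 0.20
    min_weight: float = 0.01      # floor on randomization weights
    interim_cadence_days: int = 30
    min_signature_n: int = 0      # minimum enrollment before graduation may fire

    def __post_init__(self) -> None:
        if not 0 < self.futility_threshold < self.graduation_threshold < 1:
            raise ValueError("require 0 < futility < graduation < 1")
        if self.phase3_n % 2:
            raise ValueError("phase3_n must be even (1:1 allocation)")
        if not 0 < self.control_share < 1:
            raise ValueError("control_share must be in (0,1)")


def prob_superiority(draws: PosteriorDraws, arm_id: str, signature: str) -> float:
    """Fraction of paired posterior draws with rate_arm strictly above control."""
    pe = draws.rate_draws(arm_id, signature)
    pc = draws.rate_draws(draws.control_arm_id, signature)
    if np.all(np.isnan(pe)) or np.all(np.isnan(pc)):
        return float("nan")
    return float(np.mean(pe > pc))


@lru_cache(maxsize=8)
def _reject_matrix(n_per_arm: int, alpha: float) -> np.ndarray:
    """Rejection indicator of the pooled one-sided z-test on a (xe, xc) grid."""
    x = np.arange(n_per_arm + 1)
    pe = x[:, None] / n_per_arm
    pc = x[None, :] / n_per_arm
    pbar = (x[:, None] + x[None, :]) / (2 * n_per_arm)
    var = pbar * (1 - pbar) * (2 / n_per_arm)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (pe - pc) / np.sqrt(var), -np.inf)
    return (z > norm.ppf(1 - alpha)).astype(float)


def phase3_power(p_e: np.ndarray, p_c: np.ndarray, n_per_arm: int, alpha: float) -> np.ndarray:
    """Exact rejection probability of the phase-3 test at given true rates.

    Enumerates the full binomial grid: power = pmf_e' R pmf_c with R the
    precomputed rejection mask.  Degenerate rates at 0 or 1 are handled by
    the exact binomial pmf (no NaNs).
    """
    p_e = np.atleast_1d(np.asarray(p_e, dtype=float))
    p_c = np.atleast_1d(np.asarray(p_c, dtype=float))
    R = _reject_matrix(n_per_arm, alpha)
    x = np.arange(n_per_arm + 1)
    pmf_e = binom.pmf(x[None, :], n_per_arm, np.clip(p_e, 0, 1)[:, None])  # (S, n+1)
    pmf_c = binom.pmf(x[None, :], n_per_arm, np.clip(p_c, 0, 1)[:, None])
    return np.einsum("si,ij,sj->s", pmf_e, R, pmf_c)


def pred_prob_phase3(
    draws: PosteriorDraws,
    arm_id: str,
    signature: str,
    cfg: Optional[DecisionConfig] = None,
) -> float:
    """Posterior-averaged power of the hypothetical confirmatory trial.

    For each paired posterior draw (p_e, p_c) the exact probability that a
    1:1 two-arm binomial trial of ``phase3_n`` patients rejects
    H0: p_e <= p_c at the one-sided level is computed; the predictive
    probability is the average over draws.
    """
    cfg = cfg or DecisionConfig()
    pe = draws.rate_draws(arm_id, signature)
    pc = draws.rate_draws(draws.control_arm_id, signature)
    ok = ~(np.isnan(pe) | np.isnan(pc))
    if not ok.any():
        return float("nan")
    power = phase3_power(pe[ok], pc[ok], cfg.phase3_n // 2, cfg.phase3_alpha)
    return float(power.mean())


def randomization_probs(
    weights: Mapping[str, float],
    subtype: Subtype,
    open_arms: Sequence[ArmSpec],
    cfg: Optional[DecisionConfig] = None,
) -> dict[str, float]:
    """Allocation probabilities for one patient of a given subtype.

    ``weights`` maps experimental arm ids to the current subtype-restricted
    superiority probabilities (any missing arm gets the floor).  The control
    arm receives exactly ``control_share``; eligible experimental arms share
    the remainder proportionally to their (floored) weights.  With no
    eligible experimental arm the control receives everything.
    """
    cfg = cfg or DecisionConfig()
    ctrl = control_arm(open_arms)
    eligible = [
        a for a in open_arms
        if not a.is_control and subtype in a.eligible_subtypes
    ]
    if not eligible:
        return {ctrl.arm_id: 1.0}
    w = np.array([max(float(weights.get(a.arm_id, cfg.min_weight)), cfg.min_weight)
                  for a in eligible])
    share = (1.0 - cfg.control_share) * w / w.sum()
    probs = {ctrl.arm_id: cfg.control_share}
    probs.update({a.arm_id: float(s) for a, s in zip(eligible, share)})
    return probs


def superiority_weights(
    draws: PosteriorDraws, arm_ids: Sequence[str], subtype: Subtype
) -> dict[str, float]:
    """Subtype-restricted superiority probabilities for the randomizer."""
    return {a: prob_superiority(draws, a, subtype.label) for a in arm_ids}


@dataclass
class SignatureDecision:
    signature: str
    prob_superiority: float
    pred_prob_phase3: float
    rate_mean_arm: float
    rate_pi_arm: tuple[float, float]
    rate_mean_control: float
    rate_pi_control: tuple[float, float]
    n_enrolled: int


@dataclass
class DecisionReport:
    """Per-arm decision at one analysis."""

    arm_id: str
    action: str  # graduate | futile | continue | max_accrual_reached
    graduated_signatures: list[str] = field(default_factory=list)
    rows: list[SignatureDecision] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "arm": self.arm_id,
                "signature": r.signature,
                "prob_superiority": r.prob_superiority,
                "pred_prob_phase3": r.pred_prob_phase3,
                "rate_mean_arm": r.rate_mean_arm,
                "rate_lo_arm": r.rate_pi_arm[0],
                "rate_hi_arm": r.rate_pi_arm[1],
                "rate_mean_control": r.rate_mean_control,
                "rate_lo_control": r.rate_pi_control[0],
                "rate_hi_control": r.rate_pi_control[1],
                "n_enrolled": r.n_enrolled,
                "action": self.action,
            }
            for r in self.rows
        )


def evaluate_arm(
    pred_probs: Mapping[str, float],
    enrollment: int,
    max_accrual: int,
    cfg: Optional[DecisionConfig] = None,
    signature_n: Optional[Mapping[str, int]] = None,
) -> tuple[str, list[str]]:
    """Apply the graduation/futility/accrual rules, in exactly that order.

    Returns (action, graduated signatures).  NaN predictive probabilities
    (empty signatures) are ignored for graduation and treated as futile-
    compatible.  ``signature_n`` optionally gates graduation on a minimum
    per-signature enrollment (default 0: no gate).
    """
    cfg = cfg or DecisionConfig()
    valid = {s: p for s, p in pred_probs.items() if not np.isnan(p)}
    grads = [
        s for s, p in valid.items()
        if p >= cfg.graduation_threshold
        and (signature_n is None or signature_n.get(s, 0) >= cfg.min_signature_n)
    ]
    if grads:
        return "graduate", sorted(grads)
    if valid and all(p < cfg.futility_threshold for p in valid.values()):
        return "futile", []
    if enrollment >= max_accrual:
        return "max_accrual_reached", []
    return "continue", []


def build_decision_report(
    draws: PosteriorDraws,
    arm: ArmSpec,
    signatures: Sequence[Signature],
    enrollment_by_signature: Mapping[str, int],
    cfg: Optional[DecisionConfig] = None,
) -> DecisionReport:
    """Full per-signature decision table plus the arm-level action."""
    cfg = cfg or DecisionConfig()
    rows = []
    pred = {}
    for sig in signatures:
        ps = prob_superiority(draws, arm.arm_id, sig.name)
        pp = pred_prob_phase3(draws, arm.arm_id, sig.name, cfg)
        pe = draws.rate_draws(arm.arm_id, sig.name)
        pc = draws.rate_draws(draws.control_arm_id, sig.name)
        def _summ(x):
            if np.all(np.isnan(x)):
                return float("nan"), (float("nan"), float("nan"))
            return float(np.nanmean(x)), (
                float(np.nanquantile(x, 0.025)), float(np.nanquantile(x, 0.975)))
        me, pie = _summ(pe)
        mc, pic = _summ(pc)
        rows.append(SignatureDecision(
            signature=sig.name, prob_superiority=ps, pred_prob_phase3=pp,
            rate_mean_arm=me, rate_pi_arm=pie,
            rate_mean_control=mc, rate_pi_control=pic,
            n_enrolled=int(enrollment_by_signature.get(sig.name, 0)),
        ))
        pred[sig.name] = pp
    enrollment = int(enrollment_by_signature.get("__arm_total__", 0))
    action, grads = evaluate_arm(
        pred, enrollment, arm.max_accrual, cfg,
        signature_n={s: int(enrollment_by_signature.get(s, 0)) for s in pred},
    )
    return DecisionReport(arm_id=arm.arm_id, action=action,
                          graduated_signatures=grads, rows=rows)
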