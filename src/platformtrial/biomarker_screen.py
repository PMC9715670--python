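"""Pre-specified expression-marker screen for treatment-specific pCR predictors.

For each marker in an 18-member panel (HSP90-pathway genes, the HSP90/HSP70
ratio, glucocorticoid/efflux metabolism genes and three signature scores),
logistic regressions assess association with pCR: within the experimental
arm, within the control arm, and pooled with a marker-by-treatment
interaction, each tested by a likelihood-ratio test (LRT) against the nested
model without the term of interest.  A marker qualifies as a treatment-
specific predictor when it associates with response in the experimental arm
(p < 0.05) but not in the control arm (p >= 0.05) and the interaction is
significant (p < 0.05).  Variants adjust for HR status and restrict to the
triple-negative and HR+/HER2- receptor subsets.

Markers are standardized (mean 0, sd 1) before fitting; the screen is
deliberately uncorrected for multiplicity (raw p < 0.05 screening), with an
optional Benjamini-Hochberg flag for users who want it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .trial_data import PatientRecord, Signature, signature_members, _sig

__all__ = ["LrtResult", "MarkerResult", "ScreenConfig", "logistic_lrt", "screen_markers"]

_SEP_COEF_BOUND = 15.0  # |coef| beyond this on a standardized marker => separation


@dataclass(frozen=True)
class ScreenConfig:
    alpha: float = 0.05
    standardize: bool = True
    bh_correct: bool = False   # optional Benjamini-Hochberg across the panel


@dataclass
class LrtResult:
    """One nested-model likelihood-ratio test."""

    statistic: float
    df: int
    p_value: float
    coef: float          # coefficient of the tested (last) column in the full fit
    stable: bool

    @property
    def direction(self) -> int:
        return 0 if not self.stable else int(np.sign(self.coef))


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Newton MLE; perfect separation (statsmodels raises/warns) => None."""
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, method="newton")
        except PerfectSeparationWarning:
            return None
        except Exception:
            # singular Hessian etc.: retry with a quasi-Newton fallback
            try:
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="lbfgs")
            except Exception:
                return None
    if not np.all(np.isfinite(res.params)):
        return None
    return res


def logistic_lrt(
    y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray
) -> LrtResult:
    """LRT of nested logistic models: 2*(ll_full - ll_reduced) ~ chi2(df).

    The reduced design must be nested in the full one.  Complete or quasi-
    separation (diverging coefficients or failed fits) is flagged unstable
    and the p-value reported as NaN, never silently.
    """
    y = np.asarray(y, dtype=float)
    X_full = np.atleast_2d(np.asarray(X_full, dtype=float))
    X_reduced = np.atleast_2d(np.asarray(X_reduced, dtype=float))
    if X_reduced.shape[1] >= X_full.shape[1]:
        raise ValueError("reduced design must have fewer columns than full")
    full = _fit_logit(y, X_full)
    red = _fit_logit(y, X_reduced)
    if full is None or red is None or np.any(np.abs(full.params) > _SEP_COEF_BOUND):
        coef = float("nan") if full is None else float(full.params[-1])
        return LrtResult(float("nan"), X_full.shape[1] - X_reduced.shape[1],
                         float("nan"), coef, stable=False)
    stat = max(0.0, 2.0 * (full.llf - red.llf))
    df = X_full.shape[1] - X_reduced.shape[1]
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return LrtResult(float(stat), df, p, float(full.params[-1]), stable=True)


@dataclass
class MarkerResult:
    """Screen outcome for one marker."""

    marker: str
    p_arm: float
    p_control: float
    p_interaction: float
    p_interaction_hr_adjusted: float
    p_subset_tn: float
    p_subset_hrpos_her2neg: float
    direction: int
    qualifies: bool
    notes: str = ""

    @staticmethod
    def _qualifies(p_arm: float, p_control: float, p_interaction: float,
                   alpha: float) -> bool:
        """Pure function of the three primary p-values."""
        if math.isnan(p_arm) or math.isnan(p_interaction):
            return False
        not_in_control = math.isnan(p_control) or p_control >= alpha
        return p_arm < alpha and not_in_control and p_interaction < alpha


_TN_SIG: Signature = _sig("TN", lambda s: not s.hr and not s.her2)
_HRPOS_SIG: Signature = _sig("HR+/HER2-", lambda s: s.hr and not s.her2)


def _marker_matrix(patients: Sequence[PatientRecord], marker: str,
                   standardize: bool) -> np.ndarray:
    v = np.array([p.markers[marker] for p in patients], dtype=float)
    if standardize and v.size and np.std(v) > 0:
        v = (v - v.mean()) / v.std()
    return v


def _assoc_pvalue(pats: Sequence[PatientRecord], marker: str,
                  cfg: ScreenConfig) -> LrtResult:
    """Marker-vs-pCR association within one patient set (marker effect LRT)."""
    y = np.array([p.pcr for p in pats], dtype=float)
    if len(pats) < 4 or len(set(y)) < 2:
        return LrtResult(float("nan"), 1, float("nan"), float("nan"), stable=False)
    v = _marker_matrix(pats, marker, cfg.standardize)
    n = len(pats)
    X_red = np.ones((n, 1))
    X_full = np.column_stack([X_red, v])
    return logistic_lrt(y, X_full, X_red)


def _interaction_pvalue(pats: Sequence[PatientRecord], marker: str,
                        treat: np.ndarray, adjust_hr: bool,
                        cfg: ScreenConfig) -> LrtResult:
    y = np.array([p.pcr for p in pats], dtype=float)
    v = _marker_matrix(pats, marker, cfg.standardize)
    n = len(pats)
    cols = [np.ones(n), v, treat]
    if adjust_hr:
        cols.append(np.array([float(p.hr) for p in pats]))
    X_red = np.column_stack(cols)
    X_full = np.column_stack(cols + [v * treat])
    return logistic_lrt(y, X_full, X_red)


def screen_markers(
    patients: Sequence[PatientRecord],
    experimental_arm_id: str,
    markers: Optional[Sequence[str]] = None,
    cfg: Optional[ScreenConfig] = None,
) -> list[MarkerResult]:
    """Run the full screen over the marker panel.

    ``patients`` must have passed the evaluability filter with every outcome
    coded (pending patients are coded non-pCR per protocol for biomarker
    analyses before calling, or dropped).  Output order follows the marker
    list; results are invariant to patient and marker ordering beyond that.
    """
    cfg = cfg or ScreenConfig()
    pats = [p for p in patients if p.pcr is not None and p.markers]
    if markers is None:
        common = set.intersection(*(set(p.markers) for p in pats)) if pats else set()
        markers = sorted(common)
    arm_pats = [p for p in pats if p.arm_id == experimental_arm_id]
    ctl_pats = [p for p in pats if p.arm_id != experimental_arm_id]
    treat = np.array([float(p.arm_id == experimental_arm_id) for p in pats])

    results: list[MarkerResult] = []
    for m in markers:
        r_arm = _assoc_pvalue(arm_pats, m, cfg)
        r_ctl = _assoc_pvalue(ctl_pats, m, cfg)
        r_int = _interaction_pvalue(pats, m, treat, adjust_hr=False, cfg=cfg)
        r_int_hr = _interaction_pvalue(pats, m, treat, adjust_hr=True, cfg=cfg)
        tn_arm = [p for p in signature_members(_TN_SIG, arm_pats)]
        hp_arm = [p for p in signature_members(_HRPOS_SIG, arm_pats)]
        r_tn = _assoc_pvalue(tn_arm, m, cfg)
        r_hp = _assoc_pvalue(hp_arm, m, cfg)
        notes = []
        if not r_arm.stable or not r_ctl.stable or not r_int.stable:
            notes.append("unstable fit (separation or single outcome class)")
        if math.isnan(r_tn.p_value):
            notes.append("TN subset not estimable")
        if math.isnan(r_hp.p_value):
            notes.append("HR+/HER2- subset not estimable")
        results.append(MarkerResult(
            marker=m,
            p_arm=r_arm.p_value,
            p_control=r_ctl.p_value,
            p_interaction=r_int.p_value,
            p_interaction_hr_adjusted=r_int_hr.p_value,
            p_subset_tn=r_tn.p_value,
            p_subset_hrpos_her2neg=r_hp.p_value,
            direction=r_arm.direction,
            qualifies=MarkerResult._qualifies(
                r_arm.p_value, r_ctl.p_value, r_int.p_value, cfg.alpha),
            notes="; ".join(notes),
        ))

    if cfg.bh_correct:
        _apply_bh(results, cfg.alpha)
    return results


def _apply_bh(results: list[MarkerResult], alpha: float) -> None:
    """Benjamini-Hochberg on the interaction p-values; re-flags qualifiers."""
    ps = np.array([r.p_interaction for r in results])
    ok = ~np.isnan(ps)
    if not ok.any():
        return
    order = np.argsort(ps[ok])
    n = ok.sum()
    passed = np.zeros(len(results), dtype=bool)
    idx = np.flatnonzero(ok)[order]
    thresh = alpha * (np.arange(1, n + 1) / n)
    below = ps[idx] <= thresh
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        passed[idx[: kmax + 1]] = True
    for r, ok_bh in zip(results, passed):
        r.qualifies = r.qualifies and bool(ok_bh)


def results_frame(results: Sequence[MarkerResult]) -> pd.DataFrame:
    """Dot-plot style table: one row per marker, one column per analysis."""
    return pd.DataFrame(
        {
            "marker": r.marker,
            "p_arm": r.p_arm,
            "p_control": r.p_control,
            "p_interaction": r.p_interaction,
            "p_interaction_hr_adjusted": r.p_interaction_hr_adjusted,
            "p_subset_tn": r.p_subset_tn,
            "p_subset_hrpos_her2neg": r.p_subset_hrpos_her2neg,
            "direction": r.direction,
            "qualifies": r.qualifies,
            "notes": r.notes,
        }
        for r in results
    )
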