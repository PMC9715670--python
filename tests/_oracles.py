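"""Independent brute-force oracles shared by the unit and acceptance suites.

Everything here is deliberately written in a different style from the
implementation under test: per-patient Python loops, scipy densities and the
increment form of the drift prior, with no shared code paths.
"""

import math

import numpy as np
from scipy.special import expit
from scipy.stats import bernoulli, invgamma, norm


def brute_force_log_posterior(params, patients, analysis_day, tm_cfg, model_cfg,
                              control_arm_id="control"):
    lp = 0.0
    lrs = [
        math.log(p.ftv[-1][1] / p.ftv[0][1])
        for p in patients
        if p.pcr is not None and len(p.ftv) >= 2
    ]
    mu_z, sd_z = (np.mean(lrs), np.std(lrs)) if len(lrs) >= 2 else (0.0, 1.0)
    for p in patients:
        x = [1.0, float(p.hr), float(p.her2), float(p.mp2)]
        eta = sum(a * b for a, b in zip(x, params.baseline))
        if p.arm_id != control_arm_id:
            eta += sum(a * b for a, b in zip(x, params.arm_effects[p.arm_id]))
        t = math.ceil(max(analysis_day - p.rand_day, 1) / tm_cfg.bin_width)
        if t > tm_cfg.free_recent_bins:
            field = params.delta_plus if p.her2 else params.delta_minus
            eta += field.delta[t - 1]
        if p.pcr is not None:
            lp += bernoulli.logpmf(p.pcr, expit(eta))
            if len(p.ftv) >= 2:
                z = (math.log(p.ftv[-1][1] / p.ftv[0][1]) - mu_z) / sd_z
                lp += bernoulli.logpmf(
                    p.pcr, expit(params.impute[0] + params.impute[1] * z + eta)
                )
    for coef in params.baseline:
        lp += norm.logpdf(coef, 0, model_cfg.prior_sd)
    for g in params.arm_effects.values():
        for coef in g:
            lp += norm.logpdf(coef, 0, model_cfg.prior_sd)
    for coef in params.impute:
        lp += norm.logpdf(coef, 0, model_cfg.impute_prior_sd)
    free = tm_cfg.free_recent_bins
    for field in (params.delta_minus, params.delta_plus):
        d = field.delta[free:]
        lp += norm.logpdf(d[0], tm_cfg.mu0, math.sqrt(tm_cfg.tau0_sq))
        if len(d) >= 2:
            lp += norm.logpdf(d[1] - d[0], tm_cfg.mu1, math.sqrt(tm_cfg.tau1_sq))
        for j in range(2, len(d)):
            lp += norm.logpdf(
                d[j] - 2 * d[j - 1] + d[j - 2], 0.0, math.sqrt(params.tau_sq)
            )
    lp += invgamma.logpdf(params.tau_sq, tm_cfg.ig_alpha, scale=tm_cfg.ig_beta)
    return lp
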