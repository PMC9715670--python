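# Methods

`platformtrial` implements the analysis engine of a Bayesian adaptive
platform trial for neoadjuvant breast-cancer therapy with a binary pathologic
complete response (pCR) endpoint. This note records the model, the
assumptions behind it, the numerical choices, and what the synthetic-data
tests do and do not establish.

## The outcome model

Patients are classified by three binary baseline markers — hormone-receptor
status (HR), HER2 status and the dichotomized MammaPrint risk stratum
(MP1 high / MP2 ultra-high) — into 8 subtypes. For patient *i* the pCR
probability is modelled as

    logit P(pCR_i = 1) = β·x_i + 1[arm_i ≠ control]·(γ_{arm_i}·x_i) + δ_{h_i}(t_i)

with

* x_i = (1, HR_i, HER2_i, MP2_i), 0/1 coding (positive / MP2 = 1);
* β the control-arm baseline (intercept + three main effects);
* γ_a the per-arm treatment effect: an arm main effect plus HR/HER2/MP2
  effect modifiers (a configuration switch replaces this with a saturated
  8-cell per-subtype arm effect);
* δ_h(t) the HER2-stratified calendar drift offset ("time machine").

All regression coefficients have weakly informative N(0, 2²) priors on the
log-odds scale. The regression structure is a reconstruction: the production
trial publishes only the drift system and the statement that HR, HER2 and
MammaPrint enter as covariates. The main-effects-with-modifiers form is the
smallest model that produces subtype-specific treatment effects for
signature-level decisions; it is documented as such and switchable.

A second switch (`drift_on_treatment_only`) implements the alternative
reading in which δ enters only experimental-arm predictors. The default is
shared drift across arms, because the drift term exists to bridge control
eras: it adjusts outcome levels over time within every arm.

## The time machine

At every analysis, time is reset so "now" is day 0 and the past is cut into
90-day bins (bin 1 = days 0–90 before present, with a day exactly on an edge
belonging to the more recent bin; a patient randomized 750 days before
present falls in bin 9). Each HER2 stratum has offsets δ(t) with

    δ(1) = … = δ(4) = 0
    δ(5) ~ N(μ0, τ0²)
    δ(6) − δ(5) ~ N(μ1, τ1²)
    δ(t) − 2δ(t−1) + δ(t−2) ~ N(0, τ²)   for t > 6
    τ² ~ IG(α, β)

with μ0 = μ1 = 0, τ0² = τ1² = 0.001, α = 1, β = 0.001. IG is the
shape–scale inverse gamma (density ∝ x^−(α+1) e^−β/x) — the standard
convention in this literature; this choice changes the numerics and is
therefore stated prominently. τ² is shared between the two HER2 strata by
default (`shared_tau=False` gives each stratum its own conjugate update).

Two consequences of these hyperparameters matter for interpretation:

* the most recent year counts fully (four pinned bins), and
* the level and slope anchors are *tight* (sd ≈ 0.03), so the field is
  shrunk toward the zero line and can deviate only through accumulated
  curvature whose scale τ² is learned from the data. Drift that jumps
  discontinuously at the recent boundary is essentially inexpressible under
  this prior; smooth drift over several bins is cheap. The drift-absorption
  test scenario was designed accordingly (see below).

When bins of varying `free_recent_bins` are configured, the level anchor
attaches to the first free bin and second differences begin two bins later,
extrapolating the printed t > 6 rule proportionally.

The joint prior over the free offsets is represented exactly as a banded
(bandwidth-2) precision matrix — the increment map has unit determinant, so
the density also equals the product of the increment normals; both routes
are computed and cross-checked in the tests, and a Kalman/RTS smoother on
the equivalent local-linear state space reproduces the banded-solve
posterior on Gaussian toy observations.

## Evaluability and pending outcomes

The modified intent-to-treat rule: patients who never received allocated
therapy are excluded; patients who switched to non-protocol therapy,
withdrew, or have no recorded surgery are coded non-pCR (deviations override
a recorded outcome, matching the protocol's treatment of, e.g., off-protocol
carboplatin); patients with surgery and an observed outcome keep it. Anyone
else — still on treatment at an interim — is *pending*, a first-class state.

Pending outcomes are multiply imputed inside the sampler. For a pending
patient with at least one post-baseline MRI, the imputation distribution is

    pCR ~ Bernoulli( ilogit( w0 + w1·z + η ) )

where z is the standardized log ratio of latest to baseline functional tumor
volume (FTV; standardization constants come from completers) and η is the
patient's current linear predictor; without FTV the model rate ilogit(η) is
used. The coefficients (w0, w1) carry N(0, 2²) priors and are updated
against completers that have both an observed outcome and FTV. This is a
modularized ("cut") imputation — the imputed outcomes feed the main
likelihood as data, but the submodel's completer likelihood does not feed
back into β — standing in for the trial's full longitudinal model, whose
specification is not public. Only the latest FTV ratio is used, not the
4-point trajectory: it is the simplest submodel identifiable from the
generator. Zero FTV volumes (complete radiologic response) are floored at
10⁻⁶ with a warning rather than producing infinite ratios.

## Posterior computation

No probabilistic-programming backend is assumed; the sampler is a
seed-deterministic adaptive Metropolis-within-Gibbs written for this model:

* **Regression block** (β and all γ jointly): a penalized-IRLS Laplace
  approximation is computed once at startup; odd iterations take
  preconditioned random-walk steps (proposal covariance = Laplace
  covariance, scalar scale adapted toward 0.3 acceptance during warmup),
  even iterations take independence-Metropolis proposals from the inflated
  Laplace Gaussian. The alternation keeps the chain correct if the Laplace
  fit is poor and near-independent when it is good.
* **Drift fields**: non-centered parameterization — each stratum's free
  offsets are built from iid N(0,1) innovations u scaled by (τ0, τ1, τ).
  This avoids the funnel in which a centered field pinned near zero keeps
  the conjugate τ² draw collapsed (and vice versa).
* **τ²**: an ancillarity–sufficiency interweaving pair — the conjugate
  inverse-gamma Gibbs draw given δ (shape α + k/2, scale β + ½Σ(second
  differences)², k = number of second differences), followed by a log-scale
  Metropolis step holding u fixed so the whole field can rescale in one move.
* **Imputation coefficients**: 2-dimensional adaptive random walk against
  the completer submodel (a direct prior draw when no completer has FTV).
* **Pending outcomes**: refreshed from the imputation distribution every
  sweep.

All adaptation freezes after warmup (default 500 warmup, 1000 kept draws).
Diagnostics report per-block acceptance rates and effective sample sizes
(arviz); a `warn` status is attached, never an exception, when ESS < 50 or
acceptance leaves [0.05, 0.80]. Typical arm-effect ESS is ~250 per 1000
draws at n ≈ 230.

Derived per-signature pCR rates average ilogit(η) over the empirical
covariate distribution of all enrolled patients in the signature at drift
offset 0 (present-day rates), with the arm set counterfactually; the same
paired draws feed the superiority and predictive-probability calculations.
With no enrolled patients in both arms the sampler returns prior draws and
labels the result accordingly.

## Decisions

* **Pr(superiority)** per (arm, signature): fraction of paired draws with
  the arm's rate strictly above control.
* **Predictive probability of phase-3 success**: for each posterior draw
  (p_e, p_c), the exact probability that a 1:1 trial of 300 patients rejects
  H0: p_e ≤ p_c with a one-sided pooled two-proportion z-test at α = 0.025,
  computed by full enumeration of the binomial grid (a 151×151 rejection
  mask contracted with the two pmfs — exact, fast, and NaN-free at
  degenerate rates); the predictive probability is the average over draws.
  The protocol never defines "success"; the pooled z-test is the
  conventional reading and a configuration point.
* **Actions**, in strict precedence: graduate if any signature's predictive
  probability ≥ 0.85; else futile if all are < 0.10; else stop at the accrual
  cap; else continue. An optional minimum per-signature enrollment gate
  (default 0) can hold back graduation.
* **Adaptive randomization**: control receives exactly 20%; experimental
  arms open to the patient's subtype share the remaining 80% proportionally
  to their subtype-restricted superiority probabilities, floored at 0.01 so
  no arm is starved. With no eligible experimental arm the control receives
  everything. The exact production formula is unpublished; the floor and the
  proportional rule are this package's choices.

The trial evaluates ten HR/HER2/MammaPrint signatures; only three are named
in the published arm (HER2−, TN, HR+/HER2−), so the default ten-entry
catalogue is a reconstruction and fully configurable.

## Biomarker screen

Eighteen pre-specified expression markers are screened for arm-specific
association with pCR by logistic likelihood-ratio tests (LRT): within-arm,
within-control, pooled with a marker×treatment interaction, an HR-adjusted
interaction variant, and receptor-subset (TN, HR+/HER2−) analyses. A marker
qualifies when p_arm < 0.05, p_control ≥ 0.05 and p_interaction < 0.05, with
no multiplicity correction (the published screen uses raw p < 0.05; an
optional Benjamini–Hochberg flag tightens it). Markers are standardized
before fitting; fits use Newton MLE with perfect separation detected and
reported as unstable (NaN p), and subsets with a single outcome class are
marked not estimable. The published enumeration of the panel yields 17
distinct quantities against a stated count of 18; the default panel adds
HSPA1B (an HSP70-family member) to reach 18 and the panel is configurable,
so nothing depends on this reconstruction. The HSP90/HSP70 ratio composite
is consumed as a precomputed value (log-scale difference), as are the three
signature scores (PARPi7, Module11 proliferation, LI immune), whose
gene-level formulas are out of scope.

## The synthetic generator

The generator emulates the data structure the engine assumes: homogeneous
Poisson accrual (drift lives in outcome rates, not enrollment speed), the 8
subtypes with configurable prevalence, arm- and subtype-specific true pCR
rates on the log-odds scale, piecewise-linear calendar drift per HER2
stratum, protocol deviations (never treated / switched / withdrew / no
surgery) as independent Bernoulli events, lognormal consent-to-surgery
delays (median 165 days, log-sd 0.22 — chosen to reproduce the published
71–250 day range at the published sample size), 4-point log-FTV trajectories
with a pCR-linked shrinkage slope plus measurement noise, and per-patient
marker values with optional per-arm effects on the true log-odds. Every
patient draws from a counter-based substream keyed by (seed, patient index),
with markers on a separate substream, so panel changes and added draws never
perturb other patients; identical seeds give byte-identical trials. A truth
ledger records each patient's latent log-odds components and true pCR
probability under control and under every arm.

Closed-loop randomization uses running Beta–Binomial posteriors per
(arm, subtype) for the superiority weights (Monte-Carlo with 256 paired
draws per assignment) rather than refitting the full model at every
enrollment; outcomes update the weights immediately rather than after the
surgery delay. The control share — the quantity the allocation rule fixes —
is unaffected by either simplification.

What the generator does **not** emulate: site effects, accrual seasonality,
outcome-dependent dropout, assay batch structure, correlated marker panels,
RCB grading, or survival endpoints beyond the fields needed for
completeness. Green tests on synthetic trials therefore establish internal
consistency (the engine recovers what the generator planted, at the stated
uncertainty) — not agreement with the published arm's posterior numbers,
which require the non-public patient-level data.

### The drift-absorption scenario

The stress test for the time machine injects a +0.5 log-odds drift with a
null treatment effect. Under the stated prior, a step change at the recent
bin boundary cannot be absorbed (the level and slope anchors forbid it), and
a drift era too close to the present is not identified (too few concurrent
controls anchor the intercept, so the posterior rationally prefers a shifted
intercept over a nonzero field). The scenario therefore uses a 1440-day
window: controls accrue throughout, the experimental arm opens at day 810,
and the drift is flat at +0.5 through day 630, descending quadratically to
zero by day 810 — smooth curvature in the old bins, exactly the shape the
second-order NDLM is built to express. With the drift field on, the
arm-effect posterior is centred near zero and covers it; with the field
ablated, pooling the elevated old controls biases the estimated arm effect
downward by ≈ −0.3 log-odds. Because a single ~430-patient trial has
posterior-mean noise comparable to that bias, the test aggregates six fixed
replicate seeds and asserts the aggregate pattern.

## Numerical details and degenerate inputs

* Bin arithmetic uses ceil(days/90) with day 0 mapping to bin 1; a day on a
  bin edge belongs to the more recent bin.
* `ndlm_prior` with no free bins returns an empty field; τ² sampling with no
  second difference returns a prior draw.
* The phase-3 rejection grid sets z = −∞ when the pooled variance is zero
  (all successes or all failures), so degenerate posterior draws at 0 or 1
  produce exact 0/1 powers, never NaN.
* `prob_superiority` uses a strict inequality; ties count against the arm.
* Logistic LRT statistics are clipped at 0 (nested optima can cross by
  rounding); constant marker columns yield statistic 0, p = 1.
* The evaluability filter is idempotent and reports a coding audit whose
  counts partition the retained records.

## Known limitations

* The regression form, signature catalogue, randomization formula, phase-3
  success test and imputation submodel are declared reconstructions of
  unpublished machinery; each is a configuration point.
* The sampler is exact-in-the-limit MCMC but single-chain; R-hat across
  chains is not computed (ESS and acceptance monitoring stand in).
* The cut imputation is not a fully joint Bayesian treatment of pending
  outcomes; with heavy pendency the arm-rate posteriors inherit the
  submodel's stand-in status.
* Closed-loop operating characteristics at reduced scale (small n, few
  replicates) are regression metrics for this engine, not estimates of the
  production trial's operating characteristics.
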