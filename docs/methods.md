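# Methods

This note documents the models behind `prevsim`, the defaults and why they
were chosen, the numerical choices, and what the simulations do and do not
establish about real trials.

## Hazard scenarios

All worlds use a constant baseline hazard on the month scale, calibrated from
the placebo cumulative risk *p* over the follow-up horizon *T*:
λ = −ln(1 − p)/T. Times are in months, rates in events/month. The survival
function implied by any scenario starts at 1 and is non-increasing; the
calibration is exercised by a forward-simulation round trip in the tests.

### Treatment-effect layers

**Constant HR.** Proportional hazards with one ratio; efficacy is reported as
(1 − HR)·100 throughout.

**Distributed individual effect.** Each subject carries a latent modifier
Uᵢ ~ N(0, 1) and an individual log HRᵢ = a + b·Uᵢ, applied only under
treatment. The convention is that larger modifier values mean stronger
efficacy, so b ≤ 0. Given target mean efficacies in the lower and upper tail
(default tail mass 0.15), the truncated-lognormal mean gives closed forms

    E[HR | U in lower tail] = e^{a+b²/2} Φ(z_c − b)/Φ(z_c),
    E[HR | U in upper tail] = e^{a+b²/2} Φ(z_c + b)/Φ(z_c),

with z_c = Φ⁻¹(tail); b solves a monotone one-dimensional root (Brent,
xtol 1e−12) and a follows. Both constraints are re-verified to 1e−6 after
solving, and independently against numerical quadrature in the tests. The
default anchors (33% / 74% at the 15% tails) give a population-mean efficacy
of ≈ 57%, strictly between the tail values.

**Binary subgroup effect.** Strong/weak responders with separate HRs. This
fourth kind exists because interaction-power questions are posed for a
*binary, observed* modifier ("half strong, half weak responders"); the
continuous distributed effect cannot express that. The responder fraction is
applied *exactly* (permuted labels within each arm) rather than drawn
binomially: the half-and-half composition is part of the stated scenario, not
a source of Monte-Carlo noise. With binomial assignment the interaction power
at the n = 1000 design is about 2 percentage points lower.

**Time-varying HR.** log HR(t) interpolates linearly between (0, hr_start)
and (end_time, hr_end) — the simplest monotone curve through both anchors —
and is held constant beyond end_time.

### Frailty

Unobserved heterogeneity in progression risk is a multiplicative gamma
frailty with mean 1 and variance θ (default θ = 1). Gamma is the standard
conjugate choice for multiplicative frailty; the variance is configurable
and 0 degenerates exactly to homogeneity. A defining consequence — and a
regression test — is attenuation of the marginal hazard ratio: with a
constant conditional HR of 0.5 and θ = 1, the population-averaged HR
estimated from events after month 48 is visibly closer to 1 than the one
from events before month 24 (≈ 0.74 vs ≈ 0.55 at n = 100,000), because
high-frailty placebo subjects are depleted faster.

### Event-time generation

With a time-constant subject multiplier c the latent time is exponential
with rate λc. Under a time-varying HR the cumulative hazard is accumulated
on a piecewise-exponential grid (default width 1 month, hazard evaluated at
interval midpoints), extended analytically at the final hazard beyond the
grid, and inverted exactly on the grid. A grid-refinement test (1 month vs
0.05 months on common uniforms) bounds the discretisation error at a
fraction of a month, and the implied 84-month survival agrees with
numerical quadrature of exp(−∫λ(u)HR(u)du) within Monte-Carlo error.

### TN10-like defaults

The four illustrative scenario worlds (`tn10_like`) use n = 76, horizon 84
months, placebo cumulative risk 0.9 (placebo median ≈ 25 months, in the
range observed for stage 2 disease), HR 0.5, frailty variance 1 where a
frailty layer is present, and uniform(6, 84)-month censoring to emulate
staggered follow-up from under 6 months to 7 years. These anchors are
package choices — they produce arm medians and CI widths of realistic
magnitude — and every one is configurable. Power-engine scenarios default
to administrative censoring at the horizon only (complete compliance, no
loss to follow-up), which is the standard idealisation for sample-size
tables.

## Effect measures

- **Kaplan–Meier** with Greenwood CIs comes from lifelines; a pointwise
  coverage simulation keeps it honest. Bootstrap internals use a fast numpy
  product-limit helper validated against lifelines.
- **Cox HR** is fitted by an in-package Newton–Raphson partial-likelihood
  solver (Efron ties by default, Breslow available) because the Monte-Carlo
  engines need thousands of fits per run. It is verified against lifelines
  (coefficients and standard errors to 1e−6, including tied data) and
  against brute-force likelihood maximisation on exhaustive ≤ 5-subject
  datasets. Monotone likelihoods (no events in an arm) are returned as
  flagged non-finite estimates, never exceptions.
- **Risk ratio** of incidence proportions with the delta-method log-scale CI,
  SE = √(1/a − 1/n_T + 1/b − 1/n_P).
- **Median difference**: medians read off the KM curve where it first drops
  to ≤ 0.5 (undefined medians propagate as flags, never numbers); percentile
  bootstrap CI (default B = 1000), resampling stratified by arm.
- **RMST difference** at τ: area under each KM curve to τ; CI by the same
  stratified percentile bootstrap for uniformity with the median difference,
  with a Greenwood-type plug-in variance (asymptotic) option. The lifelines
  `return_variance` output is the population variance of min(T, τ), not the
  estimator variance, so the plug-in formula is implemented here.
- **Interaction**: Wald test of the treatment×modifier term in a Cox model
  with both main effects.

## Power engine

Power is the fraction of replicates with p < α; the Monte-Carlo standard
error is √(p̂(1−p̂)/R). The primary two-arm efficacy test is the log-rank
(score) test — the standard trial primary; a vectorised numpy kernel is used
inside the loop and matches lifelines to relative 1e−9. Wald tests from the
proportional-hazards model are used where a model term is the target
(interaction, factorial main effects from the additive model, factorial
interaction from the saturated model at α = 0.025). Replicates default to
2000; per-replicate generators are spawned from the master seed via
`SeedSequence`, so results are independent of execution order.

Sample-size search evaluates a user grid (sorted ascending) and returns the
smallest n whose estimated power reaches the target, together with the whole
power curve; an unreachable target returns the curve with a flag rather than
an error. Because simulated power has Monte-Carlo noise and published sample
sizes are rounded, selected n should be read with the grid step and ±2–3
MC SE in mind.

Two closed forms serve as cross-checks, not as the engine: the Schoenfeld
approximation Φ(|log HR|·√(D/4) − z₁₋α/₂) with D the expected event count,
and a delta-method prediction for interaction power from expected
cell-level event counts. Simulated power tracks both within 0.03–0.05 in
the regimes tested.

Multiplicity over trial outcomes uses Bonferroni (α/k, e.g. 0.05/3 = 0.0167
for a three-outcome primary-prevention trial); interaction tests use
α = 0.025 since they come on top of the overall efficacy test.

## Endotype discovery simulation

The cohort draws m independent standard-normal factors per subject and three
competing cause-specific exponential times with hazards λₑ·exp(Σⱼ βₑⱼxⱼ);
the earliest event inside follow-up fixes the (unique) endotype, so
endotypes are mutually exclusive and, with equal λₑ, equally common. The
effect matrix is deterministic: factors 1–9 endotype-specific (three per
endotype), 10–15 shared, the rest null; every true coefficient is ln 2
(HR 2.0 per SD).

The per-endotype rate is calibrated to a target expected case count by
inverting E[1 − exp(−λ·S·T)] over a fixed internal Monte-Carlo sample of the
true-factor multipliers S (200,000 draws, fixed internal seed, Brent root) —
the naive rare-disease formula underestimates the needed correction because
S is heavy-tailed (E[S] ≈ 26 with nine ln-2 coefficients per endotype). The
default cohort size is 20,000 with follow-up normalised to 1; only expected
case counts matter downstream, so cohort scale is a free parameter.

Association testing uses the score test of a single-covariate logistic model
(U = Σxᵢ(yᵢ−ȳ), V = ȳ(1−ȳ)Σ(xᵢ−x̄)²), chosen because it is asymptotically
equivalent to the Wald test yet needs no iteration, so all m factors are
tested in one vectorised pass; its null p-values are uniform by a KS check.
Endotype-specific outcomes compare that endotype's cases against *all*
controls; the composite compares all cases with all controls. BH runs
jointly over the full o×m matrix (statsmodels step-up, verified against an
exhaustive cutoff search), taking the multiplicity burden of a strategy
literally: 1×m, 2×m or 4×m tests. Discovery is scored at the factor level —
a factor counts once no matter how many outcomes flag it — and realized FDR
is FP/(FP+TP) with 0/0 → 0.

A retrospective rare-disease shortcut (cases' factors drawn from
N(βₑⱼ, 1), the exponential tilt of the standard normal; Poisson case count)
is provided as a fast path and validated against the full cohort path in
the tests (case-factor means and discovery power agree within Monte-Carlo
error). The cohort path remains the default and is what the acceptance
script uses.

## Problem sizes used

The shipped test suite and acceptance script run everything on one CPU:
power estimates use 2000–10,000 replicates (the upper range where 1–2
percentage points matter), large-sample recovery checks use 50,000–200,000
subjects, and the endotype comparisons use 200–300 replicates of a 20,000
cohort. These sizes give Monte-Carlo standard errors of about 0.3–1
percentage point on power and 1–2 points on realized FDR.

## What passing tests do and do not show

The generators implement idealised worlds: exponential (or piecewise-
exponential) event times, perfect compliance, censoring independent of
everything, factors exactly standard normal and independent, effects exactly
log-linear, endotypes measured without error. Passing tests show the
machinery is correct under those assumptions — they do not show that real
trials achieve the tabulated power (dropout, staggered accrual,
non-proportional hazards and weaker, correlated, mismeasured risk factors
all reduce it). The discovery simulation in particular uses deliberately
strong effects (HR 2.0 per SD); with realistic effect sizes, power is far
lower and the multiplicity penalties bite harder.

## Known limitations

- Only gamma frailty; no cure fraction, no informative censoring, no accrual
  calendar, no non-compliance, no adaptive or group-sequential designs.
- The distributed-effect modifier influences only the treatment effect, not
  baseline risk; modifier and frailty are independent by default.
- Factorial designs are limited to 2×2 with 1:1:1:1 allocation.
- Endotype factors are independent and linear on the log-hazard scale;
  correlated or mismeasured exposures are out of scope.
- Median differences are undefined whenever a KM curve stays above 0.5; such
  runs are flagged and excluded from bootstrap summaries, which slightly
  biases CI width comparisons at very small n.
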