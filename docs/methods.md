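# Methods

## The problem being simulated

In cohort studies with a time-varying dichotomous exposure (unexposed
until a possible one-time switch, exposed thereafter), classifying the
pre-switch period as unexposed person-time prevents immortal time
bias. A Poisson log-linear model with a log person-time offset is a
common way to estimate the exposure rate ratio from that layout, but
it assumes the baseline event rate is constant over follow-up. When
the hazard trends — and exposure, by construction, accrues later in
follow-up — exposed person-time samples a different phase of the
baseline risk than unexposed person-time, and the crude rate ratio is
biased even though immortal time was handled correctly. This package
simulates that mechanism exactly and measures the bias and its
remedies.

## Data-generating model

Baseline event times are Weibull with hazard h0(t) = λυt^(υ−1) and
survival S0(t) = exp(−λt^υ). In this rate-scale parameterization
υ = 1 reduces to the exponential with rate λ, which is what the
constant-hazard scenario A (λ = 0.1, υ = 1) requires; scenario B
(λ = 0.75, υ = 0.33) has a sharply decreasing hazard and scenario C
(λ = 1e−5, υ = 7) a sharply increasing one. (The alternative
"characteristic-life" convention S(t) = exp(−(t/λ)^υ) would make
these same numerals produce degenerate cohorts — essentially no
events in B, all events instantaneous in C — so the rate-scale
convention is the one under which the scenario definitions are
coherent.)

Exposure-switch times E come from one of two schemes:

* `uniform` (default): E ~ Uniform(0, 10) for every subject. With
  censoring at 5, roughly half of potential switches fall after
  follow-up ends, giving a realized exposure prevalence near 20%.
* `binomial_gamma`: a Bernoulli(p) draw decides ever-eligibility;
  eligible subjects get E ~ Gamma(shape, scale = 0.1), so the mean
  time to exposure is shape/10, swept over 0–5 via shape 0–50.
  shape = 0 is the degenerate exposed-from-baseline endpoint.
  Realized prevalence is below p because late switches are truncated
  by events and censoring; the replicate engine reports it.

If E precedes the latent baseline event time, a new event time T > E
is drawn from the conditional distribution given survival to E with
hazard RR_T·h0(t) for t > E, by inverting the conditional survival in
closed form: T = (E^υ − ln U/(RR_T·λ))^(1/υ). The clock is not
reset, so the proportional-hazards contract — exposure multiplies the
current hazard by exactly RR_T — holds by construction; an alternative
reading ("redraw an unconditional time from the switch") would reset
the baseline clock and break proportional hazards for υ ≠ 1, making
the "constant exposure effect" premise undefined, and is therefore not
used. RR_T is a hazard ratio; under a constant hazard it coincides
with the rate ratio the Poisson model estimates, which is the only
reading under which a time-constant effect is well defined for Weibull
hazards.

Follow-up is administratively censored at 5 time units. Exposure is
recorded on the subject only when the switch occurs strictly before
the end of follow-up, so immortal person-time classification is always
explicit in the episode layout.

## Person-time bookkeeping

Each subject becomes one or two (start, stop] episodes of constant
exposure state; the event flag sits on the episode ending at the event
time. Splitting at follow-up cutpoints uses half-open intervals
[c_k, c_{k+1}) with the convention that an event exactly at a cutpoint
stays with the earlier fragment (the event happens *at* stop). Exact
ties are measure-zero in the continuous simulation but possible in
floating point. Person-time is conserved exactly under every split,
and aggregation to (exposure × interval) cells yields the sufficient
statistics for all Poisson fits.

Default cutpoints for the piecewise model are quantiles of the
observed event times with K = 10 intervals: event-time quantiles put
resolution where the events (and hence the information about the
baseline rate) are, and K is exposed as a parameter everywhere it is
used.

## Estimators

* Crude Poisson: closed form (d1/PT1)/(d0/PT0) with log-scale SE
  √(1/d1 + 1/d0); this is the exact MLE of the two-cell Poisson model
  with offset, and serves as the oracle for the iterative fit.
* Poisson GLM (statsmodels, Poisson family, log person-time offset)
  on aggregated cells, with interval indicators when adjusted.
  Intervals with zero events would push their indicator to −∞; their
  cells are dropped, which equals the profiled likelihood, with a
  warning.
* Cox with a binary time-varying covariate: Breslow partial
  likelihood written in-package. Because the covariate is 0/1 the
  risk-set sums reduce to at-risk counts per exposure state at each
  event time, computed once by sorting; Newton iteration with
  step-halving then costs O(events) per step (gradient tolerance
  1e−8, max 50 iterations). A monotone likelihood — the exposed event
  count at or beyond what the risk sets can support at either
  boundary — is detected up front and reported as a 0/∞ estimate with
  `converged_ = False` rather than a spuriously "converged" huge
  coefficient.
* Kaplan–Meier via lifelines.

Confidence intervals are 95% Wald on the log scale throughout.
Zero-event exposure margins yield 0/∞ estimates with non-finite SE and
a failure flag — never a continuity correction, which would silently
shift replicate medians; the replicate engine excludes flagged fits
and reports their count per cell.

## Replicates, seeding, problem sizes

The study conditions are 1,000 replicate cohorts of n = 10,000 per
scenario cell, with medians (and quartiles) over finite estimates as
the summary. Medians at this design are stable to roughly ±0.01 with
200 replicates, which is the size used by the test suite and the
reproduction script so a full run stays in the minutes range on one
CPU; `n_replicates` scales any sweep back up to 1,000.

Randomness: replicate r of a configuration uses the r-th spawned child
of `SeedSequence(seed)`, so replicates are independent and identical
regardless of execution order or parallelism. Within a cohort every
subject consumes a fixed block of four uniforms (eligibility, switch
time, baseline event, conditional event), drawn row-major, so growing
a cohort never reshuffles earlier subjects. Sweep cells derive child
seeds from the master seed by spawn index. Uniform draws are clamped
to [1e−12, 1−1e−12] before inversion; powers t^υ are evaluated in log
space so extreme shapes (υ = 7 with λ = 1e−5) neither overflow nor
underflow.

## What the generator does and does not emulate

The generator reproduces the mechanism of interest — a trending
baseline hazard with late-accruing exposure under exact proportional
hazards — and nothing else. There is no confounding (exposure is
assigned independently of risk), no competing risks, no time-varying
exposure effect, at most one exposure switch, no left truncation, and
censoring is purely administrative. Passing tests therefore show that
the estimators behave as the theory predicts under these clean
conditions; they do not certify performance on real cohorts, where
confounding and informative censoring can dominate and where the Cox
and piecewise-Poisson "remedies" only fix the rate-trend problem, not
design problems.

## Known limitations and observed behavior

* The piecewise Poisson model removes the bias only as well as its
  interval resolution allows. With K = 10 event-quantile intervals it
  recovers the true RR to within ~0.02 under the decreasing hazard of
  scenario B, but under scenario C's very steep t^6 hazard a residual
  upward bias of ~0.04 remains (shrinking to ~0.016 at K = 20): the
  model nests the truth only as K grows, and most of the residual
  distortion lives in the long, hazard-heterogeneous first interval
  that event-time quantiles do not subdivide. The Cox model, which
  needs no rate-constancy assumption, recovers the truth in both
  scenarios.
* The log-scale bias of the crude Poisson estimate is nearly constant
  across true effects in scenario B (spread < 0.1 over RR_T ∈ [0.5, 2])
  but visibly attenuates with RR_T in scenario C (from ≈ +0.99 at
  RR_T = 0.5 to ≈ +0.69 at RR_T = 2); "same direction at every true
  effect" holds everywhere, strict log-constancy only approximately.
* With exposure from time zero (gamma shape 0) there is no immortal
  time, yet the crude cumulative-rate ratio still differs from the
  hazard ratio under a non-constant hazard (≈ 0.68 in B and ≈ 0.80 in
  C for a true 0.75): rate ratios and hazard ratios only coincide
  when hazards are constant, a distinct and smaller effect than the
  deferred-exposure bias.
* Breslow tie handling only; ties are floating-point artifacts here.
  No robust variances, no covariates, no recurrent events.
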