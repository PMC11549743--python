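# immortaltime

Simulation toolkit for a question that recurs in pharmacoepidemiology:
when a cohort study handles **immortal time** correctly — splitting each
subject's follow-up into unexposed and exposed person-time with a
time-varying exposure — is the Poisson rate-ratio estimate of the
exposure effect then trustworthy? The answer is *no* whenever the
outcome hazard trends over time: the crude Poisson model assumes a
constant event rate, so exposure that accrues later in follow-up gets
compared against baseline person-time from a different risk regime.
`immortaltime` quantifies that bias and implements the two standard
remedies.

It is aimed at epidemiologists and biostatisticians who want to
reproduce or extend the bias study, probe their own scenario
configurations, or run the estimator suite on their own
counting-process tables.

## Model

Event times follow a Weibull proportional-hazards model,

```
h0(t) = λ υ t^(υ−1),        S0(t) = exp(−λ t^υ),
```

with λ > 0 a rate-scale parameter and υ > 0 the shape: the hazard
decreases over time for υ < 1, is constant (exponential) for υ = 1,
and increases for υ > 1. Three named scenarios fix (λ, υ):
A = (0.1, 1), B = (0.75, 0.33), C = (1e−5, 7). Each subject may switch
once from unexposed to exposed at a random time E (Uniform(0, 10) by
default, or Bernoulli(p) eligibility with a Gamma(shape, scale=0.1)
delay); from the switch onward the hazard is multiplied by the true
effect RR_T, implemented by inverse-CDF sampling of the residual event
time conditional on survival to E, so proportional hazards holds
exactly. Follow-up is administratively censored at 5 time units.

Estimators, all consuming the same (start, stop] episode layout:

* **crude Poisson** — rate ratio RR_P = (d1/PT1)/(d0/PT0), the MLE of
  the Poisson model with log person-time offset;
* **piecewise Poisson** — the same model plus indicators for K
  follow-up intervals cut at event-time quantiles (piecewise-
  exponential remedy, default K = 10);
* **Cox time-varying covariate** — Breslow partial likelihood,
  Newton-maximized in-package;
* **Kaplan–Meier** — product-limit survival curves of the scenarios.

Each scenario cell is summarized by the median RR over replicate
cohorts (study conditions: 1,000 replicates of n = 10,000).

## Worked example

```python
import immortaltime as it

cfg = it.scenario_config("B", rr_t=0.75, n_subjects=10_000, seed=1)
episodes = it.cohort_to_episodes(it.simulate_cohort(cfg))

crude = it.poisson_glm(episodes)
piecewise = it.poisson_glm(episodes, adjust_intervals=True, n_intervals=10)
cox = it.cox_tvc(episodes)
print(f"crude Poisson RR = {crude.rr:.3f}")
print(f"piecewise Poisson RR = {piecewise.rr:.3f}")
print(f"Cox TVC HR = {cox.rr:.3f}")
```

Output:

```
crude Poisson RR = 0.240
piecewise Poisson RR = 0.728
Cox TVC HR = 0.743
```

The true effect is 0.75. Under the decreasing hazard of scenario B the
crude Poisson estimate collapses to 0.24 — a protective effect three
times too strong — purely because exposed person-time accrues late in
follow-up when the baseline event rate has already fallen. The
interval-adjusted Poisson and the Cox model, which let the baseline
rate vary, both recover the truth to within Monte-Carlo error.

The same comparison at study scale, from the shell:

```bash
immortaltime sweep scenarios --reps 200 -e poisson -e poisson_adjusted -e cox -o scenarios.csv
immortaltime sweep fig2b --reps 200 -o fig2b.csv --plot fig2b.png
```

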