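"""Replicate engine and parameter sweeps.

The study design is Monte-Carlo: draw many replicate cohorts under one
scenario, fit the requested estimators to each, and summarize each
estimator by the median (and quartiles) of its finite estimates.  The
sweeps move one design knob at a time:

* :func:`sweep_shape` — the Weibull shape, from the constant-hazard
  scenario toward decreasing (lam = 0.75, ups in (0.1, 1)) or
  increasing (lam = 0.1, ups in (1, 3)) hazards, at rr_t = 0.75;
* :func:`sweep_effect` — the true effect rr_t over [0.5, 2] within a
  named scenario;
* :func:`sweep_exposure` — exposure prevalence (15/25/40%) and mean
  time to exposure (gamma_shape * 0.1, from 0 to 5) under the
  binomial-gamma exposure scheme, at rr_t = 0.75.

Defaults are the study conditions (1,000 replicates of n = 10,000 per
cell); ``n_replicates``/``n_subjects`` scale a run down.  Every cell
derives its own child seed from the master seed, so results are
reproducible and independent of execution order or worker count.
"""

from __future__ import annotations

import hashlib
import logging
import time
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ScenarioConfig, scenario_config, simulate_cohort
from .estimators import CoxTimeVaryingHR, PoissonRateRatio, poisson_rr_closed_form
from .persontime import aggregate, cohort_to_episodes

__all__ = [
    "run_replicates",
    "sweep_shape",
    "sweep_effect",
    "sweep_exposure",
    "run_named_experiment",
    "NAMED_EXPERIMENTS",
    "derive_seed",
]

logger = logging.getLogger(__name__)

ESTIMATOR_NAMES = ("poisson", "poisson_adjusted", "cox")

#: Shape grids: 0.1 steps through each open interval, plus the
#: highlighted points 0.3/0.7 (toward B) and 1.6/2.6 (toward C).
SHAPE_GRID_B = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
SHAPE_GRID_C = tuple(sorted(set(np.round(np.arange(1.1, 3.0, 0.1), 10)) | {1.6, 2.6}))
EFFECT_GRID = (0.5, 0.75, 1.0, 1.5, 2.0)
PREVALENCE_GRID = (0.15, 0.25, 0.40)
GAMMA_SHAPE_GRID = tuple(range(0, 51, 5))


def derive_seed(master: int, index: int) -> int:
    """Deterministic child seed for sweep cell ``index`` (< 2**31)."""
    ss = np.random.SeedSequence(master, spawn_key=(index,))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def _fit_one(name: str, episodes, n_intervals: int) -> tuple[float, bool]:
    if name == "poisson":
        r = poisson_rr_closed_form(aggregate(episodes))
    elif name == "poisson_adjusted":
        r = PoissonRateRatio(adjust_intervals=True, n_intervals=n_intervals).fit(episodes).result_
    elif name == "cox":
        r = CoxTimeVaryingHR().fit(episodes).result_
    else:
        raise ValueError(f"unknown estimator {name!r}; choose from {ESTIMATOR_NAMES}")
    return r.rr, r.finite


def run_replicates(
    config: ScenarioConfig,
    n_replicates: int = 1000,
    estimators: Sequence[str] = ("poisson",),
    n_intervals: int = 10,
    return_estimates: bool = False,
):
    """Simulate replicates and summarize each estimator's rate ratio.

    Returns a DataFrame with one row per estimator: median and
    quartiles of the finite estimates, the count of failed (non-finite
    or non-converged) replicates, and the mean realized exposure
    prevalence.  With ``return_estimates=True``, also returns the full
    (n_replicates x estimator) table of estimates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    t0 = time.monotonic()
    values = {name: np.full(n_replicates, np.nan) for name in estimators}
    prevalence = np.empty(n_replicates)
    for r in range(n_replicates):
        cohort = simulate_cohort(config, replicate=r)
        prevalence[r] = cohort.realized_exposure_prevalence
        episodes = cohort_to_episodes(cohort)
        for name in estimators:
            rr, finite = _fit_one(name, episodes, n_intervals)
            if finite:
                values[name][r] = rr
    rows = []
    for name in estimators:
        v = values[name]
        ok = np.isfinite(v)
        n_failed = int((~ok).sum())
        q1, med, q3 = (
            np.percentile(v[ok], [25, 50, 75]) if ok.any() else (np.nan,) * 3
        )
        rows.append(
            {
                "estimator": name,
                "median_rr": float(med),
                "q1_rr": float(q1),
                "q3_rr": float(q3),
                "n_replicates": n_replicates,
                "n_failed": n_failed,
                "realized_exposure_prevalence": float(prevalence.mean()),
            }
        )
        if n_failed > 0.1 * n_replicates:
            logger.warning(
                "%s: %d/%d replicates failed", name, n_failed, n_replicates
            )
    cfg_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:12]
    logger.info(
        "run_replicates config=%s seed=%d reps=%d runtime=%.2fs failures=%s",
        cfg_hash,
        config.seed,
        n_replicates,
        time.monotonic() - t0,
        {r["estimator"]: r["n_failed"] for r in rows},
    )
    summary = pd.DataFrame(rows)
    if return_estimates:
        return summary, pd.DataFrame(values)
    return summary


def _sweep(base_configs, labels, n_replicates, estimators, n_intervals, seed):
    rows = []
    for i, (cfg, label) in enumerate(zip(base_configs, labels)):
        cfg = cfg.replace(seed=derive_seed(seed, i))
        summary = run_replicates(cfg, n_replicates, estimators, n_intervals)
        for rec in summary.to_dict("records"):
            rows.append({**label, **rec})
    return pd.DataFrame(rows)


def sweep_shape(
    direction: str,
    ups_values: Optional[Sequence[float]] = None,
    rr_t: float = 0.75,
    n_replicates: int = 1000,
    n_subjects: int = 10_000,
    estimators: Sequence[str] = ("poisson",),
    n_intervals: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Vary the Weibull shape from constant hazard toward B or C."""
    direction = direction.upper()[-1]  # accepts "B", "C", "A->B", "A->C"
    if direction not in ("B", "C"):
        raise ValueError("direction must name scenario 'B' or 'C'")
    lam = 0.75 if direction == "B" else 0.1
    if ups_values is None:
        ups_values = SHAPE_GRID_B if direction == "B" else SHAPE_GRID_C
    configs = [
        ScenarioConfig(lam=lam, ups=float(v), rr_t=rr_t, n_subjects=n_subjects)
        for v in ups_values
    ]
    labels = [{"parameter": "ups", "value": float(v), "lam": lam} for v in ups_values]
    return _sweep(configs, labels, n_replicates, estimators, n_intervals, seed)


def sweep_effect(
    scenario: str,
    rr_values: Sequence[float] = EFFECT_GRID,
    n_replicates: int = 1000,
    n_subjects: int = 10_000,
    estimators: Sequence[str] = ("poisson",),
    n_intervals: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Vary the true effect rr_t within scenario A, B or C."""
    configs = [
        scenario_config(scenario, rr_t=float(v), n_subjects=n_subjects)
        for v in rr_values
    ]
    labels = [{"parameter": "rr_t", "value": float(v), "scenario": scenario.upper()} for v in rr_values]
    return _sweep(configs, labels, n_replicates, estimators, n_intervals, seed)


def sweep_exposure(
    scenario: str,
    p_values: Sequence[float] = PREVALENCE_GRID,
    gamma_shapes: Sequence[float] = GAMMA_SHAPE_GRID,
    rr_t: float = 0.75,
    gamma_scale: float = 0.1,
    n_replicates: int = 1000,
    n_subjects: int = 10_000,
    estimators: Sequence[str] = ("poisson",),
    n_intervals: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Vary exposure prevalence and mean time to exposure (binomial-gamma)."""
    configs, labels = [], []
    for p in p_values:
        for shape in gamma_shapes:
            configs.append(
                scenario_config(
                    scenario,
                    rr_t=rr_t,
                    n_subjects=n_subjects,
                    exposure_scheme="binomial_gamma",
                    p_exposed=float(p),
                    gamma_shape=float(shape),
                    gamma_scale=gamma_scale,
                )
            )
            labels.append(
                {
                    "parameter": "gamma_shape",
                    "value": float(shape),
                    "mean_exposure_time": float(shape) * gamma_scale,
                    "p_exposed": float(p),
                    "scenario": scenario.upper(),
                }
            )
    return _sweep(configs, labels, n_replicates, estimators, n_intervals, seed)


def _experiment_scenarios(**kw):
    frames = []
    for name in ("A", "B", "C"):
        df = sweep_effect(name, rr_values=(0.75,), **kw)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


NAMED_EXPERIMENTS = {
    "scenarios": _experiment_scenarios,
    "fig2b": lambda **kw: sweep_shape("B", **kw),
    "fig2c": lambda **kw: sweep_shape("C", **kw),
    "fig3": lambda **kw: pd.concat(
        [sweep_effect(s, **kw) for s in ("A", "B", "C")], ignore_index=True
    ),
    "fig4b": lambda **kw: sweep_exposure("B", **kw),
    "fig4c": lambda **kw: sweep_exposure("C", **kw),
}


def run_named_experiment(name: str, **kwargs) -> pd.DataFrame:
    """Run a named sweep (scenarios, fig2b, fig2c, fig3, fig4b, fig4c)."""
    try:
        fn = NAMED_EXPERIMENTS[name]
    except KeyError:
        raise ValueError(
            f"unknown experiment {name!r}; choose from {sorted(NAMED_EXPERIMENTS)}"
        ) from None
    return fn(**kwargs)
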