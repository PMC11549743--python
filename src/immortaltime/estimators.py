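"""Rate-ratio and hazard-ratio estimators on counting-process episodes.

Four estimators are compared on the same episode layout:

* the crude Poisson rate ratio — closed form
  (d1/PT1)/(d0/PT0) with log-scale SE sqrt(1/d1 + 1/d0), identical to
  the two-cell Poisson GLM with a log person-time offset;
* :class:`PoissonRateRatio` — the Poisson log-linear model with log
  person-time offset, optionally adjusted for follow-up intervals
  (the piecewise-exponential remedy for time-varying hazards);
* :class:`CoxTimeVaryingHR` — Cox partial likelihood for a single
  binary time-varying covariate, Breslow tie handling, which leaves
  the baseline hazard unspecified and is therefore immune to the
  hazard trend;
* :func:`kaplan_meier` — the product-limit survival curve.

The model classes follow the scikit-learn estimator contract: fit
returns self, hyperparameters live in ``__init__``, and fitted
quantities carry a trailing underscore (``rr_``, ``log_se_``,
``ci_low_``, ``ci_high_``, ``converged_``).  Confidence intervals are
95% Wald on the log scale throughout.

Zero-event exposure margins yield a rate ratio of 0 or inf with a
non-finite standard error and ``converged_ = False`` rather than an
exception or a continuity correction; the replicate engine counts and
excludes such fits so medians are never silently shifted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .persontime import RateTable, _as_frame, aggregate, event_time_cutpoints, split_by_cutpoints

__all__ = [
    "EstimateResult",
    "KMCurve",
    "poisson_rr_closed_form",
    "PoissonRateRatio",
    "CoxTimeVaryingHR",
    "poisson_glm",
    "cox_tvc",
    "kaplan_meier",
    "results_to_frame",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class EstimateResult:
    """Point estimate of a rate/hazard ratio with Wald interval."""

    estimator: str
    rr: float
    log_se: float
    ci_low: float
    ci_high: float
    converged: bool
    n_events: int
    n_iterations: int = 0

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.rr) and self.rr > 0.0 and np.isfinite(self.log_se))


def _wald(label, log_rr, log_se, converged, n_events, n_iter) -> EstimateResult:
    rr = float(np.exp(log_rr))
    if np.isfinite(log_rr) and np.isfinite(log_se):
        with np.errstate(over="ignore"):
            lo = float(np.exp(log_rr - _Z95 * log_se))
            hi = float(np.exp(log_rr + _Z95 * log_se))
    else:
        lo, hi = 0.0, np.inf
    return EstimateResult(label, rr, float(log_se), lo, hi, converged, int(n_events), int(n_iter))


def results_to_frame(results) -> pd.DataFrame:
    """One row per estimate, the delimited-text export layout."""
    rows = [
        {
            "estimator": r.estimator,
            "rr": r.rr,
            "log_se": r.log_se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "converged": r.converged,
            "n_events": r.n_events,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


# -- crude Poisson, closed form --------------------------------------------


def poisson_rr_closed_form(rt: RateTable) -> EstimateResult:
    """Crude rate ratio from a two-cell rate table.

    This is the exact MLE of the Poisson model with a log person-time
    offset and a single exposure indicator, so it doubles as the
    oracle for the iteratively fitted version.
    """
    d1, pt1 = rt.cell(True)
    d0, pt0 = rt.cell(False)
    if pt1 <= 0.0 or pt0 <= 0.0:
        raise ValueError("both exposure margins need positive person-time")
    n_events = d0 + d1
    if d1 == 0 or d0 == 0:
        log_rr = -np.inf if d1 == 0 else np.inf
        return _wald("poisson", log_rr, np.inf, False, n_events, 0)
    log_rr = np.log((d1 / pt1) / (d0 / pt0))
    log_se = np.sqrt(1.0 / d1 + 1.0 / d0)
    return _wald("poisson", log_rr, log_se, True, n_events, 0)


# -- Poisson GLM with offset ------------------------------------------------


class PoissonRateRatio(BaseEstimator):
    """Poisson rate-ratio regression with a log person-time offset.

    Unadjusted (``adjust_intervals=False``) this is the model whose
    crude rate ratio is biased by immortal-time-correct but
    time-varying hazards; with ``adjust_intervals=True`` it becomes
    the piecewise-exponential remedy, adding one indicator per
    follow-up interval so the baseline rate is constant only within
    intervals.

    Parameters
    ----------
    adjust_intervals : bool, default False
        Add follow-up-interval indicators to the linear predictor.
    n_intervals : int, default 10
        Number of event-time-quantile intervals to create when the
        episodes carry no ``interval`` column.

    Attributes
    ----------
    rr_ : float
        Estimated rate ratio exp(beta) for exposure.
    log_se_, ci_low_, ci_high_ : float
        Log-scale Wald standard error and 95% interval.
    converged_ : bool
    n_events_, n_iter_ : int
    cutpoints_ : ndarray
        Interval cutpoints actually used (empty when unadjusted).
    result_ : EstimateResult
    """

    def __init__(self, adjust_intervals: bool = False, n_intervals: int = 10):
        self.adjust_intervals = adjust_intervals
        self.n_intervals = n_intervals

    def fit(self, X, y=None) -> "PoissonRateRatio":
        """Fit to episodes (DataFrame / list of Episode) or a RateTable."""
        label = "poisson_adjusted" if self.adjust_intervals else "poisson"
        self.cutpoints_ = np.array([])
        if isinstance(X, RateTable):
            rt = X if self.adjust_intervals else X.marginal()
        else:
            df, _ = _as_frame(X)
            if self.adjust_intervals and "interval" not in df.columns:
                self.cutpoints_ = event_time_cutpoints(df, self.n_intervals)
                df = split_by_cutpoints(df, self.cutpoints_)
            rt = aggregate(df)
        if self.adjust_intervals and not rt.has_intervals:
            raise ValueError("adjust_intervals=True requires an interval dimension")
        cells = rt.cells if self.adjust_intervals else rt.marginal().cells

        if self.adjust_intervals:
            # intervals with no events push their indicator to -inf;
            # dropping their cells is the exact profiled likelihood
            dead = cells.groupby("interval")["events"].transform("sum") == 0
            if dead.any():
                warnings.warn(
                    f"dropping {int(dead.sum())} zero-event interval cells",
                    stacklevel=2,
                )
                cells = cells[~dead]

        d = cells["events"].to_numpy(dtype=float)
        pt = cells["person_time"].to_numpy(dtype=float)
        x = cells["exposed"].to_numpy(dtype=float)
        n_events = int(d.sum())
        d1, d0 = d[x == 1.0].sum(), d[x == 0.0].sum()
        if d1 == 0.0 or d0 == 0.0 or len(cells) < 2:
            log_rr = -np.inf if d1 == 0.0 else np.inf
            self._finish(label, log_rr, np.inf, False, n_events, 0)
            return self

        cols = [np.ones_like(x), x]
        if self.adjust_intervals:
            levels = np.sort(cells["interval"].unique())
            cols += [(cells["interval"].to_numpy() == k).astype(float) for k in levels[1:]]
        design = np.column_stack(cols)
        model = sm.GLM(d, design, family=sm.families.Poisson(), offset=np.log(pt))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # perfect-fit / domain chatter
            res = model.fit(maxiter=200, tol=1e-12)
        self._finish(
            label,
            float(res.params[1]),
            float(res.bse[1]),
            bool(res.converged),
            n_events,
            int(res.fit_history["iteration"]),
        )
        return self

    def _finish(self, label, log_rr, log_se, converged, n_events, n_iter):
        r = _wald(label, log_rr, log_se, converged, n_events, n_iter)
        self.result_ = r
        self.rr_ = r.rr
        self.log_se_ = r.log_se
        self.ci_low_ = r.ci_low
        self.ci_high_ = r.ci_high
        self.converged_ = r.converged
        self.n_events_ = r.n_events
        self.n_iter_ = r.n_iterations


# -- Cox partial likelihood, binary time-varying covariate ------------------


class CoxTimeVaryingHR(BaseEstimator):
    """Cox proportional-hazards model with one binary time-varying covariate.

    Maximizes the Breslow partial likelihood over episodes in
    (start, stop] counting-process form; the risk set at an event time
    t contains every episode with start < t <= stop.  Because the
    covariate is a single 0/1 state, the risk-set sums reduce to
    at-risk counts per exposure state, which are computed once by
    sorting, making each Newton iteration O(number of events).

    Newton steps use step-halving on partial-likelihood decrease; a
    monotone likelihood (all events in one exposure state while at
    risk) is reported as a non-finite estimate with
    ``converged_ = False``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "CoxTimeVaryingHR":
        df, _ = _as_frame(X)
        start = df["start"].to_numpy(dtype=float)
        stop = df["stop"].to_numpy(dtype=float)
        x = df["exposed"].to_numpy(dtype=bool)
        ev = df["event"].to_numpy(dtype=bool)
        if not ev.any():
            raise ValueError("no events in episode table")
        et = stop[ev]
        n_events = int(ev.sum())

        s1, e1 = np.sort(start[x]), np.sort(stop[x])
        s0, e0 = np.sort(start[~x]), np.sort(stop[~x])
        # at risk at t: start < t <= stop
        r1 = np.searchsorted(s1, et, "left") - np.searchsorted(e1, et, "left")
        r0 = np.searchsorted(s0, et, "left") - np.searchsorted(e0, et, "left")
        d1 = float(x[ev].sum())

        # interior maximum exists iff the exposed event count stays strictly
        # between what the risk sets can support at the two boundaries:
        # as beta -> -inf the likelihood climbs unless d1 > #{events whose
        # risk set holds no unexposed}; as beta -> +inf unless
        # d1 < #{events whose risk set holds any exposed}
        m_lo = float((r0 == 0).sum())
        m_hi = float((r1 > 0).sum())
        if d1 <= m_lo or d1 >= m_hi:
            log_rr = np.inf if d1 >= m_hi else -np.inf
            self._finish(log_rr, np.inf, False, n_events, 0)
            return self

        def loglik(b):
            return d1 * b - np.sum(np.log(r0 + np.exp(b) * r1))

        b = 0.0
        ll = loglik(b)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eb = np.exp(b)
            p = eb * r1 / (r0 + eb * r1)
            grad = d1 - p.sum()
            info = float((p * (1.0 - p)).sum())
            if info <= 0.0:
                break
            step = grad / info
            new_b = b + step
            new_ll = loglik(new_b)
            halvings = 0
            while new_ll < ll and halvings < 30:
                step *= 0.5
                new_b = b + step
                new_ll = loglik(new_b)
                halvings += 1
            b, ll = new_b, new_ll
            if abs(grad) < self.tol:
                converged = True
                break
        eb = np.exp(b)
        p = eb * r1 / (r0 + eb * r1)
        info = float((p * (1.0 - p)).sum())
        log_se = 1.0 / np.sqrt(info) if info > 0.0 else np.inf
        if abs(b) > 30.0:  # drifting to a monotone-likelihood boundary
            converged = False
        self._finish(b, log_se, converged, n_events, it)
        return self

    def _finish(self, log_rr, log_se, converged, n_events, n_iter):
        r = _wald("cox", log_rr, log_se, converged, n_events, n_iter)
        self.result_ = r
        self.rr_ = r.rr
        self.log_se_ = r.log_se
        self.ci_low_ = r.ci_low
        self.ci_high_ = r.ci_high
        self.converged_ = r.converged
        self.n_events_ = r.n_events
        self.n_iter_ = r.n_iterations


def poisson_glm(episodes, adjust_intervals: bool = False, n_intervals: int = 10) -> EstimateResult:
    """Fit the (optionally interval-adjusted) Poisson model; return its result."""
    return PoissonRateRatio(adjust_intervals, n_intervals).fit(episodes).result_


def cox_tvc(episodes) -> EstimateResult:
    """Fit the Cox time-varying-covariate model; return its result."""
    return CoxTimeVaryingHR().fit(episodes).result_


# -- Kaplan-Meier -----------------------------------------------------------


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve evaluated at the observed times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step evaluation of S(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out


def kaplan_meier(subjects) -> KMCurve:
    """Kaplan-Meier curve of a cohort (or a subjects table).

    Accepts a Cohort or any DataFrame with ``end_time`` and ``event``
    columns; censored subjects leave the risk set at end_time.
    """
    from lifelines import KaplanMeierFitter

    data = subjects.data if hasattr(subjects, "data") else subjects
    kmf = KaplanMeierFitter()
    kmf.fit(data["end_time"], event_observed=data["event"].astype(bool))
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0.0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    return KMCurve(times, surv, at_risk)
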