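import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from immortaltime import ScenarioConfig, cohort_to_episodes, simulate_cohort


@pytest.fixture(scope="session")
def scenario_b_episodes():
    """One mid-size decreasing-hazard cohort in episode form."""
    cfg = ScenarioConfig(lam=0.75, ups=0.33, rr_t=0.75, n_subjects=30_000, seed=11)
    return cohort_to_episodes(simulate_cohort(cfg))


def naive_cox_loglik(episodes: pd.DataFrame, beta: float) -> float:
    """Loop-based Breslow partial log-likelihood, kept deliberately naive
    so it is an independent oracle for the Newton fitter."""
    ll = 0.0
    x = episodes["exposed"].to_numpy(dtype=float)
    for row in episodes[episodes["event"]].itertuples(index=False):
        t = row.stop
        at_risk = (episodes["start"].to_numpy() < t) & (episodes["stop"].to_numpy() >= t)
        ll += beta * float(row.exposed) - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def brute_force_cox_beta(episodes: pd.DataFrame) -> float:
    """Maximize the naive partial likelihood by 1-D bounded search."""
    res = minimize_scalar(
        lambda b: -naive_cox_loglik(episodes, b),
        bounds=(-6.0, 6.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
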