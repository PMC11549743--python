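"""Simulate cohorts with a one-way unexposed-to-exposed switch.

Each subject carries a latent event time from the Weibull baseline and
an exposure-switch time from one of two generating schemes:

``uniform``
    every subject has a potential switch time drawn Uniform(0, hi)
    (default hi = 10, so roughly half the switches fall after the
    administrative censoring horizon of 5 time units);

``binomial_gamma``
    a Bernoulli(p_exposed) draw decides ever-eligibility, and eligible
    subjects get a Gamma(shape, scale=0.1) switch time, so the mean
    time to exposure is shape * scale.  ``gamma_shape == 0`` is the
    degenerate exposed-from-time-zero endpoint.

If the switch time precedes the latent event time, the subject becomes
exposed at the switch and a new event time is drawn conditional on
survival to the switch, with the hazard multiplied by the true effect
rr_t from that moment (see :mod:`immortaltime.hazards`).  Follow-up
ends at min(event time, censoring horizon).  Exposure is recorded only
when the switch occurs during observed follow-up, so immortal
person-time classification is always explicit.

Randomness: each subject consumes a fixed block of four Uniform(0,1)
draws (eligibility, switch time, baseline event, conditional event),
taken row-major from one generator, so enlarging the cohort never
reshuffles earlier subjects.  Replicate r of a scenario uses the
seed's r-th spawned child stream, making replicates independent and
reproducible regardless of execution order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .hazards import ExposureEffect, WeibullHazard

__all__ = [
    "ScenarioConfig",
    "SubjectRecord",
    "Cohort",
    "SCENARIOS",
    "scenario_config",
    "load_config",
    "draw_exposure_time",
    "simulate_subject",
    "simulate_cohort",
    "read_cohort",
]

#: Baseline Weibull (lam, ups) of the three named scenarios: constant
#: hazard (A), decreasing (B), increasing (C).
SCENARIOS: dict[str, tuple[float, float]] = {
    "A": (0.1, 1.0),
    "B": (0.75, 0.33),
    "C": (1e-05, 7.0),
}

_TINY = 1e-12  # clamp uniforms into the open interval before inversion


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulated cohort."""

    lam: float
    ups: float
    rr_t: float = 1.0
    censor_time: float = 5.0
    n_subjects: int = 10_000
    exposure_scheme: str = "uniform"
    uniform_hi: float = 10.0
    p_exposed: Optional[float] = None
    gamma_shape: Optional[float] = None
    gamma_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        WeibullHazard(self.lam, self.ups)  # validates lam, ups
        ExposureEffect(self.rr_t)
        if not (self.censor_time > 0.0):
            raise ValueError("censor_time must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.exposure_scheme == "uniform":
            if not (self.uniform_hi > 0.0):
                raise ValueError("uniform_hi must be positive")
        elif self.exposure_scheme == "binomial_gamma":
            if self.p_exposed is None or not (0.0 <= self.p_exposed <= 1.0):
                raise ValueError("binomial_gamma requires p_exposed in [0, 1]")
            if self.gamma_shape is None or self.gamma_shape < 0.0:
                raise ValueError("binomial_gamma requires gamma_shape >= 0")
            if not (self.gamma_scale > 0.0):
                raise ValueError("gamma_scale must be positive")
        else:
            raise ValueError(f"unknown exposure_scheme {self.exposure_scheme!r}")

    @property
    def hazard(self) -> WeibullHazard:
        return WeibullHazard(self.lam, self.ups)

    @property
    def effect(self) -> ExposureEffect:
        return ExposureEffect(self.rr_t)

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        name = d.pop("scenario", None)
        if name is not None:
            lam, ups = SCENARIOS[str(name).upper()]
            d.setdefault("lam", lam)
            d.setdefault("ups", ups)
        return cls(**d)


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Preset config for scenario ``A``, ``B`` or ``C`` plus overrides."""
    return ScenarioConfig.from_dict({"scenario": name, **overrides})


def load_config(path) -> ScenarioConfig:
    """Read a ScenarioConfig from a YAML or JSON key-value file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return ScenarioConfig.from_dict(data)


class SubjectRecord(NamedTuple):
    """One simulated subject.

    ``exposure_time`` is None unless the switch occurred strictly
    before ``end_time``; ``event`` is False for administratively
    censored subjects.
    """

    id: int
    exposure_time: Optional[float]
    end_time: float
    event: bool


@dataclass(frozen=True)
class Cohort:
    """A simulated cohort: one row per subject plus its config.

    ``data`` columns: id (int), exposure_time (float, NaN if never
    exposed during follow-up), end_time (float), event (bool).
    """

    data: pd.DataFrame
    config: ScenarioConfig

    def __post_init__(self) -> None:
        required = {"id", "exposure_time", "end_time", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if self.data["id"].duplicated().any():
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> Iterator[SubjectRecord]:
        for row in self.data.itertuples(index=False):
            e = None if pd.isna(row.exposure_time) else float(row.exposure_time)
            yield SubjectRecord(int(row.id), e, float(row.end_time), bool(row.event))

    @property
    def realized_exposure_prevalence(self) -> float:
        """Fraction of subjects exposed during observed follow-up."""
        return float(self.data["exposure_time"].notna().mean())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_cohort(path, config: Optional[ScenarioConfig] = None) -> Cohort:
    """Read a cohort table written by :meth:`Cohort.to_csv`."""
    df = pd.read_csv(path)
    df["event"] = df["event"].astype(bool)
    if config is None:
        config = ScenarioConfig(lam=1.0, ups=1.0, n_subjects=len(df))
    return Cohort(df, config)


# -- exposure process -------------------------------------------------------


def _exposure_times_from_uniforms(config: ScenarioConfig, u_elig, u_time):
    """Vectorized switch times; np.inf encodes 'never eligible'."""
    u_time = np.clip(u_time, _TINY, 1.0 - _TINY)
    if config.exposure_scheme == "uniform":
        return u_time * config.uniform_hi
    eligible = u_elig < config.p_exposed
    if config.gamma_shape == 0.0:
        times = np.zeros_like(u_time)
    else:
        times = stats.gamma.ppf(u_time, config.gamma_shape) * config.gamma_scale
    return np.where(eligible, times, np.inf)


def draw_exposure_time(config: ScenarioConfig, rng: np.random.Generator):
    """Draw one potential exposure-switch time; None if never eligible."""
    u = rng.random(2)
    e = float(_exposure_times_from_uniforms(config, u[0], u[1]))
    return None if np.isinf(e) else e


# -- subject and cohort simulation -----------------------------------------


def simulate_subject(
    h: WeibullHazard,
    eff: ExposureEffect,
    exposure_time: Optional[float],
    censor_time: float,
    rng: np.random.Generator,
    subject_id: int = 0,
) -> SubjectRecord:
    """Simulate one subject given its potential exposure-switch time.

    Consumes exactly two uniforms (baseline and conditional event
    draws) whether or not the switch occurs, matching the vectorized
    cohort path draw for draw.
    """
    if censor_time <= 0.0:
        raise ValueError("censor_time must be positive")
    u = np.clip(rng.random(2), _TINY, 1.0 - _TINY)
    t0 = h.ppf_survival(u[0])
    e = np.inf if exposure_time is None else float(exposure_time)
    if e < 0.0:
        raise ValueError("exposure_time must be non-negative")
    t = h.conditional_ppf_survival(u[1], e, rr_t=eff.rr_t) if e < t0 else t0
    end_time = min(t, censor_time)
    event = t <= censor_time
    kept = e if e < end_time else None
    return SubjectRecord(subject_id, kept, float(end_time), bool(event))


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def simulate_cohort(config: ScenarioConfig, replicate: int = 0) -> Cohort:
    """Simulate a full cohort, deterministic in (config.seed, replicate)."""
    n = config.n_subjects
    rng = _replicate_rng(config.seed, replicate)
    u = rng.random((n, 4))
    e = _exposure_times_from_uniforms(config, u[:, 0], u[:, 1])

    h = config.hazard
    u2 = np.clip(u[:, 2], _TINY, 1.0 - _TINY)
    u3 = np.clip(u[:, 3], _TINY, 1.0 - _TINY)
    t0 = h.ppf_survival(u2)
    switch = e < t0
    t = np.where(
        switch,
        h.conditional_ppf_survival(u3, np.where(switch, e, 0.0), rr_t=config.rr_t),
        t0,
    )
    end_time = np.minimum(t, config.censor_time)
    event = t <= config.censor_time
    exposed_during = e < end_time

    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "exposure_time": np.where(exposed_during, e, np.nan),
            "end_time": end_time,
            "event": event,
        }
    )
    return Cohort(df, config)
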