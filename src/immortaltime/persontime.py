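"""Counting-process episodes, follow-up splitting and rate tables.

This is the immortal-time-correct bookkeeping layer: a subject's
follow-up is laid out as (start, stop] episodes of constant exposure
state, with the event flag attached to the episode that ends at the
event time.  Person-time before the exposure switch counts as
unexposed, which is exactly what prevents immortal time from being
misclassified.

Episodes can be split further at follow-up cutpoints, giving each
fragment an ``interval`` index; this is the input for the
piecewise-exponential (interval-adjusted Poisson) remedy.  Splitting
uses the half-open convention [c_k, c_{k+1}): an event falling exactly
on a cutpoint stays with the earlier fragment, since the event occurs
at the fragment's stop.

Batch episodes live in a pandas DataFrame with columns
``id, start, stop, exposed, event`` (plus ``interval`` after a split)
— the de-facto (start, stop] layout shared with survival packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, SubjectRecord

__all__ = [
    "Episode",
    "RateTable",
    "to_episodes",
    "cohort_to_episodes",
    "split_by_cutpoints",
    "event_time_cutpoints",
    "aggregate",
    "write_episodes",
    "read_episodes",
]

EPISODE_COLUMNS = ["id", "start", "stop", "exposed", "event"]


class Episode(NamedTuple):
    id: int
    start: float
    stop: float
    exposed: bool
    event: bool
    interval: Optional[int] = None


def to_episodes(s: SubjectRecord) -> list[Episode]:
    """Lay out one subject as counting-process episodes.

    A never-exposed subject yields a single unexposed episode over
    (0, end_time]; an exposed subject yields an unexposed episode up to
    the switch and an exposed episode from the switch to end_time, the
    latter carrying the event flag.
    """
    if s.exposure_time is None:
        return [Episode(s.id, 0.0, s.end_time, False, s.event)]
    if not (0.0 <= s.exposure_time < s.end_time):
        raise ValueError(
            f"subject {s.id}: exposure_time {s.exposure_time} must lie in "
            f"[0, end_time={s.end_time})"
        )
    if s.exposure_time == 0.0:
        return [Episode(s.id, 0.0, s.end_time, True, s.event)]
    return [
        Episode(s.id, 0.0, s.exposure_time, False, False),
        Episode(s.id, s.exposure_time, s.end_time, True, s.event),
    ]


def cohort_to_episodes(cohort: Cohort) -> pd.DataFrame:
    """Vectorized episode layout for a whole cohort."""
    d = cohort.data
    e = d["exposure_time"].to_numpy(dtype=float)
    end = d["end_time"].to_numpy(dtype=float)
    ev = d["event"].to_numpy(dtype=bool)
    ids = d["id"].to_numpy()
    exposed = ~np.isnan(e)

    # unexposed stretch (0, min(e, end)]; zero-length when exposed at t=0
    stop0 = np.where(exposed, e, end)
    ev0 = ev & ~exposed
    df0 = pd.DataFrame(
        {
            "id": ids,
            "start": 0.0,
            "stop": stop0,
            "exposed": False,
            "event": ev0,
        }
    )
    df1 = pd.DataFrame(
        {
            "id": ids[exposed],
            "start": e[exposed],
            "stop": end[exposed],
            "exposed": True,
            "event": ev[exposed],
        }
    )
    out = pd.concat([df0, df1], ignore_index=True)
    out = out[out["stop"] > out["start"]]
    return out.sort_values(["id", "start"], kind="stable", ignore_index=True)


def _as_frame(episodes) -> tuple[pd.DataFrame, bool]:
    if isinstance(episodes, pd.DataFrame):
        return episodes, True
    return pd.DataFrame(list(episodes), columns=Episode._fields), False


def split_by_cutpoints(episodes, cutpoints: Sequence[float]):
    """Partition episodes at interior cutpoints, labelling intervals.

    Fragment k covers [c_k, c_{k+1}) of follow-up time (c_0 = 0,
    c_last = +inf); the event flag is carried only by the fragment that
    contains the original stop.  Person-time is conserved exactly.

    Accepts and returns either a DataFrame or a list of Episode.
    """
    cuts = np.asarray(list(cutpoints), dtype=float)
    if cuts.size and (np.any(np.diff(cuts) <= 0.0) or np.any(cuts <= 0.0)):
        raise ValueError("cutpoints must be strictly increasing and positive")
    df, was_frame = _as_frame(episodes)
    edges = np.concatenate([[0.0], cuts, [np.inf]])

    start = df["start"].to_numpy(dtype=float)
    stop = df["stop"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    pieces = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        fs = np.maximum(start, lo)
        fe = np.minimum(stop, hi)
        keep = fe > fs
        if not keep.any():
            continue
        # event belongs to the fragment with fs < stop <= fe (event AT stop)
        fev = event & (stop > lo) & (stop <= hi)
        piece = df.loc[keep, ["id", "exposed"]].copy()
        piece["start"] = fs[keep]
        piece["stop"] = fe[keep]
        piece["event"] = fev[keep]
        piece["interval"] = k
        pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    out = out[["id", "start", "stop", "exposed", "event", "interval"]]
    out = out.sort_values(["id", "start"], kind="stable", ignore_index=True)
    if was_frame:
        return out
    return [Episode(*row) for row in out.itertuples(index=False)]


def event_time_cutpoints(episodes, n_intervals: int = 10) -> np.ndarray:
    """Interior cutpoints at quantiles of the observed event times.

    Splitting at these cutpoints yields up to ``n_intervals`` follow-up
    intervals holding roughly equal numbers of events, which is where a
    piecewise-constant rate model needs its resolution.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    df, _ = _as_frame(episodes)
    event_times = df.loc[df["event"].astype(bool), "stop"].to_numpy(dtype=float)
    if event_times.size == 0:
        return np.array([])
    probs = np.linspace(0.0, 1.0, n_intervals + 1)[1:-1]
    cuts = np.quantile(event_times, probs)
    cuts = np.unique(cuts[cuts > 0.0])
    return cuts


@dataclass(frozen=True)
class RateTable:
    """Events and person-time aggregated by exposure (x interval).

    ``cells`` columns: exposed (bool), events (int), person_time
    (float) and, when built from split episodes, interval (int).
    """

    cells: pd.DataFrame

    @property
    def has_intervals(self) -> bool:
        return "interval" in self.cells.columns

    @property
    def total_events(self) -> int:
        return int(self.cells["events"].sum())

    @property
    def total_person_time(self) -> float:
        return float(self.cells["person_time"].sum())

    def marginal(self) -> "RateTable":
        """Collapse the interval dimension, keeping exposure only."""
        if not self.has_intervals:
            return self
        g = (
            self.cells.groupby("exposed", as_index=False)[["events", "person_time"]]
            .sum()
            .sort_values("exposed", ignore_index=True)
        )
        return RateTable(g)

    def cell(self, exposed: bool):
        """(events, person_time) for one exposure margin."""
        m = self.marginal().cells
        row = m[m["exposed"] == exposed]
        if row.empty:
            return 0, 0.0
        return int(row["events"].iloc[0]), float(row["person_time"].iloc[0])


def aggregate(episodes) -> RateTable:
    """Sum events and person-time by (exposed[, interval])."""
    df, _ = _as_frame(episodes)
    df = df.copy()
    df["duration"] = df["stop"].astype(float) - df["start"].astype(float)
    keys = ["exposed"]
    if "interval" in df.columns and df["interval"].notna().all():
        keys = ["interval", "exposed"]
    g = df.groupby(keys, as_index=False).agg(
        events=("event", "sum"), person_time=("duration", "sum")
    )
    g["events"] = g["events"].astype(int)
    g = g[g["person_time"] > 0.0].sort_values(keys, ignore_index=True)
    return RateTable(g)


def write_episodes(episodes, path) -> None:
    df, _ = _as_frame(episodes)
    df.to_csv(path, index=False)


def read_episodes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EPISODE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"episode table missing columns {sorted(missing)}")
    df["exposed"] = df["exposed"].astype(bool)
    df["event"] = df["event"].astype(bool)
    return df
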