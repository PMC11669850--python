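"""Domain types and long-format I/O for recurrent-event marker data.

A study record consists, per subject, of a scalar baseline marker ``m_i``,
a censoring (end-of-observation) time ``C_i`` and the strictly increasing
event times ``t_i1 < ... < t_i n_i`` observed on ``[0, C_i]``.  All subjects
share a common study window ``[0, tau]``.  The canonical on-disk form is a
pair of long-format CSV files: a subjects table (``id,marker,censor_time``)
and an events table (``id,time``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecurrentData",
    "RiskDefinition",
    "EmpiricalCDF",
    "load_recurrent_data",
    "write_recurrent_data",
    "from_counting_process",
    "to_counting_process",
    "empirical_cdf",
    "observed_count",
    "max_observed_count",
]


class ValidationError(ValueError):
    """Raised when input data violate the recurrent-event data contract."""


@dataclass(frozen=True)
class RecurrentData:
    """One subject's observed recurrent-event record.

    Parameters
    ----------
    subject_id
        Unique identifier within the dataset.
    marker : float
        Baseline scalar marker value ``m_i`` (higher = assumed higher risk).
    censor_time : float
        End of observation ``C_i``; events after it are unobserved.
    event_times : ndarray
        Strictly increasing observed event times, all in ``(0, censor_time]``.
    tau : float
        Common study-window end; ``censor_time <= tau``.
    """

    subject_id: object
    marker: float
    censor_time: float
    event_times: np.ndarray
    tau: float

    def __post_init__(self):
        times = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", times)
        if not np.isfinite(self.marker):
            raise ValidationError(f"subject {self.subject_id}: non-finite marker")
        if self.censor_time < 0:
            raise ValidationError(f"subject {self.subject_id}: negative censor_time")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if self.censor_time > self.tau + 1e-12:
            raise ValidationError(
                f"subject {self.subject_id}: censor_time {self.censor_time} exceeds tau {self.tau}"
            )
        if times.size:
            if times.min() <= 0:
                raise ValidationError(f"subject {self.subject_id}: non-positive event time")
            if times.max() > self.censor_time + 1e-12:
                raise ValidationError(
                    f"subject {self.subject_id}: event at {times.max()} after censor_time {self.censor_time}"
                )
            if np.any(np.diff(times) <= 0):
                raise ValidationError(
                    f"subject {self.subject_id}: event times must be strictly increasing (within-subject ties forbidden)"
                )

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


@dataclass(frozen=True)
class RiskDefinition:
    """High-risk definition: at least ``r`` events in the window ``[0, t]``."""

    r: int
    t: float

    def __post_init__(self):
        if self.r < 1:
            raise ValidationError("r must be >= 1")
        if self.t <= 0:
            raise ValidationError("horizon t must be positive")


class EmpiricalCDF:
    """Empirical distribution of the marker sample.

    ``cdf(x)`` is the fraction of sample points ``<= x``; ``quantile(v)`` is
    the left-continuous inverse, i.e. the smallest sample value whose cdf is
    at least ``v`` (type-1 quantile).  The left-continuous convention keeps
    the quantile an observed marker value, so indicator sums over the sample
    remain well defined under ties.
    """

    def __init__(self, values: Sequence[float]):
        arr = np.sort(np.asarray(values, dtype=float))
        if arr.size == 0:
            raise ValidationError("empirical CDF requires a non-empty sample")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("empirical CDF requires finite values")
        self.sorted_values = arr
        self.n = int(arr.size)

    def cdf(self, x):
        return np.searchsorted(self.sorted_values, x, side="right") / self.n

    def quantile(self, v):
        v = np.asarray(v, dtype=float)
        # tolerate floating jitter in v*n at integer breakpoints
        idx = np.clip(np.ceil(v * self.n - 1e-9).astype(int) - 1, 0, self.n - 1)
        out = self.sorted_values[idx]
        return out if out.ndim else float(out)


def empirical_cdf(markers: Sequence[float]) -> EmpiricalCDF:
    """Build the empirical marker CDF ``G-hat`` from a sample."""
    return EmpiricalCDF(markers)


def observed_count(data: RecurrentData, t: float) -> int:
    """Observed count ``N^o(t) = N(t ^ C)``: events up to ``min(t, C_i)``."""
    if t < 0 or t > data.tau + 1e-12:
        raise ValidationError(f"t={t} outside [0, tau={data.tau}]")
    cut = min(t, data.censor_time)
    return int(np.searchsorted(data.event_times, cut, side="right"))


def max_observed_count(data: Iterable[RecurrentData]) -> int:
    """``K``: the largest observed per-subject event count in the dataset."""
    return max((d.n_events for d in data), default=0)


def load_recurrent_data(subjects_table, events_table, tau: float) -> list[RecurrentData]:
    """Assemble validated per-subject records from long-format tables.

    ``subjects_table`` needs columns ``id, marker, censor_time``;
    ``events_table`` needs ``id, time`` (may be empty).  Subjects without
    events are retained with an empty event list.
    """
    subjects = pd.DataFrame(subjects_table, columns=None)
    subjects = subjects.rename(columns=str)
    for col in ("id", "marker", "censor_time"):
        if col not in subjects.columns:
            raise ValidationError(f"subjects table missing column {col!r}")
    if subjects["id"].duplicated().any():
        dup = subjects.loc[subjects["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"duplicate subject id {dup!r}")
    if tau <= 0:
        raise ValidationError("tau must be positive")

    events = pd.DataFrame(events_table)
    if len(events):
        for col in ("id", "time"):
            if col not in events.columns:
                raise ValidationError(f"events table missing column {col!r}")
        known = set(subjects["id"])
        unknown = set(events["id"]) - known
        if unknown:
            raise ValidationError(f"events refer to unknown subject ids: {sorted(unknown)!r}")
        grouped = {k: np.sort(np.asarray(g["time"], dtype=float)) for k, g in events.groupby("id")}
    else:
        grouped = {}

    out = []
    for row in subjects.itertuples(index=False):
        times = grouped.get(row.id, np.empty(0))
        if times.size and np.any(np.diff(times) == 0):
            raise ValidationError(f"subject {row.id!r}: tied event times")
        out.append(
            RecurrentData(
                subject_id=row.id,
                marker=float(row.marker),
                censor_time=float(row.censor_time),
                event_times=times,
                tau=float(tau),
            )
        )
    return out


def write_recurrent_data(data: Sequence[RecurrentData], subjects_path, events_path) -> None:
    """Write the canonical subjects/events CSV pair (UTF-8, '.' decimals)."""
    subj = pd.DataFrame(
        {
            "id": [d.subject_id for d in data],
            "marker": [d.marker for d in data],
            "censor_time": [d.censor_time for d in data],
        }
    )
    ev = pd.DataFrame(
        {
            "id": np.repeat([d.subject_id for d in data], [d.n_events for d in data]),
            "time": np.concatenate([d.event_times for d in data]) if data else np.empty(0),
        }
    )
    subj.to_csv(Path(subjects_path), index=False)
    ev.to_csv(Path(events_path), index=False)


def read_recurrent_data(subjects_path, events_path, tau: float) -> list[RecurrentData]:
    """Read the canonical CSV pair back into validated records."""
    subjects = pd.read_csv(subjects_path)
    events = pd.read_csv(events_path)
    return load_recurrent_data(subjects, events, tau)


def from_counting_process(table, tau: float) -> list[RecurrentData]:
    """Import a wide counting-process export (``id,start,stop,status,marker``).

    Rows with ``status == 1`` contribute their ``stop`` value as an event
    time; each subject's largest ``stop`` is taken as the censoring time.
    """
    df = pd.DataFrame(table)
    for col in ("id", "start", "stop", "status", "marker"):
        if col not in df.columns:
            raise ValidationError(f"counting-process table missing column {col!r}")
    subj_rows = []
    ev_rows = []
    for sid, g in df.groupby("id", sort=False):
        subj_rows.append({"id": sid, "marker": float(g["marker"].iloc[0]), "censor_time": float(g["stop"].max())})
        for stop in g.loc[g["status"] == 1, "stop"]:
            ev_rows.append({"id": sid, "time": float(stop)})
    return load_recurrent_data(pd.DataFrame(subj_rows), pd.DataFrame(ev_rows), tau)


def to_counting_process(data: Sequence[RecurrentData]) -> pd.DataFrame:
    """Export to (start, stop, status) counting-process rows for interop."""
    rows = []
    for d in data:
        start = 0.0
        for t in d.event_times:
            rows.append({"id": d.subject_id, "start": start, "stop": float(t), "status": 1, "marker": d.marker})
            start = float(t)
        if d.censor_time > start or d.n_events == 0:
            rows.append({"id": d.subject_id, "start": start, "stop": d.censor_time, "status": 0, "marker": d.marker})
    return pd.DataFrame(rows, columns=["id", "start", "stop", "status", "marker"])
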