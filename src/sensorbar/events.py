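"""Sensor event logs and their binarization onto the 15-minute grid.

In-home passive monitoring produces a stream of (timestamp, sensor label)
events.  All modelling downstream works on a regular grid of 15-minute bins
(96 per day): a bin is 1 if the sensor fired at least once inside it, 0
otherwise.  Multiple triggers inside one bin are deliberately collapsed to a
single 1 — only the presence of activity in the window is modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

BIN_MINUTES = 15
BINS_PER_DAY = 96

_BIN = timedelta(minutes=BIN_MINUTES)


@dataclass
class SensorEventLog:
    """Raw event stream: (timestamp, sensor_id) records, not necessarily sorted."""

    records: list[tuple[datetime, str]]

    @property
    def sensor_ids(self) -> list[str]:
        return sorted({s for _, s in self.records})


@dataclass
class BinarySensorSeries:
    """0/1 activity of one sensor on the 15-minute grid.

    ``values[i]`` covers the half-open interval
    ``[grid_start + i*15min, grid_start + (i+1)*15min)``; ``grid_start`` is
    anchored to local midnight so bin ``i % 96`` is a fixed time of day.
    """

    sensor_id: str
    values: np.ndarray
    grid_start: datetime
    bins_per_day: int = BINS_PER_DAY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("values must be 0/1")
        if self.bins_per_day * BIN_MINUTES != 24 * 60:
            raise ValueError("bins_per_day inconsistent with 15-minute bins")

    def __len__(self) -> int:
        return int(self.values.size)

    def bin_times(self) -> pd.DatetimeIndex:
        """Start time of every bin."""
        return pd.date_range(self.grid_start, periods=len(self), freq=f"{BIN_MINUTES}min")

    def to_events(self) -> SensorEventLog:
        """Reconstruct a minimal event log: one event at the start of each active bin."""
        times = self.bin_times()
        recs = [(times[i].to_pydatetime(), self.sensor_id)
                for i in np.flatnonzero(self.values)]
        return SensorEventLog(recs)


@dataclass
class HouseholdSeries:
    """A target sensor series y plus J aligned covariate sensor series z_j."""

    target: BinarySensorSeries
    covariates: list[BinarySensorSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.covariates:
            if len(s) != len(self.target) or s.grid_start != self.target.grid_start:
                raise ValueError(
                    f"covariate {s.sensor_id!r} is not aligned with target "
                    f"{self.target.sensor_id!r}"
                )
            if s.sensor_id == self.target.sensor_id:
                raise ValueError("target must not appear among the covariates")

    @property
    def T(self) -> int:
        return len(self.target)

    @property
    def J(self) -> int:
        return len(self.covariates)

    @property
    def y(self) -> np.ndarray:
        return self.target.values

    @property
    def Z(self) -> np.ndarray:
        """Covariate matrix of shape (T, J)."""
        if not self.covariates:
            return np.zeros((self.T, 0), dtype=np.int8)
        return np.stack([s.values for s in self.covariates], axis=1)

    @property
    def covariate_ids(self) -> list[str]:
        return [s.sensor_id for s in self.covariates]


def _check_midnight(start: datetime) -> None:
    if (start.hour, start.minute, start.second, start.microsecond) != (0, 0, 0, 0):
        raise ValueError(f"grid start must be midnight-aligned, got {start!r}")


def binarize_events(
    log: SensorEventLog, sensor_id: str, start: datetime, end: datetime
) -> BinarySensorSeries:
    """Binarize one sensor's events onto the grid spanning [start, end).

    An event at time s lands in the bin with index floor((s - start)/15min),
    i.e. a timestamp exactly on a bin boundary belongs to the *later* bin
    (half-open convention).  Events outside [start, end) are ignored.
    """
    _check_midnight(start)
    if end <= start:
        raise ValueError("end must be after start")
    span = end - start
    n_bins, rem = divmod(span, _BIN)
    if rem:
        raise ValueError("start..end must span a whole number of 15-minute bins")
    values = np.zeros(int(n_bins), dtype=np.int8)
    seen = False
    for idx, (ts, sid) in enumerate(log.records):
        if sid != sensor_id:
            continue
        seen = True
        if isinstance(ts, str):
            try:
                ts = datetime.fromisoformat(ts)
            except ValueError as exc:
                raise ValueError(f"unparseable timestamp in record {idx}: {ts!r}") from exc
        if not isinstance(ts, datetime):
            raise ValueError(f"unparseable timestamp in record {idx}: {ts!r}")
        if start <= ts < end:
            values[int((ts - start) // _BIN)] = 1
    if not seen:
        warnings.warn(
            f"sensor {sensor_id!r} has no events in the log; returning all-zero series",
            stacklevel=2,
        )
    return BinarySensorSeries(sensor_id, values, start)


def assemble_household(
    series: list[BinarySensorSeries], target_id: str
) -> HouseholdSeries:
    """Split a list of aligned series into target y and label-sorted covariates z."""
    ids = [s.sensor_id for s in series]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sensor labels: {dupes}")
    if target_id not in ids:
        raise ValueError(f"target sensor {target_id!r} not among {sorted(ids)}")
    target = next(s for s in series if s.sensor_id == target_id)
    for s in series:
        if len(s) != len(target) or s.grid_start != target.grid_start:
            raise ValueError(
                f"series {s.sensor_id!r} misaligned: length {len(s)} from "
                f"{s.grid_start}, expected length {len(target)} from {target.grid_start}"
            )
    covs = sorted(
        (s for s in series if s.sensor_id != target_id), key=lambda s: s.sensor_id
    )
    return HouseholdSeries(target, covs)


def read_events_csv(path) -> SensorEventLog:
    """Read an event log CSV with columns ``timestamp,sensor_id`` (ISO-8601)."""
    df = pd.read_csv(path)
    missing = {"timestamp", "sensor_id"} - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    bad = df.index[pd.to_datetime(df["timestamp"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"unparseable timestamp in record {int(bad[0])}")
    ts = pd.to_datetime(df["timestamp"])
    return SensorEventLog(
        [(t.to_pydatetime(), str(s)) for t, s in zip(ts, df["sensor_id"])]
    )


def write_events_csv(log: SensorEventLog, path) -> None:
    recs = sorted(log.records)
    pd.DataFrame(
        {"timestamp": [t.isoformat() for t, _ in recs],
         "sensor_id": [s for _, s in recs]}
    ).to_csv(path, index=False)


def write_series_csv(series: list[BinarySensorSeries], path) -> None:
    """Write binarized series in long format: ``datetime,sensor_id,value``."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {"datetime": s.bin_times(), "sensor_id": s.sensor_id, "value": s.values}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series_csv(path) -> list[BinarySensorSeries]:
    """Read the long-format series CSV written by :func:`write_series_csv`."""
    df = pd.read_csv(path, parse_dates=["datetime"])
    out = []
    for sid, grp in df.groupby("sensor_id", sort=True):
        grp = grp.sort_values("datetime")
        out.append(
            BinarySensorSeries(
                str(sid),
                grp["value"].to_numpy(),
                grp["datetime"].iloc[0].to_pydatetime(),
            )
        )
    return out
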