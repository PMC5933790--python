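"""Event-stream pre-processing for both analysis tracks.

The daily-routine (macro) track consumes a per-day grid of 10-minute
activity windows — ``days x 144 x n_sensors`` — scaled so that each
sensor's training-set range maps onto [0, 10].  The agitation-detection
(micro) track consumes hourly per-sensor aggregates grouped into
participant-proximal (G2) and ambient multi-occupancy (G3) sensors.
An inclusion filter keeps only homes with enough continuously-reporting
sensors to support either analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityGrid",
    "aggregate_windows",
    "ActivityScaler",
    "normalise_grid",
    "inclusion_filter",
    "hourly_aggregate",
]


@dataclass
class ActivityGrid:
    """Normalised per-day activity tensor for one home.

    ``values`` has shape (n_days, slots_per_day, n_sensors) with entries in
    [0, 10]; ``scaling`` holds the per-sensor (min, max) learned on the
    training partition and reused unchanged afterwards.
    """

    home_id: str
    days: pd.DatetimeIndex
    values: np.ndarray
    sensor_index: list[str]
    scaling: np.ndarray  # (n_sensors, 2) of (min, max)

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be a (days, slots, sensors) tensor")
        if self.values.shape[0] != len(self.days):
            raise ValueError("day axis does not match the day index")
        if self.values.shape[2] != len(self.sensor_index):
            raise ValueError("sensor axis does not match the sensor index")


def _coerce_timestamps(events: pd.DataFrame) -> pd.DataFrame:
    ts = pd.to_datetime(events["timestamp"], errors="coerce")
    bad = ts.isna()
    if bad.any():
        logger.warning("rejected %d event(s) with unparseable timestamps", int(bad.sum()))
        events = events.loc[~bad].copy()
        ts = ts[~bad]
    events = events.copy()
    events["timestamp"] = ts
    return events


def aggregate_windows(
    events: pd.DataFrame,
    interval_minutes: int = 10,
    n_days: int | None = None,
    start: pd.Timestamp | None = None,
    sensor_index: Sequence[str] | None = None,
) -> tuple[np.ndarray, pd.DatetimeIndex, list[str]]:
    """Bin events into per-day fixed-width slots (half-open ``[t, t+interval)``).

    Cell (d, w, s) is the sum of sensor s's values falling in slot w of day
    d; slots with no events are zero.  Records with unparseable timestamps
    are rejected with a logged count.

    Returns the raw count grid ``(n_days, 1440/interval, n_sensors)``, the
    day index and the sensor order.
    """
    if 1440 % interval_minutes != 0:
        raise ValueError("interval_minutes must divide 1440")
    slots = 1440 // interval_minutes

    events = _coerce_timestamps(events)
    if start is None:
        if events.empty:
            raise ValueError("cannot infer a start date from an empty stream")
        start = events["timestamp"].min().normalize()
    start = pd.Timestamp(start).normalize()
    if n_days is None:
        if events.empty:
            raise ValueError("cannot infer the horizon from an empty stream")
        n_days = int((events["timestamp"].max().normalize() - start).days) + 1
    if sensor_index is None:
        sensor_index = sorted(events["sensor_id"].unique())
    sensor_index = list(sensor_index)
    sensor_pos = {s: i for i, s in enumerate(sensor_index)}

    grid = np.zeros((n_days, slots, len(sensor_index)), dtype=float)
    if not events.empty:
        delta = events["timestamp"] - start
        day = (delta / pd.Timedelta(days=1)).astype(int)
        minute = ((delta - day * pd.Timedelta(days=1)) / pd.Timedelta(minutes=1))
        slot = (minute // interval_minutes).astype(int)
        keep = (day >= 0) & (day < n_days) & events["sensor_id"].isin(sensor_pos)
        sidx = events.loc[keep, "sensor_id"].map(sensor_pos).to_numpy(dtype=int)
        np.add.at(grid,
                  (day[keep].to_numpy(), slot[keep].to_numpy(), sidx),
                  events.loc[keep, "value"].to_numpy(dtype=float))

    day_index = pd.date_range(start, periods=n_days, freq="D")
    return grid, day_index, sensor_index


class ActivityScaler(BaseEstimator, TransformerMixin):
    """Affine per-sensor map of a raw grid onto the fixed [0, 10] range.

    Learns per-sensor (min, max) on the training grid; `transform` applies
    ``10 * (x - min) / (max - min)`` and clips to [0, 10], so test values
    beyond the training range saturate.  A sensor whose training values are
    constant maps to zero everywhere (with a warning).  Fitted state is
    frozen: verification and test data reuse the training scaling unchanged.
    """

    def __init__(self, out_max: float = 10.0):
        self.out_max = out_max

    def fit(self, X: np.ndarray, y=None) -> "ActivityScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a (days, slots, sensors) tensor")
        flat = X.reshape(-1, X.shape[2])
        self.min_ = flat.min(axis=0)
        self.max_ = flat.max(axis=0)
        constant = self.max_ <= self.min_
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} sensor(s) have constant training values; "
                "their normalised activity is identically 0", stacklevel=2)
        self.constant_ = constant
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = np.where(self.constant_, 1.0, self.max_ - self.min_)
        out = self.out_max * (X - self.min_) / span
        out[..., self.constant_] = 0.0
        return np.clip(out, 0.0, self.out_max)

    @property
    def scaling_(self) -> np.ndarray:
        return np.stack([self.min_, self.max_], axis=1)


def normalise_grid(
    raw: np.ndarray,
    days: pd.DatetimeIndex,
    sensor_index: Sequence[str],
    home_id: str = "",
    scaler: ActivityScaler | None = None,
) -> tuple[ActivityGrid, ActivityScaler]:
    """Scale a raw count grid to [0, 10]; fit the scaler if none is given."""
    if scaler is None:
        scaler = ActivityScaler().fit(raw)
    values = scaler.transform(raw)
    grid = ActivityGrid(home_id, days, values, list(sensor_index), scaler.scaling_)
    return grid, scaler


def inclusion_filter(
    homes: Mapping[str, pd.DataFrame],
    min_sensors: int = 3,
    min_days: int = 90,
    coverage_fraction: float = 0.9,
    as_of: pd.Timestamp | None = None,
) -> list[str]:
    """Keep homes with >= `min_sensors` sensors reporting near-continuously.

    A sensor qualifies when it reports on at least
    ``coverage_fraction * min_days`` distinct days within the trailing
    `min_days`-day window ending at `as_of` (default: the home's latest
    event).  "Continuous" is deliberately tolerant of brief outages.
    """
    eligible = []
    required_days = coverage_fraction * min_days
    for home_id, events in homes.items():
        if events.empty:
            continue
        events = _coerce_timestamps(events)
        end = (pd.Timestamp(as_of) if as_of is not None
               else events["timestamp"].max()).normalize()
        window_start = end - pd.Timedelta(days=min_days - 1)
        recent = events[(events["timestamp"] >= window_start)
                        & (events["timestamp"] < end + pd.Timedelta(days=1))]
        if recent.empty:
            continue
        days_per_sensor = (
            recent.assign(day=recent["timestamp"].dt.normalize())
            .groupby("sensor_id")["day"].nunique()
        )
        if int((days_per_sensor >= required_days).sum()) >= min_sensors:
            eligible.append(home_id)
    return eligible


def hourly_aggregate(
    events: pd.DataFrame,
    group_map: Mapping[str, str],
    n_days: int | None = None,
    start: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Hourly per-sensor aggregates P_x for the grouped motion-class sensors.

    Every motion-class sensor (PIR, motion, pressure) present in the stream
    must appear in `group_map` (values "G2" or "G3"); other modalities are
    ignored.  Hours are half-open ``[h:00, h+1:00)`` bins and silent hours
    are zero-filled, so the output has exactly one row per
    (sensor, day, hour).

    Returns a DataFrame with columns ``group, sensor_id, day, hour, p_x``.
    """
    bad_groups = set(group_map.values()) - {"G2", "G3"}
    if bad_groups:
        raise ValueError(f"group_map values must be 'G2' or 'G3', got {bad_groups}")
    events = _coerce_timestamps(events)

    motion_class = events["sensor_type"].isin(["pir", "motion", "pressure"])
    unmapped = set(events.loc[motion_class, "sensor_id"]) - set(group_map)
    if unmapped:
        raise ValueError(
            f"motion-class sensor(s) missing from group_map: {sorted(unmapped)}")

    events = events[events["sensor_id"].isin(group_map)]
    if start is None:
        if events.empty:
            raise ValueError("cannot infer a start date from an empty stream")
        start = events["timestamp"].min().normalize()
    start = pd.Timestamp(start).normalize()
    if n_days is None:
        n_days = int((events["timestamp"].max().normalize() - start).days) + 1

    sensors = sorted(group_map)
    index = pd.MultiIndex.from_product(
        [sensors, range(n_days), range(24)], names=["sensor_id", "day", "hour"])
    counts = pd.Series(0.0, index=index)
    if not events.empty:
        delta = events["timestamp"] - start
        day = (delta / pd.Timedelta(days=1)).astype(int)
        hour = events["timestamp"].dt.hour
        keep = (day >= 0) & (day < n_days)
        observed = (
            pd.DataFrame({"sensor_id": events.loc[keep, "sensor_id"],
                          "day": day[keep], "hour": hour[keep],
                          "value": events.loc[keep, "value"]})
            .groupby(["sensor_id", "day", "hour"])["value"].sum()
        )
        counts.loc[observed.index] = observed

    out = counts.rename("p_x").reset_index()
    out.insert(0, "group", out["sensor_id"].map(group_map))
    return out
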