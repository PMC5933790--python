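"""Synthetic ambient-sensor home deployments with known ground truth.

Real in-home monitoring deployments for people living with dementia are not
publicly deposited, so this module generates event streams that emulate one:
passive-infrared and motion sensors, chair/bed pressure mats, a front-door
contact and a mains energy meter, each firing according to a per-sensor
24-hour piecewise-constant rate profile.  Days are a mixture of high-active
and low-active days; visitor days, away days, sensor dropout windows,
agitation (AIA) episodes with repetitive participant-proximal motion, and
out-of-range physiological readings can be injected on a known schedule,
which is returned alongside the events as ground truth.

Event sensors are simulated as inhomogeneous Poisson processes with hourly
piecewise-constant rates; the energy meter emits one continuous hourly
consumption reading (baseline plus activity-proportional noise) instead of
point events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SensorSpec",
    "HomeProfile",
    "AIAEpisode",
    "AnomalySchedule",
    "GroundTruth",
    "default_profile",
    "default_group_map",
    "simulate_home",
    "simulate_physiology",
    "simulate_deployment",
    "DEFAULT_CLINICAL_THRESHOLDS",
    "VITALS",
]

EVENT_SENSOR_TYPES = ("pir", "motion", "pressure", "door")
START_DATE = pd.Timestamp("2024-01-01")  # arbitrary naive local origin


@dataclass(frozen=True)
class SensorSpec:
    """One deployed sensor: stable id, modality and location label."""

    sensor_id: str
    type: str
    location: str


def _rates(base: float, night: float, peaks: Mapping[tuple[int, int], float]) -> np.ndarray:
    """24 hourly rates: `night` for 0-6 and 23, `base` otherwise, peak overrides."""
    r = np.full(24, base, dtype=float)
    r[:7] = night
    r[23] = night
    for (h0, h1), v in peaks.items():
        r[h0:h1] = v
    return r


# Qualitative daily routine: hallway traffic in the 8-11 morning window,
# living-room occupancy in the evening, kitchen activity around meals,
# bed pressure at night, chair pressure through the day.
DEFAULT_ROUTINE: dict[str, np.ndarray] = {
    "pir_hallway": _rates(20.0, 2.0, {(8, 11): 60.0}),
    "pir_living": _rates(30.0, 2.0, {(20, 22): 80.0}),
    "motion_kitchen": _rates(15.0, 1.0, {(8, 9): 80.0, (13, 14): 80.0, (18, 19): 80.0}),
    "motion_bedroom_door": _rates(5.0, 3.0, {(7, 8): 40.0, (22, 23): 40.0}),
    "motion_bathroom_door": _rates(20.0, 5.0, {}),
    "pressure_chair": _rates(10.0, 0.0, {(10, 12): 40.0, (14, 17): 40.0, (20, 22): 40.0}),
    "pressure_bed": _rates(3.0, 30.0, {(22, 23): 30.0}),
    "door_front": _rates(5.0, 0.0, {}),
}

DEFAULT_SENSORS: tuple[SensorSpec, ...] = (
    SensorSpec("pir_hallway", "pir", "hallway"),
    SensorSpec("pir_living", "pir", "living room"),
    SensorSpec("motion_kitchen", "motion", "kitchen"),
    SensorSpec("motion_bedroom_door", "motion", "bedroom door"),
    SensorSpec("motion_bathroom_door", "motion", "bathroom door"),
    SensorSpec("pressure_chair", "pressure", "chair"),
    SensorSpec("pressure_bed", "pressure", "bed"),
    SensorSpec("door_front", "door", "front door"),
    SensorSpec("energy_main", "energy", "mains"),
)

# Participant-proximal (G2) versus ambient multi-occupancy (G3) motion sensors.
DEFAULT_G2 = ("pressure_chair", "pressure_bed", "motion_bedroom_door")
DEFAULT_G3 = ("pir_living", "pir_hallway", "motion_kitchen")


@dataclass(frozen=True)
class HomeProfile:
    """Static description of one simulated home.

    Parameters
    ----------
    home_id : opaque identifier carried into every output row.
    sensors : deployed roster; defaults to the nine-sensor deployment
        (2 PIR, 3 motion, 2 pressure mats, door contact, energy meter).
    routine : per event-sensor array of 24 hourly event rates (events/hour).
    high_low_mix : probability that a day is high-active.
    rate_multipliers : (low-day, high-day) scalars applied to every routine.
    """

    home_id: str = "home-001"
    sensors: tuple[SensorSpec, ...] = DEFAULT_SENSORS
    routine: Mapping[str, np.ndarray] = field(default_factory=lambda: dict(DEFAULT_ROUTINE))
    high_low_mix: float = 0.5
    rate_multipliers: tuple[float, float] = (0.7, 1.3)

    def validate(self) -> None:
        if not 0.0 <= self.high_low_mix <= 1.0:
            raise ValueError(f"high_low_mix must be in [0, 1], got {self.high_low_mix}")
        if any(m <= 0 for m in self.rate_multipliers):
            raise ValueError("rate multipliers must be > 0")
        for spec in self.event_sensors():
            if spec.sensor_id not in self.routine:
                raise ValueError(f"sensor {spec.sensor_id!r} has no routine rate profile")
            rates = np.asarray(self.routine[spec.sensor_id], dtype=float)
            if rates.shape != (24,):
                raise ValueError(f"routine for {spec.sensor_id!r} must have 24 hourly rates")
            if (rates < 0).any():
                raise ValueError(f"negative rate in routine for {spec.sensor_id!r}")

    def event_sensors(self) -> tuple[SensorSpec, ...]:
        return tuple(s for s in self.sensors if s.type in EVENT_SENSOR_TYPES)

    def energy_sensors(self) -> tuple[SensorSpec, ...]:
        return tuple(s for s in self.sensors if s.type == "energy")


def default_profile(home_id: str = "home-001") -> HomeProfile:
    return HomeProfile(home_id=home_id)


def default_group_map(profile: HomeProfile | None = None) -> dict[str, str]:
    """Map participant-proximal sensors to G2 and ambient ones to G3."""
    return {**{s: "G2" for s in DEFAULT_G2}, **{s: "G3" for s in DEFAULT_G3}}


@dataclass(frozen=True)
class AIAEpisode:
    """An agitation episode: repetitive motion on `day` during [hour_start, hour_end)."""

    day: int
    hour_start: int
    hour_end: int
    physio_vitals: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.hour_start < self.hour_end <= 24:
            raise ValueError(f"episode hours must satisfy 0 <= start < end <= 24, got "
                             f"[{self.hour_start}, {self.hour_end})")


@dataclass(frozen=True)
class AnomalySchedule:
    """Days on which the normal routine is perturbed, with known labels.

    `visitor_days` multiply ambient (G3) rates, `away_days` scale every
    non-energy sensor to near zero, `dropout` silences one sensor over an
    inclusive day range, and `aia_episodes` multiply participant-proximal
    (G2) rates — and more weakly ambient rates — during the episode hours.
    """

    visitor_days: frozenset[int] = frozenset()
    away_days: frozenset[int] = frozenset()
    dropout: tuple[tuple[str, tuple[int, int]], ...] = ()
    aia_episodes: tuple[AIAEpisode, ...] = ()
    visitor_multiplier: float = 3.0
    away_multiplier: float = 0.02
    # Agitated, repetitive motion is an additional event process layered on
    # top of the routine (Poisson superposition): a multiplicative model
    # would make identical agitation look different by time of day and emit
    # nothing at all over a zero-rate baseline (e.g. the chair at night).
    aia_g2_rate: float = 120.0  # extra events/hour on each G2 sensor
    aia_g3_rate: float = 30.0  # weaker ambient echo (pacing) on G3 sensors
    g2_sensors: tuple[str, ...] = DEFAULT_G2
    g3_sensors: tuple[str, ...] = DEFAULT_G3

    def __post_init__(self) -> None:
        object.__setattr__(self, "visitor_days", frozenset(self.visitor_days))
        object.__setattr__(self, "away_days", frozenset(self.away_days))

    def dropout_days(self) -> frozenset[int]:
        days: set[int] = set()
        for _sensor, (d0, d1) in self.dropout:
            days.update(range(d0, d1 + 1))
        return frozenset(days)

    def aia_days(self) -> frozenset[int]:
        return frozenset(ep.day for ep in self.aia_episodes)

    def validate(self, days: int) -> None:
        if self.visitor_multiplier <= 1:
            raise ValueError("visitor_multiplier must be > 1")
        groups = {
            "visitor": self.visitor_days,
            "away": self.away_days,
            "dropout": self.dropout_days(),
            "aia": self.aia_days(),
        }
        for name, dayset in groups.items():
            bad = [d for d in dayset if not 0 <= d < days]
            if bad:
                raise ValueError(
                    f"{name} day {min(bad)} outside the simulated horizon of {days} days")
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = groups[a] & groups[b]
                if overlap:
                    raise ValueError(
                        f"{a} and {b} day sets overlap on day {min(overlap)}")

    def day_label(self, day: int) -> str:
        if day in self.away_days:
            return "away"
        if day in self.visitor_days:
            return "visitor"
        if day in self.aia_days():
            return "aia"
        if day in self.dropout_days():
            return "dropout"
        return "normal"


@dataclass
class GroundTruth:
    """Per-day, per-hour and per-reading labels matching one simulated home."""

    home_id: str
    day_labels: list[str]
    hour_labels: np.ndarray  # (days, 24) array of {"normal", "AIA"}
    physio_labels: pd.DataFrame | None = None  # aligned with the physiology series

    def to_dict(self) -> dict:
        out = {
            "home_id": self.home_id,
            "day_labels": list(self.day_labels),
            "hour_labels": self.hour_labels.tolist(),
        }
        if self.physio_labels is not None:
            out["physio_labels"] = self.physio_labels["label"].tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        physio = None
        if "physio_labels" in d:
            physio = pd.DataFrame({"label": d["physio_labels"]})
        return cls(
            home_id=d["home_id"],
            day_labels=list(d["day_labels"]),
            hour_labels=np.asarray(d["hour_labels"], dtype=object),
            physio_labels=physio,
        )


def _effective_rate(
    profile: HomeProfile,
    schedule: AnomalySchedule,
    sensor: SensorSpec,
    day: int,
    hour: int,
    day_mult: float,
    episodes_by_day: Mapping[int, list[AIAEpisode]],
) -> float:
    rate = float(profile.routine[sensor.sensor_id][hour]) * day_mult
    if day in schedule.away_days:
        return rate * schedule.away_multiplier
    if day in schedule.visitor_days and sensor.sensor_id in schedule.g3_sensors:
        rate *= schedule.visitor_multiplier
    for ep in episodes_by_day.get(day, ()):
        if ep.hour_start <= hour < ep.hour_end:
            if sensor.sensor_id in schedule.g2_sensors:
                rate += schedule.aia_g2_rate
            elif sensor.sensor_id in schedule.g3_sensors:
                rate += schedule.aia_g3_rate
    return rate


def simulate_home(
    profile: HomeProfile,
    schedule: AnomalySchedule,
    days: int,
    seed: int,
    start: pd.Timestamp = START_DATE,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one home's event stream and its ground-truth labels.

    Event sensors fire as inhomogeneous Poisson processes with hourly
    piecewise-constant effective rates (routine rate x high/low day
    multiplier x schedule multiplier); the energy meter contributes one
    hourly consumption reading.  Identical arguments yield identical output.

    Returns
    -------
    events : DataFrame with columns
        ``timestamp, home_id, sensor_id, sensor_type, location, value``,
        sorted by timestamp; firing events carry value 1.0.
    truth : GroundTruth with per-day and per-hour labels (physiology labels
        are attached by :func:`simulate_physiology`).
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    profile.validate()
    schedule.validate(days)

    rng = np.random.default_rng(seed)
    episodes_by_day: dict[int, list[AIAEpisode]] = {}
    for ep in schedule.aia_episodes:
        episodes_by_day.setdefault(ep.day, []).append(ep)

    dropout_lookup: dict[str, set[int]] = {}
    for sensor_id, (d0, d1) in schedule.dropout:
        dropout_lookup.setdefault(sensor_id, set()).update(range(d0, d1 + 1))

    low_mult, high_mult = profile.rate_multipliers
    is_high = rng.random(days) < profile.high_low_mix
    day_mults = np.where(is_high, high_mult, low_mult)

    event_sensors = profile.event_sensors()
    energy_sensors = profile.energy_sensors()
    minute_chunks: list[np.ndarray] = []
    value_chunks: list[np.ndarray] = []
    chunk_sensors: list[SensorSpec] = []
    for day in range(days):
        away = day in schedule.away_days
        for sensor in event_sensors:
            if day in dropout_lookup.get(sensor.sensor_id, ()):
                continue
            rates = np.array([
                _effective_rate(profile, schedule, sensor, day, hour,
                                day_mults[day], episodes_by_day)
                for hour in range(24)])
            counts = rng.poisson(rates)
            total = int(counts.sum())
            if total == 0:
                continue
            hours = np.repeat(np.arange(24), counts)
            minutes = day * 1440.0 + hours * 60.0 + rng.random(total) * 60.0
            minute_chunks.append(minutes)
            value_chunks.append(np.ones(total))
            chunk_sensors.append(sensor)
        for sensor in energy_sensors:
            if day in dropout_lookup.get(sensor.sensor_id, ()):
                continue
            # the meter reports a consumption value every 10 minutes,
            # proportional to household activity plus a standing baseline
            if away:
                activity = np.zeros(24)
            else:
                activity = sum(
                    np.asarray(profile.routine[s.sensor_id], dtype=float)
                    for s in event_sensors) * day_mults[day]
            per_tick = np.repeat((0.15 + 0.01 * activity) / 6.0, 6)
            values = np.maximum(0.0, per_tick + rng.normal(0.0, 0.004, 144))
            minute_chunks.append(day * 1440.0 + np.arange(144) * 10.0 + 5.0)
            value_chunks.append(np.round(values, 6))
            chunk_sensors.append(sensor)

    if minute_chunks:
        minutes = np.concatenate(minute_chunks)
        values = np.concatenate(value_chunks)
        sensor_idx = np.concatenate([
            np.full(len(chunk), i, dtype=int)
            for i, chunk in zip(
                (profile.sensors.index(s) for s in chunk_sensors),
                minute_chunks)])
    else:
        minutes = np.empty(0)
        values = np.empty(0)
        sensor_idx = np.empty(0, dtype=int)

    roster = list(profile.sensors)
    events = pd.DataFrame({
        "timestamp": start + pd.to_timedelta(np.round(minutes * 60.0, 6),
                                             unit="s"),
        "home_id": profile.home_id,
        "sensor_id": [roster[i].sensor_id for i in sensor_idx],
        "sensor_type": [roster[i].type for i in sensor_idx],
        "location": [roster[i].location for i in sensor_idx],
        "value": values,
    })
    events = events.sort_values(
        ["timestamp", "sensor_id"], kind="mergesort").reset_index(drop=True)

    day_labels = [schedule.day_label(d) for d in range(days)]
    hour_labels = np.full((days, 24), "normal", dtype=object)
    for ep in schedule.aia_episodes:
        hour_labels[ep.day, ep.hour_start:ep.hour_end] = "AIA"
    truth = GroundTruth(profile.home_id, day_labels, hour_labels)
    return events, truth


# name, unit, clinical (lower, upper), in-range mean, in-range sd
VITALS: tuple[tuple[str, str, tuple[float, float], float, float], ...] = (
    ("systolic_bp", "mmHg", (90.0, 160.0), 125.0, 8.0),
    ("diastolic_bp", "mmHg", (60.0, 100.0), 78.0, 6.0),
    ("heart_rate", "bpm", (50.0, 110.0), 72.0, 7.0),
    ("body_temperature", "degC", (36.0, 37.8), 36.8, 0.25),
    ("weight", "kg", (50.0, 110.0), 74.0, 1.0),
    ("hydration", "percent", (45.0, 65.0), 55.0, 2.0),
)

DEFAULT_CLINICAL_THRESHOLDS: dict[str, tuple[float, float]] = {
    name: bounds for name, _unit, bounds, _mu, _sd in VITALS
}

READING_HOURS = (8, 20)  # twice-daily self-measurements


def simulate_physiology(
    profile: HomeProfile,
    schedule: AnomalySchedule,
    days: int,
    seed: int,
    start: pd.Timestamp = START_DATE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Twice-daily vital-sign readings with known in/out-of-range labels.

    On AIA-episode days whose episode lists vitals under ``physio_vitals``,
    both of that day's readings for those vitals are pushed strictly above
    the upper clinical threshold; every other reading is drawn inside its
    clinical range (clipped into the central 90% of the interval).

    Returns
    -------
    physio : DataFrame ``timestamp, home_id, vital, value, unit``.
    labels : DataFrame aligned row-for-row with `physio`, single column
        ``label`` in {"in-range", "out-of-range"}.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    schedule.validate(days)
    rng = np.random.default_rng(seed)

    excursions: dict[int, set[str]] = {}
    for ep in schedule.aia_episodes:
        if ep.physio_vitals:
            excursions.setdefault(ep.day, set()).update(ep.physio_vitals)
    known = {name for name, *_ in VITALS}
    for vitals in excursions.values():
        unknown = vitals - known
        if unknown:
            raise ValueError(f"unknown vital(s) in schedule: {sorted(unknown)}")

    rows, label_rows = [], []
    for day in range(days):
        day_start = start + pd.Timedelta(days=day)
        for hour in READING_HOURS:
            ts = day_start + pd.Timedelta(hours=hour)
            for name, unit, (lo, hi), mu, sd in VITALS:
                span = hi - lo
                if name in excursions.get(day, ()):
                    value = hi + abs(rng.normal(0.10 * span, 0.05 * span)) + 1e-6
                    label = "out-of-range"
                else:
                    value = float(np.clip(rng.normal(mu, sd),
                                          lo + 0.05 * span, hi - 0.05 * span))
                    label = "in-range"
                rows.append((ts, profile.home_id, name, round(float(value), 4), unit))
                label_rows.append(label)

    physio = pd.DataFrame(
        rows, columns=["timestamp", "home_id", "vital", "value", "unit"])
    labels = pd.DataFrame({"label": label_rows})
    return physio, labels


def simulate_deployment(
    profile: HomeProfile,
    schedule: AnomalySchedule,
    days: int,
    seed: int,
    start: pd.Timestamp = START_DATE,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Events + physiology + complete ground truth for one home.

    The event stream and the physiology series are drawn from independent
    sub-streams of `seed`, so each matches its single-call counterpart.
    """
    ev_seed, ph_seed = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
    events, truth = simulate_home(profile, schedule, days, int(ev_seed), start=start)
    physio, labels = simulate_physiology(profile, schedule, days, int(ph_seed), start=start)
    truth.physio_labels = labels
    return events, physio, truth
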