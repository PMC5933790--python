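"""File formats for simulator output and analysis artifacts.

Events and physiology travel as plain CSV (ISO-8601 timestamps), ground
truth and evaluation results as JSON, and every run directory carries a
manifest recording the package version, the resolved configuration and
all seeds, so a run can be replayed bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .simulate import GroundTruth

EVENT_COLUMNS = ["timestamp", "home_id", "sensor_id", "sensor_type", "location", "value"]
PHYSIO_COLUMNS = ["timestamp", "home_id", "vital", "value", "unit"]


def write_events(events: pd.DataFrame, path: Path | str) -> None:
    events.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_events(path: Path | str) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"events file {path} lacks column(s) {sorted(missing)}")
    events["timestamp"] = pd.to_datetime(events["timestamp"])
    return events


def write_physio(physio: pd.DataFrame, path: Path | str) -> None:
    physio.to_csv(path, index=False, columns=PHYSIO_COLUMNS)


def read_physio(path: Path | str) -> pd.DataFrame:
    physio = pd.read_csv(path)
    missing = set(PHYSIO_COLUMNS) - set(physio.columns)
    if missing:
        raise ValueError(f"physiology file {path} lacks column(s) {sorted(missing)}")
    physio["timestamp"] = pd.to_datetime(physio["timestamp"])
    return physio


def write_truth(truths: dict[str, GroundTruth], path: Path | str) -> None:
    payload = {home_id: t.to_dict() for home_id, t in truths.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: Path | str) -> dict[str, GroundTruth]:
    payload = json.loads(Path(path).read_text())
    return {home_id: GroundTruth.from_dict(d) for home_id, d in payload.items()}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path: Path | str, config: dict, seeds: dict[str, int]) -> None:
    manifest = {
        "package": "adlsense",
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "seeds": seeds,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))


def read_manifest(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())
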