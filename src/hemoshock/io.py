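"""Configuration loading, time-series persistence and run manifests."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .engine import EngineParams
from .scenario import ScenarioConfig, TimeSeriesRecord

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "save_config",
    "write_timeseries",
    "read_timeseries",
    "TIMESERIES_COLUMNS",
]

# Fixed, documented CSV header (units in the key names).
TIMESERIES_COLUMNS = [
    "time_s",
    "heart_rate_per_min",
    "systolic_mmHg",
    "diastolic_mmHg",
    "map_mmHg",
    "cvp_mmHg",
    "blood_volume_mL",
    "ph",
    "lactate_mmol_L",
    "respiration_per_min",
    "shock_index",
]

_RECORD_FIELDS = ["time", "heart_rate", "systolic", "diastolic", "map", "cvp",
                  "blood_volume", "ph", "lactate", "respiration_rate",
                  "shock_index"]


class ConfigError(ValueError):
    """Scenario/engine configuration failed validation."""


@dataclass
class RunManifest:
    """Provenance for one simulation run: config snapshot, seed, outputs."""

    seed: int
    config: dict
    outputs: list[str] = field(default_factory=list)
    software_version: str = __version__
    created_unix: float = field(default_factory=time.time)
    wall_time_s: float = 0.0

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def _coerce_section(cls, data: dict, section: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = known[key]
        if isinstance(value, list) and "tuple" in str(f.type):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path: str | Path) -> tuple[ScenarioConfig, EngineParams]:
    """Load a YAML or JSON scenario file.

    Two optional sections, ``scenario`` and ``engine``, override the
    defaults; unknown sections or keys are rejected with the offending key
    named.  An empty file yields pure defaults (dt = 0.05 s, q_w = 0.04, …).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - {"scenario", "engine"}
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")

    scenario = _coerce_section(ScenarioConfig, data.get("scenario") or {},
                               "scenario")
    engine_data = dict(data.get("engine") or {})
    if "gains" in engine_data:
        from .baroreflex import EfferentGains
        engine_data["gains"] = _coerce_section(EfferentGains,
                                               engine_data["gains"],
                                               "engine.gains")
    params = _coerce_section(EngineParams, engine_data, "engine")
    return scenario, params


def save_config(path: str | Path, scenario: ScenarioConfig,
                params: EngineParams | None = None) -> Path:
    """Write a round-trippable YAML config (load_config(save_config(x)) == x)."""
    path = Path(path)
    doc: dict = {"scenario": asdict(scenario)}
    if params is not None:
        doc["engine"] = asdict(params)
        doc["engine"]["gains"] = asdict(params.gains)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def write_timeseries(records: list[TimeSeriesRecord], path: str | Path) -> Path:
    """Write records as CSV with the fixed documented header."""
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    rows = {col: [getattr(r, f) for r in records]
            for col, f in zip(TIMESERIES_COLUMNS, _RECORD_FIELDS)}
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a time-series CSV back; validates the fixed header."""
    df = pd.read_csv(path)
    if list(df.columns) != TIMESERIES_COLUMNS:
        raise ValueError(
            f"unexpected columns in {path}: {list(df.columns)}")
    return df
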