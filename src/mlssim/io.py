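"""Reading and writing of the package's file formats.

Tidy CSV for time series (comma-separated, dot decimal, header row, UTF-8;
times in seconds for traces/breaths and minutes for lactate series), JSON
for athletes and results, YAML for model constants and run configs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelConstants
from .types import Athlete, BreathSeries, LactateSeries, PowerTrace

__all__ = [
    "write_power_trace",
    "read_power_trace",
    "write_breath_series",
    "read_breath_series",
    "write_lactate_series",
    "read_lactate_series",
    "write_athlete",
    "read_athlete",
    "write_constants",
    "read_constants",
    "to_jsonable",
    "write_json",
]


def write_power_trace(trace: PowerTrace, path) -> None:
    pd.DataFrame({"time_s": trace.sample_times, "power_w": trace.power}).to_csv(
        path, index=False
    )


def read_power_trace(path) -> PowerTrace:
    df = pd.read_csv(path)
    return PowerTrace(df["time_s"].to_numpy(), df["power_w"].to_numpy())


def write_breath_series(breaths: BreathSeries, path) -> None:
    pd.DataFrame(
        {
            "time_s": breaths.sample_times,
            "vo2_ml_min": breaths.vo2,
            "vco2_ml_min": breaths.vco2,
            "load_w": breaths.load,
        }
    ).to_csv(path, index=False)


def read_breath_series(path) -> BreathSeries:
    df = pd.read_csv(path)
    return BreathSeries(
        df["time_s"].to_numpy(),
        df["vo2_ml_min"].to_numpy(),
        df["vco2_ml_min"].to_numpy(),
        df["load_w"].to_numpy(),
    )


def write_lactate_series(series: LactateSeries, path) -> None:
    df = pd.DataFrame({"time_min": series.sample_times, "blc_mmol_l": series.blc})
    df["load_w"] = series.load
    df["duration_min"] = series.duration
    df.to_csv(path, index=False)


def read_lactate_series(path) -> LactateSeries:
    df = pd.read_csv(path)
    return LactateSeries(
        df["time_min"].to_numpy(),
        df["blc_mmol_l"].to_numpy(),
        load=float(df["load_w"].iloc[0]) if "load_w" in df else 0.0,
        duration=float(df["duration_min"].iloc[0]) if "duration_min" in df else None,
    )


def write_athlete(athlete: Athlete, path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(athlete), indent=2, sort_keys=True) + "\n"
    )


def read_athlete(path) -> Athlete:
    return Athlete(**json.loads(Path(path).read_text()))


def write_constants(constants: ModelConstants, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(constants), sort_keys=True)
    )


def read_constants(path) -> ModelConstants:
    return ModelConstants(**yaml.safe_load(Path(path).read_text()))


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy values to JSON-friendly types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(to_jsonable(obj), indent=2, sort_keys=True) + "\n")
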