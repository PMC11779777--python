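"""File dialects and run configuration.

All on-disk formats are plain text: JSON (UTF-8, sorted keys) for shape sets,
CSV (UTF-8, comma separator, '.' decimal, mandatory header) for traces and
trial logs.  Units in files are fixed at cm and ms; seconds and cm^2 appear
only in derived outputs.

Dialect reference
-----------------
shape set JSON : set_id, n_points, step_distance, shapes (list of {shape_id,
                 points [[x, y], ...] closed}), distance_matrix (8x8)
trace CSV      : trial_id, shape_id, hand, session_day, t_ms, x_cm, y_cm,
                 pen_down — one row per sample
trial-log CSV  : participant_id, group, time_point, trial_index, target_id,
                 chosen_id, rt_ms
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assessment import GROUPS, TIME_POINTS
from .exceptions import SchemaError
from .kinematics import Trace
from .shapes import ShapeSet, ContourShape, SynthesisConfig

TRACE_COLUMNS = ["trial_id", "shape_id", "hand", "session_day",
                 "t_ms", "x_cm", "y_cm", "pen_down"]
TRIAL_COLUMNS = ["participant_id", "group", "time_point", "trial_index",
                 "target_id", "chosen_id", "rt_ms"]


# ---------------------------------------------------------------------------
# Shape sets
# ---------------------------------------------------------------------------

def write_shape_set(shape_set: ShapeSet, path) -> None:
    payload = {
        "set_id": shape_set.set_id,
        "n_points": shape_set.shapes[0].n_points,
        "step_distance": shape_set.step_distance,
        "shapes": [{"shape_id": s.shape_id,
                    "points": np.round(s.points, 12).tolist()}
                   for s in shape_set.shapes],
        "distance_matrix": np.round(shape_set.distance_matrix, 12).tolist(),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")


def read_shape_set(path) -> ShapeSet:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise SchemaError(f"malformed shape-set JSON: {e}") from e
    for key in ("set_id", "shapes", "step_distance", "distance_matrix"):
        if key not in payload:
            raise SchemaError(f"shape-set JSON missing field '{key}'")
    shapes = [ContourShape(np.asarray(s["points"], float), shape_id=int(s["shape_id"]))
              for s in payload["shapes"]]
    return ShapeSet(shapes=shapes, step_distance=float(payload["step_distance"]),
                    distance_matrix=np.asarray(payload["distance_matrix"], float),
                    set_id=payload["set_id"])


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def write_traces(traces: list[Trace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "trial_id": tr.trial_id, "shape_id": tr.shape_id, "hand": tr.hand,
            "session_day": tr.session_day, "t_ms": tr.t_ms, "x_cm": tr.x_cm,
            "y_cm": tr.y_cm, "pen_down": tr.pen_down.astype(int)}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[Trace]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"trace CSV missing column(s): {sorted(missing)}")
    traces = []
    for (tid, sid, hand, day), block in df.groupby(
            ["trial_id", "shape_id", "hand", "session_day"], sort=False):
        t = block["t_ms"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            row = int(block.index[np.argmax(np.diff(t) <= 0) + 1])
            raise SchemaError(
                f"non-monotone t_ms in trial {tid} at CSV row {row + 2}")
        traces.append(Trace(t_ms=t, x_cm=block["x_cm"].to_numpy(float),
                            y_cm=block["y_cm"].to_numpy(float),
                            pen_down=block["pen_down"].to_numpy(bool),
                            trial_id=int(tid), shape_id=int(sid),
                            hand=str(hand), session_day=int(day)))
    return traces


# ---------------------------------------------------------------------------
# Trial logs
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"trial CSV missing column(s): {sorted(missing)}")
    bad_group = set(df["group"].unique()) - set(GROUPS)
    if bad_group:
        raise SchemaError(f"unknown group label(s): {sorted(bad_group)}")
    bad_tp = set(df["time_point"].unique()) - set(TIME_POINTS)
    if bad_tp:
        raise SchemaError(f"unknown time_point value(s): {sorted(bad_tp)}")
    ids = df[["target_id", "chosen_id"]].to_numpy(int)
    if ids.min() < 1 or ids.max() > 8:
        raise SchemaError("target_id/chosen_id outside 1..8")
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level configuration of a pipeline run."""

    experiment: int = 1
    seed: int = 0
    out_dir: str = "run-output"
    shape_config: SynthesisConfig = field(default_factory=SynthesisConfig)
    kernel_lapse: float = 0.01
    n_trace_trials_per_shape: int = 3
    group_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        shape_cfg = SynthesisConfig(**raw.pop("shapes", {}))
        known = {"experiment", "seed", "out_dir", "kernel_lapse",
                 "n_trace_trials_per_shape", "group_overrides"}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(shape_config=shape_cfg, **raw)
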