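"""Reading and writing the package's plain-text artifact formats.

Formats: marker trajectories as wide TSV (``time_s`` then ``<marker>_{x,y,z}``
in metres), angle series as two-column CSV (``time_s, angle_deg``), trial
tables as CSV with a versioned header comment, ground truth and results as
JSON, run configuration as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import MARKER_NAMES, AngleSeries, MarkerFrameSeries
from .simulate import GroundTruth

TRIAL_TABLE_VERSION = "groovesync-trial-table-v1"


def write_marker_tsv(series: MarkerFrameSeries, path) -> None:
    cols = {"time_s": series.times}
    for name in series.markers:
        xyz = series.marker(name)
        for k, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = xyz[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_marker_tsv(path, markers: tuple[str, ...] = MARKER_NAMES) -> MarkerFrameSeries:
    frame = pd.read_csv(path, sep="\t")
    if "time_s" not in frame.columns:
        raise ValueError(f"{path}: missing time_s column")
    t = frame["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two frames")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling")
    positions = np.empty((len(t), len(markers), 3))
    for j, name in enumerate(markers):
        for k, ax in enumerate("xyz"):
            col = f"{name}_{ax}"
            if col not in frame.columns:
                raise ValueError(f"{path}: missing marker column {col}")
            positions[:, j, k] = frame[col].to_numpy()
    return MarkerFrameSeries(positions, 1.0 / dt[0], markers)


def write_angle_csv(series: AngleSeries, path) -> None:
    pd.DataFrame({"time_s": series.times, "angle_deg": series.values}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_angle_csv(path) -> AngleSeries:
    frame = pd.read_csv(path, comment="#")
    t = frame["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    return AngleSeries(frame["angle_deg"].to_numpy(), 1.0 / (t[1] - t[0]))


def write_trial_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {TRIAL_TABLE_VERSION}\n")
        table.to_csv(fh, index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "dgp": {
            "intercepts": truth.dgp.intercepts,
            "paths": {f"{src}->{dst}": v for (src, dst), v in truth.dgp.paths.items()},
            "random_intercept_sd": truth.dgp.random_intercept_sd,
            "residual_sd": truth.dgp.residual_sd,
            "rating_bounds": list(truth.dgp.rating_bounds),
        },
        "seed": truth.seed,
        "latent": truth.latent.to_dict(orient="list"),
        "participant_intercepts": {
            "participant": truth.participant_intercepts.index.tolist(),
            **truth.participant_intercepts.to_dict(orient="list"),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
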