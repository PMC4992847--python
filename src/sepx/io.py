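"""CSV / JSON output: the package's only wire formats.

All tabular results are plain CSV with headers, numbers printed with 12
significant digits; analytic coefficients and the echoed run configuration
travel in a small JSON sidecar next to the CSV.  Everything is
deterministic, so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .scans import VmaxMap
from .separatrix import SampledBoundary, SeparatrixLine, ThresholdPlane, ThresholdPoint
from .threshold import ThresholdTrace

__all__ = [
    "FLOAT_FMT",
    "write_trajectory",
    "read_trajectory",
    "write_vmax_map",
    "write_threshold_trace",
    "write_boundary",
    "write_sidecar",
    "separatrix_coefficients",
]

FLOAT_FMT = "%.12g"


def _write_df(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_trajectory(traj: Trajectory, path) -> None:
    _write_df(traj.to_dataframe(), path)


def read_trajectory(path, model=None) -> Trajectory:
    df = pd.read_csv(path, keep_default_na=False)
    state_cols = [c for c in df.columns if c not in ("t", "i_e", "event")]
    events = []
    for t, flag in zip(df["t"], df["event"].astype(str)):
        for kind in filter(None, flag.split("+")):
            events.append((float(t), kind))
    return Trajectory(
        times=df["t"].to_numpy(float),
        states=df[state_cols].to_numpy(float),
        stimulus=df["i_e"].to_numpy(float),
        events=events,
        model_name=model.name if model is not None else "",
        state_names=tuple(state_cols),
    )


def write_vmax_map(vmax_map: VmaxMap, path) -> None:
    _write_df(vmax_map.to_dataframe(), path)


def write_threshold_trace(trace: ThresholdTrace, path) -> None:
    _write_df(
        pd.DataFrame(
            {
                "t": trace.times,
                "theta": trace.theta,
                "theta_direct": trace.theta_direct,
                "method": trace.method,
            }
        ),
        path,
    )


def write_boundary(df: pd.DataFrame, path) -> None:
    _write_df(df, path)


def separatrix_coefficients(obj) -> dict:
    """JSON-ready analytic coefficients of a separatrix object."""
    if isinstance(obj, ThresholdPoint):
        return {"kind": "point", "theta": obj.theta, "v_rest": obj.v_rest, "i_e": obj.i_e}
    if isinstance(obj, SeparatrixLine):
        return {
            "kind": "line",
            "k_theta": obj.k_theta,
            "b_theta": obj.b_theta,
            "i_e": obj.i_e,
            "validity": list(obj.validity),
            "firing_side": "w < k_theta * v + b_theta",
        }
    if isinstance(obj, ThresholdPlane):
        return {
            "kind": "plane",
            "normal": obj.normal.tolist(),
            "point": obj.point.tolist(),
            "spanning_eigenvalues": list(obj.spanning_eigenvalues),
            "dominant_eigenvalue": obj.dominant_eigenvalue,
            "firing_side": obj.firing_side,
            "i_e": obj.i_e,
            "validity": list(obj.validity),
        }
    if isinstance(obj, SampledBoundary):
        return {
            "kind": "sampled",
            "n_points": int(len(obj.points)),
            "parameterization": obj.parameterization,
            "truncated": obj.truncated,
        }
    raise TypeError(f"not a separatrix object: {type(obj).__name__}")


def write_sidecar(path, payload: dict) -> None:
    """JSON sidecar (coefficients, echoed config, ...); stable key order."""
    Path(path).write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
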