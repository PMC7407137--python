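"""Plain-text serialization of count series and trajectory fixtures.

Count series travel as a two-column CSV (``window_index,count``) with a JSON
sidecar (same path + ``.meta.json``) carrying the window duration, the seed
and — for synthetic data — the true generator parameters and latent path.
Trajectory tables are TSV (``frame,molecule_id,z``) with a sidecar holding
slab bounds, box height, frame times and (for fixtures) the schedule.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .counting import CrossingCountSeries, MembraneSlab, TrajectorySlice

__all__ = [
    "write_count_series",
    "read_count_series",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
]


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_count_series(series: CrossingCountSeries, path, seed=None, extra=None) -> None:
    path = Path(path)
    pd.DataFrame(
        {"window_index": np.arange(series.n_windows), "count": series.counts}
    ).to_csv(path, index=False)
    meta = {"window_ps": series.window_ps}
    if series.direction_totals is not None:
        meta["direction_totals"] = list(series.direction_totals)
    if seed is not None:
        meta["seed"] = int(seed)
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=_jsonify))


def read_count_series(path) -> CrossingCountSeries:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"window_index", "count"} <= set(df.columns):
        raise ValueError(f"{path} lacks the window_index,count header")
    df = df.sort_values("window_index")
    window_ps = 10.0
    direction_totals = None
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        window_ps = float(meta.get("window_ps", window_ps))
        if "direction_totals" in meta:
            direction_totals = tuple(int(v) for v in meta["direction_totals"])
    return CrossingCountSeries(
        counts=df["count"].to_numpy(),
        window_ps=window_ps,
        direction_totals=direction_totals,
    )


def write_trajectory_tsv(
    traj: TrajectorySlice, path, slab: Optional[MembraneSlab] = None, extra=None
) -> None:
    path = Path(path)
    nf, nm = traj.z.shape
    frame_col = np.repeat(traj.frames, nm)
    mol_col = np.tile(np.asarray(traj.molecule_ids), nf)
    pd.DataFrame(
        {"frame": frame_col, "molecule_id": mol_col, "z": traj.z.reshape(-1)}
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")
    meta = {
        "times_ps": traj.times_ps.tolist(),
        "box_z": traj.box_z,
    }
    if slab is not None:
        meta["slab"] = {"z_lower": slab.z_lower, "z_upper": slab.z_upper}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, default=_jsonify))


def read_trajectory_tsv(path) -> tuple:
    """Read a trajectory TSV; returns (TrajectorySlice, slab-or-None)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if not {"frame", "molecule_id", "z"} <= set(df.columns):
        raise ValueError(f"{path} lacks the frame,molecule_id,z header")
    wide = df.pivot(index="frame", columns="molecule_id", values="z").sort_index()
    if wide.isna().any().any():
        raise ValueError("molecule missing from some frame")
    sc = _sidecar(path)
    box_z = None
    slab = None
    times = None
    if sc.exists():
        meta = json.loads(sc.read_text())
        box_z = meta.get("box_z")
        if meta.get("slab"):
            slab = MembraneSlab(**meta["slab"])
        if meta.get("times_ps"):
            times = np.asarray(meta["times_ps"], dtype=float)
    frames = wide.index.to_numpy()
    if times is None:
        times = 10.0 * np.arange(len(frames))
    traj = TrajectorySlice(
        frames=frames,
        times_ps=times,
        z=wide.to_numpy(),
        molecule_ids=list(wide.columns),
        box_z=box_z,
    )
    return traj, slab


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
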