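"""Readers and writers for the pipeline's table and HDF5 formats.

Trajectories travel as delimited text with columns
``assay_id, larva_id, frame, t_s, x_mm, y_mm, theta_deg``; calcium data
as an HDF5 container with per-condition groups::

    /traces/<cond>   (n_rois, n_trials, n_frames) raw fluorescence
    /stim/<cond>/l   (n_trials, n_frames) raw left stimulus-ROI trace
    /stim/<cond>/r   (n_trials, n_frames) raw right stimulus-ROI trace
    /tail/<cond>     (n_trials, n_tail_frames) boolean tail activity
    /rois            roi_id, region, side, x, y, z table

Configs are YAML or JSON documents.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import Trajectory
from .encoding import RoiTraceSet

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_calcium_h5",
    "read_calcium_h5",
    "load_config_file",
]

_TRAJ_COLUMNS = ["assay_id", "larva_id", "frame", "t_s", "x_mm", "y_mm", "theta_deg"]


def write_trajectories(
    trajs: list[Trajectory], path: str | Path, assay_id: str = "assay0"
) -> None:
    frames = []
    for traj in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "assay_id": assay_id,
                    "larva_id": traj.larva_id,
                    "frame": np.arange(traj.n_frames),
                    "t_s": traj.t,
                    "x_mm": traj.x,
                    "y_mm": traj.y,
                    "theta_deg": traj.theta,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> dict[str, list[Trajectory]]:
    """Read a trajectory table, returning {assay_id: [Trajectory, ...]}."""
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    out: dict[str, list[Trajectory]] = {}
    for (assay, larva), g in df.groupby(["assay_id", "larva_id"], sort=True):
        g = g.sort_values("frame")
        out.setdefault(str(assay), []).append(
            Trajectory(
                str(larva),
                g["t_s"].to_numpy(),
                g["x_mm"].to_numpy(),
                g["y_mm"].to_numpy(),
                g["theta_deg"].to_numpy(),
            )
        )
    return out


def write_calcium_h5(dataset: RoiTraceSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fps_img"] = dataset.fps_img
        f.attrs["fps_tail"] = dataset.fps_tail
        for cond, arr in dataset.traces.items():
            f.create_dataset(f"traces/{cond}", data=arr)
        for cond, sides in dataset.stim.items():
            for side, arr in sides.items():
                f.create_dataset(f"stim/{cond}/{side}", data=arr)
        for cond, arr in dataset.tail.items():
            f.create_dataset(f"tail/{cond}", data=np.asarray(arr, dtype=bool))
        g = f.create_group("rois")
        info = dataset.roi_info
        g.create_dataset("roi_id", data=info["roi_id"].astype(str).to_numpy(dtype="S"))
        g.create_dataset("region", data=info["region"].astype(str).to_numpy(dtype="S"))
        g.create_dataset("side", data=info["side"].astype(str).to_numpy(dtype="S"))
        for c in ("x", "y", "z"):
            if c in info:
                g.create_dataset(c, data=info[c].to_numpy(dtype=float))


def read_calcium_h5(path: str | Path) -> RoiTraceSet:
    with h5py.File(path, "r") as f:
        traces = {c: f[f"traces/{c}"][()] for c in f["traces"]}
        stim = {
            c: {s: f[f"stim/{c}/{s}"][()] for s in f[f"stim/{c}"]}
            for c in f["stim"]
        }
        tail = (
            {c: f[f"tail/{c}"][()].astype(bool) for c in f["tail"]}
            if "tail" in f
            else {}
        )
        g = f["rois"]
        info = pd.DataFrame(
            {
                "roi_id": [s.decode() for s in g["roi_id"][()]],
                "region": [s.decode() for s in g["region"][()]],
                "side": [s.decode() for s in g["side"][()]],
            }
        )
        for c in ("x", "y", "z"):
            if c in g:
                info[c] = g[c][()]
        return RoiTraceSet(
            traces=traces,
            roi_info=info,
            stim=stim,
            tail=tail,
            fps_img=float(f.attrs.get("fps_img", 2.0)),
            fps_tail=float(f.attrs.get("fps_tail", 200.0)),
        )


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON config document into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}
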