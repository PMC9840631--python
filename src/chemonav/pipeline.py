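"""End-to-end orchestration: simulate -> behavior -> encode -> fluidics.

``run_pipeline`` executes the stages enabled in a validated config,
writes per-stage tables under the output directory, and produces a JSON
manifest (parameters and seeds actually used) plus a report of summary
statistics: zone-time fractions, escape metrics, per-region selectivity
and nonlinear-information distributions, and the dimensionless-number
row.  Outputs are byte-identical across runs with the same config and
seed (no timestamps enter the files).

Group-comparison statistics in the report (Kruskal-Wallis on escape
metrics when several assays/groups are present) are delegated to
scipy.stats and labelled as such.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    ArenaGeometry,
    detect_bouts,
    occupancy_footprint,
    proximity_exclusion,
    segment_crossings,
)
from .config import validate_config
from .encoding import analyze_encoding
from .fluidics import ChannelSpec, characterize_channel
from .io import (
    read_calcium_h5,
    read_trajectories,
    write_calcium_h5,
    write_trajectories,
)
from .synthetic import BehaviorGenConfig, NeuralGenConfig, gen_calcium, gen_trajectory

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _arena_from_cfg(b: dict) -> ArenaGeometry:
    return ArenaGeometry(
        width=b["arena_width_mm"],
        height=b["arena_height_mm"],
        border_x=b["border_x_mm"],
        mirror_border_x=b["mirror_border_x_mm"],
        margin=b["margin_mm"],
        exclusion_distance=b["exclusion_mm"],
    )


def run_pipeline(cfg: dict, output_dir: str | Path | None = None) -> dict:
    """Run the enabled stages and write tables, manifest and report.

    Returns the report dict.  Raises StageError with a stage-tagged
    message if any stage fails.
    """
    cfg = validate_config(cfg)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    manifest = {"version": __version__, "config": cfg}

    traj_path = cfg["behavior"]["trajectories"]
    h5_path = cfg["encoding"]["h5"]

    if cfg["simulate"]["enabled"]:
        try:
            sim_seed = int(cfg["simulate"]["seed"])
            bsim = cfg["simulate"]["behavior"]
            bcfg = BehaviorGenConfig(
                arena=_arena_from_cfg(cfg["behavior"]),
                seed=sim_seed,
                **{k: v for k, v in bsim.items()},
            )
            trajs, bout_log = gen_trajectory(bcfg)
            traj_path = out / "trajectories.csv"
            write_trajectories(trajs, traj_path)
            bout_log.to_csv(out / "true_bouts.csv", index=False)

            csim = dict(cfg["simulate"]["calcium"])
            csim["regions"] = tuple(csim["regions"])
            ncfg = NeuralGenConfig(seed=sim_seed + 1, **csim)
            dataset, truth = gen_calcium(ncfg)
            h5_path = out / "calcium.h5"
            write_calcium_h5(dataset, h5_path)
            truth.to_csv(out / "true_rois.csv", index=False)
            manifest["simulate"] = {
                "behavior": dataclasses.asdict(bcfg),
                "calcium": dataclasses.asdict(ncfg),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"[simulate] {exc}") from exc

    if cfg["behavior"]["enabled"]:
        try:
            if traj_path is None:
                raise ValueError("no trajectory table configured or simulated")
            b = cfg["behavior"]
            arena = _arena_from_cfg(b)
            assays = read_trajectories(traj_path)
            all_bout_rows, all_event_rows = [], []
            occ_maps = []
            for assay_id, trajs in assays.items():
                masks = proximity_exclusion(trajs, arena)
                for traj, mask in zip(trajs, masks):
                    bouts = detect_bouts(
                        traj,
                        ang_thresh=b["ang_thresh"],
                        lin_thresh=b["lin_thresh"],
                        smooth_frames=b["smooth_frames"],
                        merge_gap_ms=b["merge_gap_ms"],
                        min_frames=b["min_frames"],
                    )
                    events = segment_crossings(
                        traj, arena, bouts=bouts, exclusion_mask=mask
                    )
                    for bout in bouts:
                        all_bout_rows.append(
                            {
                                "assay_id": assay_id,
                                "larva_id": traj.larva_id,
                                **dataclasses.asdict(bout),
                            }
                        )
                    for ev in events:
                        all_event_rows.append(
                            {
                                "assay_id": assay_id,
                                "larva_id": traj.larva_id,
                                "entry_frame": ev.entry_frame,
                                "exit_frame": ev.exit_frame,
                                "entry_angle": ev.entry_angle,
                                "n_bouts": ev.n_bouts,
                                "path_length_mm": ev.path_length,
                                "escape_time_s": ev.escape_time,
                                "excluded": ev.excluded,
                            }
                        )
                occ_maps.append(
                    occupancy_footprint(trajs, arena, b["pixel_mm"])
                )
            pd.DataFrame(all_bout_rows).to_csv(out / "bouts.csv", index=False)
            events_df = pd.DataFrame(all_event_rows)
            events_df.to_csv(out / "events.csv", index=False)
            report["behavior"] = {
                "n_bouts_total": len(all_bout_rows),
                "n_events": len(all_event_rows),
                "zone_fractions": occ_maps[0].zone_fractions if occ_maps else {},
                "delta_mirror": occ_maps[0].delta_mirror if occ_maps else None,
            }
            if len(all_event_rows) > 0:
                summary = {
                    "median_bouts": float(events_df["n_bouts"].median()),
                    "median_path_mm": float(events_df["path_length_mm"].median()),
                    "median_escape_s": float(events_df["escape_time_s"].median()),
                    "frac_escape_le2_bouts": float(
                        (events_df["n_bouts"] <= 2).mean()
                    ),
                }
                report["behavior"]["escape"] = summary
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"[behavior] {exc}") from exc

    if cfg["encoding"]["enabled"]:
        try:
            if h5_path is None:
                raise ValueError("no calcium container configured or simulated")
            e = cfg["encoding"]
            dataset = read_calcium_h5(h5_path)
            result = analyze_encoding(
                dataset,
                strong_factor=e["strong_factor"],
                moderate_factor=e["moderate_factor"],
                n_shuffles=e["shuffles"],
                seed=int(e["seed"]),
                exclude_frames=e["exclude_frames"],
                baseline_frames=e["baseline_frames"],
                method=e["mi_method"],
                grid_size=e["mi_grid"],
            )
            result.to_csv(out / "encoding.csv", index=False)
            sens = result[result["sensory"]]
            by_region = {
                region: {
                    "n": int(len(g)),
                    "ipsi_selectivity_median": float(
                        np.nanmedian(g["ipsi_selectivity"])
                    )
                    if len(g)
                    else None,
                    "f_is_median": float(np.nanmedian(g["f_is"]))
                    if g["f_is"].notna().any()
                    else None,
                }
                for region, g in sens.groupby("region")
            }
            report["encoding"] = {
                "n_rois": int(len(result)),
                "n_sensory": int(result["sensory"].sum()),
                "n_motor": int(result["motor"].sum()),
                "n_sensorimotor": int(result["sensorimotor"].sum()),
                "sensory_by_region": by_region,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"[encoding] {exc}") from exc

    if cfg["fluidics"]["enabled"]:
        try:
            f = cfg["fluidics"]
            spec = ChannelSpec.from_lab_units(
                f["a_mm"],
                f["b_mm"],
                f["q_inlet_ul_min"],
                f["n_inlets"],
                f["rho"],
                f["mu"],
                f["diffusivity"],
            )
            nums = characterize_channel(spec)
            row = dataclasses.asdict(nums)
            pd.DataFrame([row]).to_csv(out / "fluidics.csv", index=False)
            report["fluidics"] = row
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"[fluidics] {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str)
    )
    return report
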