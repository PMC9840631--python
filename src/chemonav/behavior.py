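"""Swim-bout kinematics and chemical-zone escape analysis.

Larval zebrafish swim in discrete bouts: brief episodes of turning and/or
translation separated by glides.  Given head-center trajectories
``(x, y, theta)`` sampled at a uniform frame rate (240 fps in the assay),
this module

* detects bouts by thresholding instantaneous angular velocity
  (>= 1.2 deg/ms) or linear velocity (>= 12 um/ms),
* segments border-crossing events into the rightmost chemical zone, with a
  1-mm hysteresis margin around the border so that dithering within the
  diffusion margin does not create spurious events,
* computes per-event escape statistics (bout count, path length, escape
  time), turn-angle statistics per bout index, arena occupancy footprints,
  and wall/conspecific proximity exclusion masks,
* provides tail-angle helpers for the tail-flip assay (200 fps).

Positions are arena-frame millimetres with the origin at the bottom-left
corner; positive heading change is a leftward (counter-clockwise) turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ArenaGeometry",
    "SwimBout",
    "CrossingEvent",
    "OccupancyMap",
    "detect_bouts",
    "segment_crossings",
    "escape_metrics",
    "turn_statistics",
    "bout_frequency",
    "occupancy_footprint",
    "proximity_exclusion",
    "compute_tail_angle",
    "tail_events",
]


@dataclass
class Trajectory:
    """Head-center kinematic time series of one larva.

    ``t`` is in seconds and must be uniform; ``x, y`` in mm; ``theta`` the
    heading in degrees (any winding; unwrapped internally).
    """

    larva_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == self.theta.size == n):
            raise ValueError("t, x, y, theta must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must be uniformly sampled")
        for arr in (self.x, self.y, self.theta):
            if not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")

    @property
    def fps(self) -> float:
        if self.t.size < 2:
            raise ValueError("need >= 2 frames to infer frame rate")
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def n_frames(self) -> int:
        return self.t.size

    def theta_unwrapped(self) -> np.ndarray:
        return np.unwrap(self.theta, period=360.0)


@dataclass
class ArenaGeometry:
    """Rectangular swimming arena with a rightmost stimulus zone.

    ``border_x`` is the x-position of the chemical border (the stimulus
    zone is ``x >= border_x``); ``mirror_border_x`` bounds the symmetric
    mirror control zone (``x <= mirror_border_x``).  ``margin`` is the
    diffusion margin applied as hysteresis in crossing detection, and
    ``exclusion_distance`` the wall/conspecific proximity cutoff.
    """

    width: float = 60.0
    height: float = 30.0
    border_x: float = 40.0
    mirror_border_x: float = 20.0
    margin: float = 1.0
    exclusion_distance: float = 4.0

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if not (0 < self.border_x < self.width):
            raise ValueError("border must lie inside the arena")
        if not (0 < self.mirror_border_x < self.width):
            raise ValueError("mirror border must lie inside the arena")

    def in_stimulus_zone(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) >= self.border_x

    def in_mirror_zone(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) <= self.mirror_border_x


@dataclass
class SwimBout:
    """One detected movement episode.

    ``final_dtheta`` is the signed net heading change over the bout
    (degrees, positive = leftward); ``mean_angular_velocity`` is
    ``|final_dtheta| / duration`` in deg/ms; ``peak_linear_velocity`` in
    um/ms.
    """

    start_frame: int
    end_frame: int
    duration: float
    final_dtheta: float
    mean_angular_velocity: float
    displacement: float
    peak_linear_velocity: float


@dataclass
class CrossingEvent:
    """One entry-to-escape episode in the stimulus zone."""

    entry_frame: int
    exit_frame: int
    entry_angle: float
    bouts: list[SwimBout]
    path_length: float
    escape_time: float
    excluded: bool = False

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)


@dataclass
class OccupancyMap:
    """Normalized dwell-time footprint over the arena grid."""

    grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    zone_fractions: dict[str, float]

    @property
    def delta_mirror(self) -> float:
        """Stimulus-zone time fraction minus mirror-zone time fraction."""
        return self.zone_fractions["stimulus"] - self.zone_fractions["mirror"]


# ---------------------------------------------------------------------------
# velocity estimation and bout detection


def _boxcar(a: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return a
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(a, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + a.size]
    return out


def frame_velocities(
    traj: Trajectory, smooth_frames: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame angular (deg/ms) and linear (um/ms) speed.

    Central differences on boxcar-smoothed x, y and unwrapped heading;
    one-sided differences at the ends.
    """
    dt_ms = 1000.0 / traj.fps
    x = _boxcar(traj.x, smooth_frames)
    y = _boxcar(traj.y, smooth_frames)
    th = _boxcar(traj.theta_unwrapped(), smooth_frames)
    ang = np.abs(np.gradient(th)) / dt_ms
    vx = np.gradient(x) / dt_ms
    vy = np.gradient(y) / dt_ms
    lin = np.hypot(vx, vy) * 1000.0  # mm/ms -> um/ms
    return ang, lin


def _active_runs(active: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) frame pairs."""
    if not active.any():
        return []
    padded = np.concatenate([[False], active, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_bouts(
    traj: Trajectory,
    ang_thresh: float = 1.2,
    lin_thresh: float = 12.0,
    smooth_frames: int = 3,
    merge_gap_ms: float = 50.0,
    min_frames: int = 2,
) -> list[SwimBout]:
    """Detect swim bouts by angular-OR-linear velocity thresholding.

    A frame is bout-active when angular speed >= ``ang_thresh`` (deg/ms)
    or linear speed >= ``lin_thresh`` (um/ms).  Contiguous active runs
    separated by gaps shorter than ``merge_gap_ms`` are merged, and runs
    shorter than ``min_frames`` frames discarded.  Bout kinematics are
    computed from the start/end states of the (unsmoothed) trajectory.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames")
    dt_ms = 1000.0 / traj.fps
    ang, lin = frame_velocities(traj, smooth_frames)
    active = (ang >= ang_thresh) | (lin >= lin_thresh)
    runs = _active_runs(active)

    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1] - 1) * dt_ms < merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if (e - s + 1) >= min_frames]

    th = traj.theta_unwrapped()
    bouts = []
    for s, e in kept:
        dur_ms = (e - s) * dt_ms
        dth = float(th[e] - th[s])
        bouts.append(
            SwimBout(
                start_frame=s,
                end_frame=e,
                duration=dur_ms / 1000.0,
                final_dtheta=dth,
                mean_angular_velocity=abs(dth) / dur_ms if dur_ms > 0 else 0.0,
                displacement=float(
                    np.hypot(traj.x[e] - traj.x[s], traj.y[e] - traj.y[s])
                ),
                peak_linear_velocity=float(lin[s : e + 1].max()),
            )
        )
    return bouts


# ---------------------------------------------------------------------------
# border crossings


def segment_crossings(
    traj: Trajectory,
    arena: ArenaGeometry,
    bouts: list[SwimBout] | None = None,
    exclusion_mask: np.ndarray | None = None,
    **bout_kwargs,
) -> list[CrossingEvent]:
    """Segment entry-to-escape events into the stimulus zone.

    Entry is registered when the head crosses ``border_x + margin``
    (i.e. past the diffusion margin into the zone); escape requires
    crossing back past ``border_x - margin``.  The hysteresis prevents
    dithering within the +/- margin band from creating events.  Events
    whose span overlaps ``exclusion_mask`` (per-frame proximity flags)
    are kept but marked ``excluded``.
    """
    if np.any(traj.x < -1e-9) or np.any(traj.x > arena.width + 1e-9):
        import warnings

        warnings.warn("trajectory leaves arena bounds; clipping", stacklevel=2)
        traj = Trajectory(
            traj.larva_id,
            traj.t,
            np.clip(traj.x, 0, arena.width),
            np.clip(traj.y, 0, arena.height),
            traj.theta,
        )
    if bouts is None:
        bouts = detect_bouts(traj, **bout_kwargs)

    enter_level = arena.border_x + arena.margin
    exit_level = arena.border_x - arena.margin
    x = traj.x
    events: list[CrossingEvent] = []
    inside = x[0] >= enter_level
    entry = 0 if inside else -1
    step = np.hypot(np.diff(traj.x), np.diff(traj.y))
    for i in range(1, x.size):
        if not inside and x[i] >= enter_level:
            inside = True
            entry = i
        elif inside and x[i] <= exit_level:
            inside = False
            events.append(_make_event(traj, entry, i, bouts, step, exclusion_mask))
            entry = -1
    return events


def _make_event(
    traj: Trajectory,
    entry: int,
    exit_: int,
    bouts: list[SwimBout],
    step: np.ndarray,
    exclusion_mask: np.ndarray | None,
) -> CrossingEvent:
    ev_bouts = [b for b in bouts if entry <= b.start_frame <= exit_]
    # incidence angle: heading at entry relative to the inward border
    # normal (+x), folded to (-180, 180]
    entry_angle = float((traj.theta[entry] + 180.0) % 360.0 - 180.0)
    excluded = False
    if exclusion_mask is not None:
        excluded = bool(np.asarray(exclusion_mask)[entry : exit_ + 1].any())
    return CrossingEvent(
        entry_frame=entry,
        exit_frame=exit_,
        entry_angle=entry_angle,
        bouts=ev_bouts,
        path_length=float(step[entry:exit_].sum()),
        escape_time=float(traj.t[exit_] - traj.t[entry]),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# event-level statistics


def escape_metrics(events: list[CrossingEvent]) -> dict:
    """Per-event escape statistics and group-level summaries.

    Returns a dict with a per-event table and medians/quartiles of bout
    count, path length and escape time, plus the fraction of events
    escaped within one or two bouts.  Proximity-excluded events are
    retained here (exclusion applies to turn statistics only); an empty
    input yields an empty summary.
    """
    if not events:
        return {"events": pd.DataFrame(), "summary": {}}
    table = pd.DataFrame(
        {
            "n_bouts": [e.n_bouts for e in events],
            "path_length_mm": [e.path_length for e in events],
            "escape_time_s": [e.escape_time for e in events],
            "excluded": [e.excluded for e in events],
        }
    )
    summary = {}
    for col in ("n_bouts", "path_length_mm", "escape_time_s"):
        v = table[col].to_numpy(dtype=float)
        summary[col] = {
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
        }
    summary["frac_escape_le2_bouts"] = float((table["n_bouts"] <= 2).mean())
    return {"events": table, "summary": summary}


def turn_statistics(events: list[CrossingEvent]) -> dict:
    """Turn-angle statistics of first and subsequent bouts after entry.

    Uses non-excluded events carrying at least one bout.  Returns the
    first-bout signed turn angles and mean angular velocities, the mean
    +/- s.e.m. of ``|final dtheta|`` per bout index since entry, and
    signed-direction tallies split by entry-angle side for stereo-turn
    testing.
    """
    usable = [e for e in events if not e.excluded and e.n_bouts > 0]
    first_angles = np.array([e.bouts[0].final_dtheta for e in usable])
    first_angvel = np.array([e.bouts[0].mean_angular_velocity for e in usable])

    by_index: dict[int, list[float]] = {}
    for e in usable:
        for k, b in enumerate(e.bouts):
            by_index.setdefault(k, []).append(abs(b.final_dtheta))
    indices = sorted(by_index)
    mean_abs = np.array([np.mean(by_index[k]) for k in indices])
    sem_abs = np.array(
        [
            np.std(by_index[k], ddof=1) / np.sqrt(len(by_index[k]))
            if len(by_index[k]) > 1
            else np.nan
            for k in indices
        ]
    )
    # stereo-turn tally: do first turns go left vs right, split by the
    # side the larva approached from (sign of entry incidence angle)?
    direction = {"left_turns": int((first_angles > 0).sum()),
                 "right_turns": int((first_angles < 0).sum())}
    by_entry_side = {}
    for side, mask in (
        ("entry_left", np.array([e.entry_angle > 0 for e in usable])),
        ("entry_right", np.array([e.entry_angle < 0 for e in usable])),
    ):
        if mask.size:
            sel = first_angles[mask]
            by_entry_side[side] = {
                "left_turns": int((sel > 0).sum()),
                "right_turns": int((sel < 0).sum()),
            }
    return {
        "first_final_dtheta": first_angles,
        "first_mean_angular_velocity": first_angvel,
        "bout_index": np.array(indices),
        "abs_dtheta_mean": mean_abs,
        "abs_dtheta_sem": sem_abs,
        "direction_tally": direction,
        "direction_by_entry_side": by_entry_side,
    }


def bout_frequency(
    bouts: list[SwimBout], interval: tuple[int, int], fps: float
) -> float:
    """Bout rate (Hz) within an inclusive frame interval."""
    start, end = interval
    if end <= start:
        raise ValueError("interval must have positive duration")
    n = sum(1 for b in bouts if start <= b.start_frame <= end)
    return n * fps / (end - start)


# ---------------------------------------------------------------------------
# occupancy and exclusion


def occupancy_footprint(
    trajs: list[Trajectory],
    arena: ArenaGeometry,
    pixel_mm: float = 1.0,
) -> OccupancyMap:
    """Head-center dwell-time footprint, normalized per larva and time.

    Each frame contributes one frame-interval of dwell to the pixel under
    the head center; the grid is divided by (number of larvae x assay
    duration) so maps from different assays are comparable.  Zone
    fractions are the proportions of total dwell time spent in the
    stimulus zone, the mirror zone, and the remainder.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    x_edges = np.arange(0.0, arena.width + pixel_mm, pixel_mm)
    y_edges = np.arange(0.0, arena.height + pixel_mm, pixel_mm)
    grid = np.zeros((x_edges.size - 1, y_edges.size - 1))
    t_stim = t_mirror = t_total = 0.0
    duration = 0.0
    for traj in trajs:
        dt = 1.0 / traj.fps
        h, _, _ = np.histogram2d(traj.x, traj.y, bins=(x_edges, y_edges))
        grid += h * dt
        t_stim += float(arena.in_stimulus_zone(traj.x).sum()) * dt
        t_mirror += float(arena.in_mirror_zone(traj.x).sum()) * dt
        t_total += traj.n_frames * dt
        duration = max(duration, traj.n_frames * dt)
    grid /= len(trajs) * duration
    fractions = {
        "stimulus": t_stim / t_total,
        "mirror": t_mirror / t_total,
        "remainder": (t_total - t_stim - t_mirror) / t_total,
    }
    return OccupancyMap(grid=grid, x_edges=x_edges, y_edges=y_edges,
                        zone_fractions=fractions)


def zone_fraction_sem(maps: list[OccupancyMap]) -> dict[str, float]:
    """Across-assay s.e.m. of the stimulus-zone fraction and delta-mirror."""
    stim = np.array([m.zone_fractions["stimulus"] for m in maps])
    delta = np.array([m.delta_mirror for m in maps])
    n = len(maps)
    sem = lambda a: float(np.std(a, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {
        "stimulus_mean": float(stim.mean()),
        "stimulus_sem": sem(stim),
        "delta_mirror_mean": float(delta.mean()),
        "delta_mirror_sem": sem(delta),
    }


def proximity_exclusion(
    trajs: list[Trajectory], arena: ArenaGeometry
) -> list[np.ndarray]:
    """Per-frame masks flagging wall or conspecific proximity.

    True where the head is within ``exclusion_distance`` of the nearest
    arena wall or of another larva (the latter skipped for a single
    larva).  Trajectories must share a time base; differing lengths are
    compared over the common prefix.
    """
    d = arena.exclusion_distance
    masks = []
    for traj in trajs:
        wall = np.minimum.reduce(
            [traj.x, arena.width - traj.x, traj.y, arena.height - traj.y]
        )
        masks.append(wall <= d)
    if len(trajs) > 1:
        n_common = min(t.n_frames for t in trajs)
        xs = np.stack([t.x[:n_common] for t in trajs])
        ys = np.stack([t.y[:n_common] for t in trajs])
        for i in range(len(trajs)):
            for j in range(i + 1, len(trajs)):
                close = (
                    np.hypot(xs[i] - xs[j], ys[i] - ys[j]) <= d
                )
                masks[i][:n_common] |= close
                masks[j][:n_common] |= close
    return masks


# ---------------------------------------------------------------------------
# tail-flip analysis (200 fps assay)


def compute_tail_angle(
    body_axis: np.ndarray, waist: np.ndarray, tail_tip: np.ndarray
) -> float:
    """Angle between the body long axis and the waist-to-tail-tip line.

    The tail line is undirected, so the angle is folded to [0, 90]
    degrees: 0 when the tail tip lies on the body axis, 90 when the tail
    line is perpendicular to it.
    """
    axis = np.asarray(body_axis, dtype=float)
    v = np.asarray(tail_tip, dtype=float) - np.asarray(waist, dtype=float)
    nv = np.linalg.norm(v)
    na = np.linalg.norm(axis)
    if nv == 0:
        raise ValueError("waist and tail tip coincide")
    if na == 0:
        raise ValueError("body axis must be non-zero")
    cos = abs(float(np.dot(axis, v)) / (na * nv))
    return float(np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))


def tail_events(
    angle_trace: np.ndarray,
    fps: float = 200.0,
    angle_thresh: float = 10.0,
    min_frames: int = 2,
) -> dict:
    """Threshold-crossing tail-flick episodes and their rate.

    An event is a contiguous run of frames (>= ``min_frames``) with tail
    angle >= ``angle_thresh`` degrees.  Returns event onset times, an
    active-frame boolean vector, and the event frequency in Hz.
    """
    a = np.asarray(angle_trace, dtype=float)
    active = a >= angle_thresh
    runs = [(s, e) for s, e in _active_runs(active) if e - s + 1 >= min_frames]
    onsets = np.array([s / fps for s, _ in runs])
    mask = np.zeros(a.size, dtype=bool)
    for s, e in runs:
        mask[s : e + 1] = True
    duration = a.size / fps
    return {
        "event_times": onsets,
        "active": mask,
        "frequency_hz": len(runs) / duration if duration > 0 else 0.0,
    }
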