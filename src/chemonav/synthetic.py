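"""Synthetic trajectories, calcium recordings and tail-event trains.

Every analysis stage of the package can be exercised against data with
known ground truth.  The generators emulate the study conditions of the
assays they stand in for:

* ``gen_trajectory`` — bout-and-glide 2D swimming in the rectangular
  arena: exponential inter-bout intervals whose rate increases inside
  the chemical zone (klinokinesis, ``zone_rate_multiplier``), and
  zero-mean normal heading changes whose spread increases in the zone
  (angular orthokinesis, ``turn_angle_sd_zone`` / ``first_bout_gain``).
  Turns are undirected by default, matching the absence of directional
  bias in real escape data; a ``turn_bias_deg`` knob exists but is off.
* ``gen_calcium`` — GCaMP6f-like transients at 2 Hz driven by lateralized
  square-pulse stimulus profiles with finite rise/decay, with
  configurable ipsi/contra drive weights, binasal summation rule
  (linear / supralinear / saturating) and additive Gaussian noise, plus
  motor-coupled ROIs driven by a Poisson tail-event train.
* ``gen_tail`` — Poisson tail-flick event train at 200 fps.

All outputs are bit-reproducible given (config, seed), and each
generator returns a ground-truth log sufficient to compute the
downstream metrics independently of the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import ArenaGeometry, Trajectory
from .encoding import RoiTraceSet

__all__ = [
    "BehaviorGenConfig",
    "NeuralGenConfig",
    "gen_trajectory",
    "gen_tail",
    "gen_calcium",
]


# ---------------------------------------------------------------------------
# behavior


@dataclass
class BehaviorGenConfig:
    """Ground-truth parameters of the swimming simulator.

    ``baseline_bout_rate`` (Hz) is the spontaneous bout rate outside the
    chemical zone; inside, it is multiplied by ``zone_rate_multiplier``.
    Heading changes per bout are N(0, sd) with ``turn_angle_sd_baseline``
    / ``turn_angle_sd_zone`` degrees; the first bout after entering the
    zone is scaled by ``first_bout_gain``.  Bouts translate at
    ``linear_speed`` um/ms for ``bout_duration`` seconds, turning within
    the initial ``turn_duration`` seconds; walls are reflective.
    """

    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    baseline_bout_rate: float = 1.0
    zone_rate_multiplier: float = 1.0
    turn_angle_sd_baseline: float = 30.0
    turn_angle_sd_zone: float = 30.0
    first_bout_gain: float = 1.0
    turn_bias_deg: float = 0.0
    bout_duration: float = 0.2
    turn_duration: float = 0.05
    linear_speed: float = 15.0
    n_larvae: int = 3
    duration_s: float = 120.0
    fps: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_bout_rate < 0 or self.zone_rate_multiplier < 0:
            raise ValueError("rates must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


def _reflect(p: float, lo: float, hi: float) -> tuple[float, bool]:
    """Reflect a coordinate into [lo, hi]; True when a wall was hit."""
    hit = False
    span = hi - lo
    while p < lo or p > hi:
        hit = True
        if p < lo:
            p = 2 * lo - p
        else:
            p = 2 * hi - p
        if not np.isfinite(p) or span <= 0:
            return lo, True
    return p, hit


def gen_trajectory(cfg: BehaviorGenConfig) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate bout-and-glide trajectories with a ground-truth bout log.

    Returns the per-larva trajectories and a DataFrame with one row per
    true bout: larva, start/end frame, signed heading change, whether the
    bout started inside the stimulus zone, and whether it was the first
    bout after a zone entry.
    """
    rng = np.random.default_rng(cfg.seed)
    arena = cfg.arena
    n_frames = int(round(cfg.duration_s * cfg.fps))
    turn_frames = max(int(round(cfg.turn_duration * cfg.fps)), 1)
    bout_frames = max(int(round(cfg.bout_duration * cfg.fps)), turn_frames + 1)
    speed_mm_s = cfg.linear_speed  # um/ms == mm/s

    trajectories = []
    log_rows = []
    for larva in range(cfg.n_larvae):
        x = np.empty(n_frames)
        y = np.empty(n_frames)
        th = np.empty(n_frames)
        # start in the water region, away from walls
        px = rng.uniform(5.0, arena.border_x - 5.0)
        py = rng.uniform(5.0, arena.height - 5.0)
        heading = rng.uniform(0.0, 360.0)
        frame = 0
        was_in_zone = px >= arena.border_x
        first_pending = False
        while frame < n_frames:
            in_zone = px >= arena.border_x
            if in_zone and not was_in_zone:
                first_pending = True
            was_in_zone = in_zone
            rate = cfg.baseline_bout_rate * (
                cfg.zone_rate_multiplier if in_zone else 1.0
            )
            if rate <= 0 or speed_mm_s <= 0 and cfg.turn_angle_sd_baseline == 0:
                x[frame:] = px
                y[frame:] = py
                th[frame:] = heading
                frame = n_frames
                break
            wait = rng.exponential(1.0 / rate)
            wait_frames = max(int(round(wait * cfg.fps)), 1)
            end_wait = min(frame + wait_frames, n_frames)
            x[frame:end_wait] = px
            y[frame:end_wait] = py
            th[frame:end_wait] = heading
            frame = end_wait
            if frame >= n_frames:
                break
            # --- execute one bout ---
            sd = cfg.turn_angle_sd_zone if in_zone else cfg.turn_angle_sd_baseline
            dtheta = rng.normal(cfg.turn_bias_deg if in_zone else 0.0, sd)
            if in_zone and first_pending:
                dtheta *= cfg.first_bout_gain
            first = in_zone and first_pending
            first_pending = False
            start = frame
            end = min(frame + bout_frames, n_frames)
            new_heading = heading + dtheta
            dist_per_frame = speed_mm_s / cfg.fps
            for k in range(start, end):
                j = k - start
                if j < turn_frames:
                    heading_k = heading + dtheta * (j + 1) / turn_frames
                else:
                    heading_k = new_heading
                rad = np.radians(heading_k)
                px += dist_per_frame * np.cos(rad)
                py += dist_per_frame * np.sin(rad)
                px, hx_ = _reflect(px, 0.0, arena.width)
                py, hy_ = _reflect(py, 0.0, arena.height)
                if hx_:
                    new_heading = 180.0 - new_heading
                    heading_k = 180.0 - heading_k
                if hy_:
                    new_heading = -new_heading
                    heading_k = -heading_k
                x[k] = px
                y[k] = py
                th[k] = heading_k
            heading = new_heading
            log_rows.append(
                {
                    "larva": larva,
                    "start_frame": start,
                    "end_frame": end - 1,
                    "dtheta": float(dtheta),
                    "in_zone": bool(in_zone),
                    "first_in_zone": bool(first),
                }
            )
            frame = end
        t = np.arange(n_frames) / cfg.fps
        trajectories.append(Trajectory(f"larva{larva}", t, x, y, th))
    return trajectories, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# tail events


def gen_tail(
    rate: float,
    duration_s: float,
    fps: float = 200.0,
    event_duration_s: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson tail-flick train: boolean activity vector plus event times.

    Events arrive at ``rate`` Hz; each marks ``event_duration_s`` of
    contiguous active frames.  Deterministic under the seed.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(round(duration_s * fps))
    active = np.zeros(n, dtype=bool)
    times = []
    if rate > 0:
        t = rng.exponential(1.0 / rate)
        while t < duration_s:
            times.append(t)
            s = int(t * fps)
            active[s : s + int(event_duration_s * fps)] = True
            t += rng.exponential(1.0 / rate)
    return active, np.array(times)


# ---------------------------------------------------------------------------
# calcium


@dataclass
class NeuralGenConfig:
    """Ground-truth parameters of the calcium-recording simulator.

    Trials follow the imaging protocol: 2-Hz frames, a 30-s baseline,
    a 10-s stimulus window and a 10-s post epoch (100 frames).  Stimulus
    profiles are square pulses with exponential 10-90% rise/decay.  Each
    sensory ROI's drive is ``f(w_ipsi*C_ipsi + w_contra*C_contra)`` with
    the configured summation rule, convolved with a double-exponential
    GCaMP6f-like kernel; Gaussian noise is added to the raw fluorescence.
    """

    n_rois: int = 10
    regions: tuple[str, ...] = ("OB",)
    w_ipsi: float = 1.0
    w_contra: float = 0.0
    summation: str = "linear"  # linear | supralinear | saturating
    supralinear_gamma: float = 2.0
    saturation_beta: float = 3.0
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.6
    noise_sd: float = 0.15
    amplitude: float = 0.4
    motor_weight: float = 0.0
    n_trials: int = 4
    n_frames: int = 100
    fps: float = 2.0
    stim_onset_s: float = 30.0
    stim_duration_s: float = 10.0
    stim_rise_s: float = 0.9
    stim_decay_s: float = 1.6
    tail_rate_hz: float = 0.33
    fps_tail: float = 200.0
    f0: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_ipsi < 0 or self.w_contra < 0:
            raise ValueError("drive weights must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= 0:
            raise ValueError("kernel constants must be positive")
        if self.summation not in ("linear", "supralinear", "saturating"):
            raise ValueError(f"unknown summation rule {self.summation!r}")


def stimulus_pulse(cfg: NeuralGenConfig) -> np.ndarray:
    """Ideal [0, 1] stimulus profile: smoothed square pulse, one trial."""
    t = np.arange(cfg.n_frames) / cfg.fps
    on, off = cfg.stim_onset_s, cfg.stim_onset_s + cfg.stim_duration_s
    # exponential time constants chosen so the 10-90% interval matches
    # the configured rise/decay times: t_1090 = tau * ln 9
    tau_r = cfg.stim_rise_s / np.log(9.0)
    tau_d = cfg.stim_decay_s / np.log(9.0)
    c = np.zeros_like(t)
    rising = (t >= on) & (t < off)
    c[rising] = 1.0 - np.exp(-(t[rising] - on) / tau_r)
    level_off = 1.0 - np.exp(-(off - on) / tau_r)
    after = t >= off
    c[after] = level_off * np.exp(-(t[after] - off) / tau_d)
    return c


def _gcamp_kernel(cfg: NeuralGenConfig) -> np.ndarray:
    t = np.arange(0, 6.0 * cfg.kernel_decay_s, 1.0 / cfg.fps)
    k = np.exp(-t / cfg.kernel_decay_s) - np.exp(-t / cfg.kernel_rise_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def _summation(u: np.ndarray, cfg: NeuralGenConfig) -> np.ndarray:
    if cfg.summation == "linear":
        return u
    if cfg.summation == "supralinear":
        return np.power(u, cfg.supralinear_gamma)
    return np.tanh(cfg.saturation_beta * u) / np.tanh(cfg.saturation_beta)


def gen_calcium(cfg: NeuralGenConfig) -> tuple[RoiTraceSet, pd.DataFrame]:
    """Simulate one larva's trial-structured calcium dataset.

    Returns the RoiTraceSet (raw fluorescence, raw stimulus-ROI traces,
    tail activity, atlas labels) and the ground-truth ROI table (weights,
    summation rule, motor coupling).  ROIs alternate L/R hemispheres and
    cycle through ``cfg.regions``.
    """
    rng = np.random.default_rng(cfg.seed)
    kernel = _gcamp_kernel(cfg)
    pulse = stimulus_pulse(cfg)
    conditions = ("l-STIM", "r-STIM", "b-STIM", "null")

    sides = np.array(["L", "R"])[np.arange(cfg.n_rois) % 2]
    regions = np.array(cfg.regions)[np.arange(cfg.n_rois) % len(cfg.regions)]
    roi_info = pd.DataFrame(
        {
            "roi_id": [f"roi{i:04d}" for i in range(cfg.n_rois)],
            "region": regions,
            "side": sides,
            "x": rng.uniform(0, 500, cfg.n_rois),
            "y": rng.uniform(0, 1000, cfg.n_rois),
            "z": rng.uniform(0, 300, cfg.n_rois),
        }
    )

    stim: dict[str, dict[str, np.ndarray]] = {}
    traces: dict[str, np.ndarray] = {}
    tail: dict[str, np.ndarray] = {}
    n_tail_frames = int(round(cfg.n_frames / cfg.fps * cfg.fps_tail))
    for cond in conditions:
        c_l = pulse if cond in ("l-STIM", "b-STIM") else np.zeros_like(pulse)
        c_r = pulse if cond in ("r-STIM", "b-STIM") else np.zeros_like(pulse)
        # raw stimulus-ROI intensities: offset + scaled profile + noise
        stim[cond] = {
            "l": 100.0
            + 200.0 * np.tile(c_l, (cfg.n_trials, 1))
            + rng.normal(0, 1.0, (cfg.n_trials, cfg.n_frames)),
            "r": 100.0
            + 200.0 * np.tile(c_r, (cfg.n_trials, 1))
            + rng.normal(0, 1.0, (cfg.n_trials, cfg.n_frames)),
        }
        tail_cond = np.zeros((cfg.n_trials, n_tail_frames), dtype=bool)
        for trial in range(cfg.n_trials):
            tail_cond[trial], _ = gen_tail(
                cfg.tail_rate_hz,
                cfg.n_frames / cfg.fps,
                cfg.fps_tail,
                seed=rng,
            )
        tail[cond] = tail_cond

        cond_traces = np.empty((cfg.n_rois, cfg.n_trials, cfg.n_frames))
        motor_binned = tail_cond.reshape(
            cfg.n_trials, cfg.n_frames, int(cfg.fps_tail / cfg.fps)
        ).mean(axis=2)
        for r in range(cfg.n_rois):
            ipsi_c, contra_c = (c_l, c_r) if sides[r] == "L" else (c_r, c_l)
            u = cfg.w_ipsi * ipsi_c + cfg.w_contra * contra_c
            drive = _summation(np.clip(u, 0.0, None), cfg)
            for trial in range(cfg.n_trials):
                total = drive + cfg.motor_weight * motor_binned[trial]
                dff = cfg.amplitude * np.convolve(total, kernel)[: cfg.n_frames]
                raw = cfg.f0 * (
                    1.0 + dff + rng.normal(0, cfg.noise_sd, cfg.n_frames)
                )
                cond_traces[r, trial] = np.maximum(raw, 1e-3)
        traces[cond] = cond_traces

    truth = roi_info.assign(
        w_ipsi=cfg.w_ipsi,
        w_contra=cfg.w_contra,
        summation=cfg.summation,
        motor_weight=cfg.motor_weight,
        is_responsive=(cfg.w_ipsi + cfg.w_contra) > 0,
    )
    dataset = RoiTraceSet(
        traces=traces,
        roi_info=roi_info,
        stim=stim,
        tail=tail,
        fps_img=cfg.fps,
        fps_tail=cfg.fps_tail,
    )
    return dataset, truth


def mixed_population(
    configs: list[NeuralGenConfig],
) -> tuple[RoiTraceSet, pd.DataFrame]:
    """Concatenate ROI populations generated under different configs.

    All configs must share the trial design (conditions, trial count,
    frame count).  Stimulus and tail data are taken from the first
    config's dataset; ROI ids are re-labelled to stay unique.
    """
    sets = [gen_calcium(c) for c in configs]
    base, _ = sets[0]
    traces = {
        cond: np.concatenate([s.traces[cond] for s, _ in sets], axis=0)
        for cond in base.traces
    }
    infos = []
    truths = []
    offset = 0
    for s, truth in sets:
        info = s.roi_info.copy()
        ids = [f"roi{offset + i:04d}" for i in range(len(info))]
        info["roi_id"] = ids
        truth = truth.copy()
        truth["roi_id"] = ids
        infos.append(info)
        truths.append(truth)
        offset += len(info)
    dataset = RoiTraceSet(
        traces=traces,
        roi_info=pd.concat(infos, ignore_index=True),
        stim=base.stim,
        tail=base.tail,
        fps_img=base.fps_img,
        fps_tail=base.fps_tail,
    )
    return dataset, pd.concat(truths, ignore_index=True)
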