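"""Brainwide neural-encoding statistics from trial-structured calcium data.

Implements the dF/F computation, stimulus-profile normalization,
shuffled-null significance rules and the derived encoding statistics:

* ``I_S`` — mutual information between a ROI's dF/F and the left
  (``C_L,t``), right (``C_R,t``) or bilateral (``C_L+R,t``) stimulus
  profile, one value per stimulus condition (l-STIM, r-STIM, b-STIM);
* ``I_M`` — MI between dF/F and the binned motor output (proportion of
  200-fps frames with active tail flipping per 0.5-s bin);
* sensory / motor / sensorimotor / sensory-only / motor-only labels via
  the 2.5x (strong) and 1.25x (moderate) shuffled-null-maximum rules;
* ipsilateral and right input selectivity, normalized information
  ``I_N`` (relative to the olfactory-bulb mean), and the fraction of
  nonlinear information ``F_Is = (I_S_b - I_S_u_sum) / I_S_b`` probing
  binasal summation.

Imaging runs at 2 Hz; the first 21 frames (10.5 s) of each trial are
excluded (illumination-onset transient) and the baseline ``F`` is the
minimum over the following 9 frames (4.5 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mi import mi_kde

__all__ = [
    "CONDITIONS",
    "STIM_CONDITIONS",
    "RoiTraceSet",
    "StimulusProfile",
    "MotorOutput",
    "compute_dff",
    "normalize_stimulus",
    "motor_output",
    "spillover_qc",
    "stimulus_timing",
    "shuffle_null",
    "classify_roi",
    "ipsi_selectivity",
    "right_selectivity",
    "bias_classification",
    "nonlinear_fraction",
    "normalized_information",
    "analyze_encoding",
    "InvalidBaselineError",
    "DegenerateStimulusError",
]

CONDITIONS = ("l-STIM", "r-STIM", "b-STIM", "null")
STIM_CONDITIONS = ("l-STIM", "r-STIM", "b-STIM")
#: stimulus profile each condition's I_S is computed against
_PROFILE_FOR_CONDITION = {"l-STIM": "c_l", "r-STIM": "c_r", "b-STIM": "c_bl"}

EXCLUDE_FRAMES = 21
BASELINE_FRAMES = 9


class InvalidBaselineError(ValueError):
    """Raised when the baseline fluorescence F is non-positive."""


class DegenerateStimulusError(ValueError):
    """Raised when a required stimulus trace is constant."""


@dataclass
class StimulusProfile:
    """Per-condition stimulus profiles, each normalized to [0, 1].

    ``c_l``/``c_r`` are the left/right olfactory-placode stimulus-ROI
    profiles; ``c_bl`` is the min-max-renormalized mean of the two and is
    the profile used for bilateral-stimulation trials.  Arrays are
    (n_trials, n_frames), already aligned to the retained dF/F frames.
    """

    condition: str
    c_l: np.ndarray
    c_r: np.ndarray
    c_bl: np.ndarray


@dataclass
class RoiTraceSet:
    """ROI x trial x frame fluorescence with atlas labels and stimuli.

    ``traces[cond]`` holds raw fluorescence of shape
    (n_rois, n_trials_cond, n_frames); ``roi_info`` carries one row per
    ROI with columns roi_id, region, side (L/R) and atlas coordinates.
    ``stim[cond]`` are the raw per-trial stimulus-ROI intensity traces
    (dict with 'l' and 'r' arrays of shape (n_trials_cond, n_frames)),
    and ``tail[cond]`` per-trial 200-fps boolean tail-activity vectors.
    """

    traces: dict[str, np.ndarray]
    roi_info: pd.DataFrame
    stim: dict[str, dict[str, np.ndarray]]
    tail: dict[str, np.ndarray] = field(default_factory=dict)
    fps_img: float = 2.0
    fps_tail: float = 200.0

    @property
    def n_rois(self) -> int:
        return len(self.roi_info)


# ---------------------------------------------------------------------------
# elementary transforms


def compute_dff(
    raw_trial: np.ndarray,
    exclude_frames: int = EXCLUDE_FRAMES,
    baseline_frames: int = BASELINE_FRAMES,
) -> np.ndarray:
    """dF/F of one trial's raw fluorescence trace.

    The first ``exclude_frames`` frames are dropped (illumination-onset
    transient); the baseline ``F`` is the minimum of the next
    ``baseline_frames`` frames; the returned trace is ``(F_t - F)/F`` for
    all retained frames (length = input length - exclude_frames).

    Works on a 1D trace or on an array whose last axis is time.
    """
    raw = np.asarray(raw_trial, dtype=float)
    n = raw.shape[-1]
    if n <= exclude_frames + baseline_frames:
        raise ValueError(
            f"trial length {n} too short for {exclude_frames}+{baseline_frames} frames"
        )
    retained = raw[..., exclude_frames:]
    f0 = retained[..., :baseline_frames].min(axis=-1, keepdims=True)
    if np.any(f0 <= 0):
        raise InvalidBaselineError("baseline fluorescence must be positive")
    return (retained - f0) / f0


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    return (a - lo) / (hi - lo)


def normalize_stimulus(
    raw_l: np.ndarray,
    raw_r: np.ndarray,
    condition: str = "b-STIM",
    atol: float = 1e-12,
) -> StimulusProfile:
    """Min-max-normalize raw left/right stimulus-ROI traces to [0, 1].

    Sides required by ``condition`` (left for l-STIM, right for r-STIM,
    both for b-STIM) must be non-constant; a constant non-required side
    normalizes to zeros.  The bilateral profile is the min-max of the
    mean of the two normalized sides.
    """
    raw_l = np.atleast_2d(np.asarray(raw_l, dtype=float))
    raw_r = np.atleast_2d(np.asarray(raw_r, dtype=float))
    required = {
        "l-STIM": ("l",),
        "r-STIM": ("r",),
        "b-STIM": ("l", "r"),
        "null": (),
    }[condition]
    out = {}
    for name, raw in (("l", raw_l), ("r", raw_r)):
        if np.ptp(raw) <= atol:
            if name in required:
                raise DegenerateStimulusError(
                    f"constant {name}-side stimulus trace in {condition}"
                )
            out[name] = np.zeros_like(raw)
        else:
            out[name] = _minmax(raw)
    mean = 0.5 * (out["l"] + out["r"])
    c_bl = _minmax(mean) if np.ptp(mean) > atol else np.zeros_like(mean)
    return StimulusProfile(condition=condition, c_l=out["l"], c_r=out["r"], c_bl=c_bl)


def motor_output(
    tail_active: np.ndarray, fps: float = 200.0, bin_s: float = 0.5
) -> np.ndarray:
    """Proportion of active tail-flip frames in each time bin.

    ``tail_active`` is a boolean vector at ``fps``; bins of ``bin_s``
    seconds are averaged, partial trailing bins dropped.  Works on 1D or
    (trial, frame) arrays.
    """
    a = np.asarray(tail_active, dtype=float)
    per_bin = int(round(fps * bin_s))
    n_bins = a.shape[-1] // per_bin
    trimmed = a[..., : n_bins * per_bin]
    return trimmed.reshape(*a.shape[:-1], n_bins, per_bin).mean(axis=-1)


def spillover_qc(
    intended_dff: np.ndarray, unintended_dff: np.ndarray, min_ratio: float = 20.0
) -> tuple[float, bool]:
    """Unilateral-trial spillover check on fluorescein-channel dF/F peaks.

    Returns (peak ratio intended:unintended, pass flag); the trial passes
    when the ratio is at least ``min_ratio`` (20:1).  A non-positive
    unintended peak gives an infinite ratio (pass).
    """
    peak_in = float(np.max(intended_dff))
    peak_un = float(np.max(unintended_dff))
    if peak_un <= 0:
        return float("inf"), True
    ratio = peak_in / peak_un
    return ratio, ratio >= min_ratio


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float, last: bool) -> float:
    above = y >= level
    if last:
        idx = np.flatnonzero(above[:-1] & ~above[1:])
        if idx.size == 0:
            return float("nan")
        i = idx[-1]
    else:
        if above[0]:
            return float(t[0])
        idx = np.flatnonzero(~above[:-1] & above[1:])
        if idx.size == 0:
            return float("nan")
        i = idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def stimulus_timing(profile: np.ndarray, fps: float) -> tuple[float, float]:
    """10-90% rise and 90-10% decay times (s) of a [0, 1] profile.

    Rise is the first upward 10% to 90% crossing interval, decay the last
    downward 90% to 10% interval, with linear interpolation between
    samples.  NaN when the profile never reaches the 90% level.
    """
    y = np.asarray(profile, dtype=float)
    t = np.arange(y.size) / fps
    peak = y.max()
    if peak <= 0:
        return float("nan"), float("nan")
    lo, hi = 0.1 * peak, 0.9 * peak
    if not np.any(y >= hi):
        return float("nan"), float("nan")
    rise = _crossing_time(t, y, hi, last=False) - _crossing_time(t, y, lo, last=False)
    decay = _crossing_time(t, y, lo, last=True) - _crossing_time(t, y, hi, last=True)
    return float(rise), float(decay)


# ---------------------------------------------------------------------------
# information statistics


def _concat_condition(
    dff: np.ndarray, profile: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (trial, frame) response/profile pairs in register."""
    return dff.ravel(), profile.ravel()


def roi_sensory_mi(
    dff_by_cond: dict[str, np.ndarray],
    profiles: dict[str, StimulusProfile],
    **mi_kwargs,
) -> dict[str, float]:
    """I_S per stimulus condition for one ROI.

    ``dff_by_cond[cond]`` is (n_trials, n_frames) dF/F; the condition's
    trials are concatenated and evaluated against the matching profile
    (``C_L,t`` for l-STIM, ``C_R,t`` for r-STIM, ``C_L+R,t`` for b-STIM).
    """
    out = {}
    for cond in STIM_CONDITIONS:
        prof = getattr(profiles[cond], _PROFILE_FOR_CONDITION[cond])
        x, y = _concat_condition(dff_by_cond[cond], prof)
        out[cond] = mi_kde(x, y, **mi_kwargs)
    return out


def shuffle_null(
    dff_by_cond: dict[str, np.ndarray],
    profiles: dict[str, StimulusProfile],
    rng: np.random.Generator,
    n_shuffles: int = 1,
    **mi_kwargs,
) -> dict[str, list[float]]:
    """Shuffled-null I_S values for one ROI (one value per shuffle/cond).

    The concatenated dF/F time points are fully permuted (temporal
    structure destroyed) while the stimulus profile is left intact, and
    the MI recomputed.  Returns per-condition lists of null values.
    """
    out: dict[str, list[float]] = {c: [] for c in STIM_CONDITIONS}
    for cond in STIM_CONDITIONS:
        prof = getattr(profiles[cond], _PROFILE_FOR_CONDITION[cond])
        x, y = _concat_condition(dff_by_cond[cond], prof)
        for _ in range(n_shuffles):
            out[cond].append(mi_kde(rng.permutation(x), y, **mi_kwargs))
    return out


def classify_roi(
    i_s: dict[str, float],
    i_m: float,
    pooled_is_null_max: float,
    im_null_max: float,
    strong_factor: float = 2.5,
    moderate_factor: float = 1.25,
    i_m_baseline: float | None = None,
    im_baseline_null_max: float | None = None,
) -> set[str]:
    """Encoding labels for one ROI from the shuffled-null-maximum rules.

    * sensory: any I_S > ``strong_factor`` x pooled shuffled-I_S max;
    * motor: I_M > ``strong_factor`` x shuffled-I_M max;
    * sensorimotor: any I_S and I_M both > ``moderate_factor`` x the
      respective null maxima;
    * sensory-only: sensory and I_M <= moderate threshold;
    * motor-only: motor and all I_S <= moderate threshold;
    * baseline-motor: motor, with null-trial I_M > ``strong_factor`` x
      its own null maximum (when baseline values are supplied).
    """
    if np.isnan(pooled_is_null_max) or np.isnan(im_null_max):
        raise ValueError("shuffled-null maxima are required for classification")
    max_is = max(i_s.values())
    sensory = max_is > strong_factor * pooled_is_null_max
    motor = i_m > strong_factor * im_null_max
    mod_s = max_is > moderate_factor * pooled_is_null_max
    mod_m = i_m > moderate_factor * im_null_max
    labels: set[str] = set()
    if sensory:
        labels.add("sensory")
    if motor:
        labels.add("motor")
    if mod_s and mod_m:
        labels.add("sensorimotor")
    if sensory and not mod_m:
        labels.add("sensory-only")
    if motor and not mod_s:
        labels.add("motor-only")
    if motor and i_m_baseline is not None and im_baseline_null_max is not None:
        if i_m_baseline > strong_factor * im_baseline_null_max:
            labels.add("baseline-motor")
    return labels


def ipsi_selectivity(i_s_ipsi: float, i_s_contra: float) -> float:
    """Ipsilateral input selectivity ``I_ipsi / (I_ipsi + I_contra)``.

    0.5 is balanced, 1 fully ipsilateral.  NaN when both inputs carry no
    information (flagged for exclusion).
    """
    total = i_s_ipsi + i_s_contra
    if total <= 0:
        return float("nan")
    return i_s_ipsi / total


def right_selectivity(i_s_l: float, i_s_r: float) -> float:
    """Right input selectivity ``I_S_r / (I_S_l + I_S_r)``."""
    total = i_s_l + i_s_r
    if total <= 0:
        return float("nan")
    return i_s_r / total


def bias_classification(
    right_selectivities: np.ndarray, bound: float = 0.15
) -> str:
    """Larva-level response-bias label from non-OE sensory-ROI means.

    The larva is right-biased when the mean right selectivity exceeds
    ``0.5 + bound`` (0.65), left-biased below ``0.5 - bound`` (0.35), and
    unbiased otherwise.  Callers must exclude olfactory-epithelium ROIs.
    """
    v = np.asarray(right_selectivities, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("need at least one sensory ROI with defined selectivity")
    mean = float(v.mean())
    if mean > 0.5 + bound:
        return "right-biased"
    if mean < 0.5 - bound:
        return "left-biased"
    return "unbiased"


def nonlinear_fraction(
    dff_by_cond: dict[str, np.ndarray],
    profiles: dict[str, StimulusProfile],
    i_s_l: float,
    i_s_r: float,
    i_s_b: float,
    **mi_kwargs,
) -> float:
    """Fraction of nonlinear information ``(I_S_b - I_S_u_sum)/I_S_b``.

    The linearly summed unilateral response set adds the trial-averaged
    non-preferred-side response trace (the side with lower unilateral
    I_S) to each preferred-side trial; ``I_S_u_sum`` is the MI of those
    summed traces against the bilateral profile ``C_L+R,t``.  Positive
    values indicate supralinear binasal summation, negative saturating
    summation.  Callers should restrict to ROIs passing the b-STIM
    strong-sensory criterion (I_S_b near zero makes the ratio undefined).
    """
    if i_s_b <= 0:
        return float("nan")
    pref, nonpref = ("l-STIM", "r-STIM") if i_s_l >= i_s_r else ("r-STIM", "l-STIM")
    summed = dff_by_cond[pref] + dff_by_cond[nonpref].mean(axis=0, keepdims=True)
    c_bl = profiles["b-STIM"].c_bl
    n_trials = summed.shape[0]
    prof = np.broadcast_to(c_bl.mean(axis=0), (n_trials, c_bl.shape[1]))
    x, y = _concat_condition(summed, prof)
    i_s_u_sum = mi_kde(x, y, **mi_kwargs)
    return (i_s_b - i_s_u_sum) / i_s_b


def normalized_information(i_s: float, ob_reference: float) -> float:
    """I_N: I_S normalized to the matching olfactory-bulb mean I_S."""
    if ob_reference <= 0:
        return float("nan")
    return i_s / ob_reference


# ---------------------------------------------------------------------------
# whole-dataset driver


def analyze_encoding(
    dataset: RoiTraceSet,
    strong_factor: float = 2.5,
    moderate_factor: float = 1.25,
    n_shuffles: int = 1,
    seed: int = 0,
    exclude_frames: int = EXCLUDE_FRAMES,
    baseline_frames: int = BASELINE_FRAMES,
    **mi_kwargs,
) -> pd.DataFrame:
    """Run the full per-ROI encoding analysis on one larva's dataset.

    Computes dF/F, normalized stimulus profiles and motor output, the
    three I_S values and I_M per ROI, shuffled-null distributions (one
    value per ROI per condition by default, pooled across the three
    stimulus conditions), encoding labels, selectivities, ``I_N`` and
    ``F_Is``, and returns them as one row per ROI.
    """
    rng = np.random.default_rng(seed)
    trim = lambda a: a[..., exclude_frames:]

    # normalized stimulus profiles aligned to retained frames
    profiles: dict[str, StimulusProfile] = {}
    for cond in STIM_CONDITIONS:
        profiles[cond] = normalize_stimulus(
            trim(dataset.stim[cond]["l"]), trim(dataset.stim[cond]["r"]), cond
        )

    # per-ROI dF/F by condition
    dff: dict[str, np.ndarray] = {
        cond: compute_dff(dataset.traces[cond], exclude_frames, baseline_frames)
        for cond in dataset.traces
    }

    # motor output aligned 1:1 with imaging frames, then trimmed alike
    has_motor = bool(dataset.tail)
    if has_motor:
        motor = {
            cond: motor_output(dataset.tail[cond], dataset.fps_tail)[
                ..., exclude_frames:
            ]
            for cond in dataset.tail
        }
        motor_concat = np.concatenate(
            [motor[c].ravel() for c in dataset.traces if c in motor]
        )

    rows = []
    null_is_pool: list[float] = []
    null_im_pool: list[float] = []
    null_im_base_pool: list[float] = []
    per_roi: list[dict] = []
    for r in range(dataset.n_rois):
        dff_r = {c: dff[c][r] for c in dff}
        i_s = roi_sensory_mi(dff_r, profiles, **mi_kwargs)
        nulls = shuffle_null(dff_r, profiles, rng, n_shuffles, **mi_kwargs)
        for cond in STIM_CONDITIONS:
            null_is_pool.extend(nulls[cond])
        rec = {"i_s_l": i_s["l-STIM"], "i_s_r": i_s["r-STIM"], "i_s_b": i_s["b-STIM"]}
        if has_motor:
            x = np.concatenate([dff_r[c].ravel() for c in dff if c in motor])
            rec["i_m"] = mi_kde(x, motor_concat, **mi_kwargs)
            null_im_pool.append(
                mi_kde(x, rng.permutation(motor_concat), **mi_kwargs)
            )
            if "null" in dff_r and "null" in motor:
                xb = dff_r["null"].ravel()
                yb = motor["null"].ravel()
                rec["i_m_baseline"] = mi_kde(xb, yb, **mi_kwargs)
                null_im_base_pool.append(
                    mi_kde(xb, rng.permutation(yb), **mi_kwargs)
                )
        else:
            rec["i_m"] = 0.0
        per_roi.append(rec)

    pooled_is_max = max(null_is_pool)
    im_max = max(null_im_pool) if null_im_pool else float("inf")
    im_base_max = max(null_im_base_pool) if null_im_base_pool else None

    ob_means = _ob_reference_means(dataset.roi_info, per_roi)

    for r, rec in enumerate(per_roi):
        info = dataset.roi_info.iloc[r]
        i_s = {"l-STIM": rec["i_s_l"], "r-STIM": rec["i_s_r"], "b-STIM": rec["i_s_b"]}
        labels = classify_roi(
            i_s,
            rec["i_m"],
            pooled_is_max,
            im_max if has_motor else float("inf"),
            strong_factor,
            moderate_factor,
            rec.get("i_m_baseline"),
            im_base_max,
        )
        ipsi, contra = (
            (rec["i_s_l"], rec["i_s_r"])
            if info["side"] == "L"
            else (rec["i_s_r"], rec["i_s_l"])
        )
        f_is = float("nan")
        if rec["i_s_b"] > strong_factor * pooled_is_max:
            dff_r = {c: dff[c][r] for c in dff}
            f_is = nonlinear_fraction(
                dff_r, profiles, rec["i_s_l"], rec["i_s_r"], rec["i_s_b"], **mi_kwargs
            )
        row = {
            "roi_id": info["roi_id"],
            "region": info["region"],
            "side": info["side"],
            **rec,
            "null_is_max": pooled_is_max,
            "null_im_max": im_max if has_motor else float("nan"),
            "sensory": "sensory" in labels,
            "motor": "motor" in labels,
            "sensorimotor": "sensorimotor" in labels,
            "sensory_only": "sensory-only" in labels,
            "motor_only": "motor-only" in labels,
            "baseline_motor": "baseline-motor" in labels,
            "ipsi_selectivity": ipsi_selectivity(ipsi, contra),
            "right_selectivity": right_selectivity(rec["i_s_l"], rec["i_s_r"]),
            "i_n_l": normalized_information(rec["i_s_l"], ob_means["L"]),
            "i_n_r": normalized_information(rec["i_s_r"], ob_means["R"]),
            "i_n_b": normalized_information(rec["i_s_b"], ob_means["B"]),
            "f_is": f_is,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def _ob_reference_means(roi_info: pd.DataFrame, per_roi: list[dict]) -> dict:
    """Mean olfactory-bulb I_S per side rule (left/right/bilateral)."""
    is_ob = (roi_info["region"] == "OB").to_numpy()
    sides = roi_info["side"].to_numpy()
    out = {}
    for key, col, side in (("L", "i_s_l", "L"), ("R", "i_s_r", "R")):
        sel = is_ob & (sides == side)
        vals = [per_roi[i][col] for i in np.flatnonzero(sel)]
        out[key] = float(np.mean(vals)) if vals else float("nan")
    vals = [per_roi[i]["i_s_b"] for i in np.flatnonzero(is_ob)]
    out["B"] = float(np.mean(vals)) if vals else float("nan")
    return out
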