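"""Bout detection, crossing segmentation and kinematic statistics."""

import numpy as np
import pytest

from chemonav.behavior import (
    Trajectory,
    bout_frequency,
    compute_tail_angle,
    detect_bouts,
    escape_metrics,
    occupancy_footprint,
    proximity_exclusion,
    segment_crossings,
    tail_events,
    turn_statistics,
    zone_fraction_sem,
)
from chemonav.synthetic import BehaviorGenConfig, gen_trajectory

FPS = 240.0


def make_traj(x, y, theta, fps=FPS, larva_id="t"):
    n = len(x)
    return Trajectory(larva_id, np.arange(n) / fps, np.asarray(x, float),
                      np.asarray(y, float), np.asarray(theta, float))


def static_traj(n=200, x=30.0, y=15.0, theta=0.0):
    return make_traj(np.full(n, x), np.full(n, y), np.full(n, theta))


def oracle_detect(traj, ang_thresh=1.2, lin_thresh=12.0, smooth_frames=3,
                  merge_gap_ms=50.0, min_frames=2):
    """Independent frame-wise reimplementation of the bout rules."""
    dt_ms = 1000.0 / traj.fps
    n = traj.n_frames

    def smooth(a):
        if smooth_frames <= 1:
            return a
        pad = smooth_frames // 2
        padded = np.concatenate([[a[0]] * pad, a, [a[-1]] * pad])
        return np.array(
            [padded[i : i + smooth_frames].mean() for i in range(n)]
        )

    x, y = smooth(traj.x), smooth(traj.y)
    th = smooth(np.unwrap(traj.theta, period=360.0))
    active = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        span = (hi - lo) * dt_ms
        ang = abs(th[hi] - th[lo]) / span
        lin = np.hypot(x[hi] - x[lo], y[hi] - y[lo]) / span * 1000.0
        active[i] = ang >= ang_thresh or lin >= lin_thresh
    # runs, merge, minimum length
    runs = []
    i = 0
    while i < n:
        if active[i]:
            j = i
            while j + 1 < n and active[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and (s - merged[-1][1] - 1) * dt_ms < merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s + 1 >= min_frames]


class TestDetectBouts:
    def test_stationary_trajectory_has_no_bouts(self):
        assert detect_bouts(static_traj()) == []

    def test_single_turn_episode(self):
        # 20-frame episode turning at 1.5 deg/ms, otherwise static
        n, dt_ms = 400, 1000.0 / FPS
        theta = np.zeros(n)
        step = 1.5 * dt_ms
        for k in range(20):
            theta[200 + k :] += step
        traj = make_traj(np.full(n, 30.0), np.full(n, 15.0), theta)
        bouts = detect_bouts(traj)
        assert len(bouts) == 1
        # net heading change ~ rate x episode duration
        # detected run boundaries may shave the first/last turn frame
        assert bouts[0].final_dtheta == pytest.approx(1.5 * 20 * dt_ms, rel=0.15)
        assert bouts[0].mean_angular_velocity > 0

    def test_pure_translation_detected_by_linear_criterion(self):
        n, dt = 400, 1.0 / FPS
        x = np.full(n, 10.0)
        speed = 15.0  # um/ms == mm/s
        for k in range(30):
            x[200 + k :] += speed * dt
        traj = make_traj(x, np.full(n, 15.0), np.zeros(n))
        bouts = detect_bouts(traj)
        assert len(bouts) == 1
        assert bouts[0].final_dtheta == pytest.approx(0.0, abs=1e-9)
        assert bouts[0].peak_linear_velocity >= 12.0
        # raising the linear threshold above the speed removes the bout
        assert detect_bouts(traj, lin_thresh=20.0) == []

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            detect_bouts(static_traj(n=2))

    def test_nonuniform_timestamps_rejected(self):
        t = np.array([0.0, 0.1, 0.3])
        with pytest.raises(ValueError):
            Trajectory("t", t, np.zeros(3), np.zeros(3), np.zeros(3))

    def test_matches_framewise_oracle_on_synthetic_swims(self):
        for seed in range(5):
            cfg = BehaviorGenConfig(n_larvae=1, duration_s=5.0, seed=seed)
            (traj,), _ = gen_trajectory(cfg)
            got = [(b.start_frame, b.end_frame) for b in detect_bouts(traj)]
            assert got == oracle_detect(traj), f"seed={seed}"

    def test_threshold_monotonicity(self):
        cfg = BehaviorGenConfig(n_larvae=2, duration_s=20.0, seed=3)
        trajs, _ = gen_trajectory(cfg)
        for traj in trajs:
            base = len(detect_bouts(traj))
            assert len(detect_bouts(traj, ang_thresh=2.4)) <= base
            assert len(detect_bouts(traj, lin_thresh=24.0)) <= base


class TestSegmentCrossings:
    def path_through_zone(self, arena):
        # straight line in and back out of the stimulus zone
        x = np.concatenate([
            np.linspace(30, 45, 300), np.linspace(45, 30, 300)])
        return make_traj(x, np.full(600, 15.0), np.zeros(600))

    def test_single_round_trip_is_one_event(self, arena):
        traj = self.path_through_zone(arena)
        events = segment_crossings(traj, arena)
        assert len(events) == 1
        ev = events[0]
        assert ev.entry_frame < ev.exit_frame
        assert ev.escape_time > 0
        assert ev.path_length >= 2 * (45 - (arena.border_x + arena.margin)) - 1

    def test_path_short_of_margin_no_event(self, arena):
        x = np.concatenate([
            np.linspace(30, arena.border_x + 0.5, 300),
            np.linspace(arena.border_x + 0.5, 30, 300)])
        traj = make_traj(x, np.full(600, 15.0), np.zeros(600))
        assert segment_crossings(traj, arena) == []

    def test_dither_within_margin_no_event(self, arena):
        # oscillate within +-0.9 mm of the border: hysteresis suppresses it
        n = 1000
        x = arena.border_x + 0.9 * np.sin(np.linspace(0, 20 * np.pi, n))
        traj = make_traj(x, np.full(n, 15.0), np.zeros(n))
        assert segment_crossings(traj, arena) == []

    def test_events_disjoint_and_ordered(self, arena):
        cfg = BehaviorGenConfig(n_larvae=1, duration_s=120.0, seed=9)
        (traj,), _ = gen_trajectory(cfg)
        events = segment_crossings(traj, arena)
        for a, b in zip(events, events[1:]):
            assert a.exit_frame < b.entry_frame

    def test_exclusion_mask_flags_event(self, arena):
        traj = self.path_through_zone(arena)
        mask = np.zeros(traj.n_frames, dtype=bool)
        mask[350] = True
        events = segment_crossings(traj, arena, exclusion_mask=mask)
        assert len(events) == 1 and events[0].excluded


class TestEscapeAndTurnStats:
    def make_events(self, bout_counts, arena):
        events = []
        for n_b in bout_counts:
            cfg = BehaviorGenConfig(n_larvae=1, duration_s=60.0, seed=n_b)
            (traj,), _ = gen_trajectory(cfg)
            evs = segment_crossings(traj, arena)
            events.extend(evs)
        return events

    def test_escape_fraction_trivial_cases(self):
        from chemonav.behavior import CrossingEvent, SwimBout

        def ev(n):
            bouts = [
                SwimBout(i, i + 1, 0.1, 10.0, 0.1, 0.5, 15.0) for i in range(n)
            ]
            return CrossingEvent(0, 10, 0.0, bouts, 5.0, 1.0)

        res = escape_metrics([ev(2)])
        assert res["summary"]["frac_escape_le2_bouts"] == 1.0
        res = escape_metrics([ev(1), ev(2), ev(3), ev(4)])
        assert res["summary"]["frac_escape_le2_bouts"] == 0.5
        assert res["summary"]["n_bouts"]["median"] == 2.5

    def test_empty_input_empty_summary(self):
        res = escape_metrics([])
        assert res["summary"] == {}

    def test_uniform_turns_concentrate_histogram(self):
        from chemonav.behavior import CrossingEvent, SwimBout

        bouts = [SwimBout(i * 10, i * 10 + 5, 0.1, 30.0, 0.3, 1.0, 15.0)
                 for i in range(4)]
        ev = CrossingEvent(0, 100, 10.0, bouts, 5.0, 1.0)
        stats = turn_statistics([ev])
        assert np.allclose(stats["first_final_dtheta"], 30.0)
        assert np.allclose(stats["abs_dtheta_mean"], 30.0)
        assert stats["direction_tally"]["left_turns"] == 1  # first bouts only

    def test_first_bout_gain_recovered(self, arena):
        # generator inflating first in-zone bouts 2x should show up as a
        # first/subsequent |dtheta| ratio near 2
        cfg = BehaviorGenConfig(
            n_larvae=6, duration_s=240.0, first_bout_gain=2.0, seed=21
        )
        trajs, log = gen_trajectory(cfg)
        events = []
        for traj in trajs:
            events.extend(segment_crossings(traj, arena))
        stats = turn_statistics(events)
        first = np.mean(np.abs(stats["first_final_dtheta"]))
        subseq = stats["abs_dtheta_mean"][1:4].mean()
        assert first / subseq == pytest.approx(2.0, rel=0.35)

    def test_unbiased_turn_directions(self, arena):
        cfg = BehaviorGenConfig(n_larvae=8, duration_s=600.0, seed=22)
        trajs, _ = gen_trajectory(cfg)
        events = []
        for traj in trajs:
            events.extend(segment_crossings(traj, arena))
        stats = turn_statistics(events)
        tal = stats["direction_tally"]
        n = tal["left_turns"] + tal["right_turns"]
        assert n > 20
        # within 4 sigma of a fair binomial
        assert abs(tal["left_turns"] - n / 2) < 4 * np.sqrt(n * 0.25)


class TestBoutFrequency:
    def test_simple_rate(self):
        from chemonav.behavior import SwimBout

        bouts = [SwimBout(int(k * 800), int(k * 800 + 40), 0.2, 10, 0.05, 1, 15)
                 for k in range(6)]
        # 6 bouts across 4800 frames at 240 fps = 20 s
        assert bout_frequency(bouts, (0, 4800), 240.0) == pytest.approx(0.3)
        assert bout_frequency([], (0, 4800), 240.0) == 0.0

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            bout_frequency([], (5, 5), 240.0)

    def test_poisson_rate_recovery(self, arena):
        lam = 1.0
        cfg = BehaviorGenConfig(n_larvae=1, duration_s=300.0,
                                baseline_bout_rate=lam, seed=4)
        (traj,), log = gen_trajectory(cfg)
        bouts = detect_bouts(traj)
        est = bout_frequency(bouts, (0, traj.n_frames - 1), traj.fps)
        se = np.sqrt(lam / 300.0)
        # detection merges a few adjacent bouts, so allow a little slack
        assert abs(est - lam) < 3 * se + 0.1


class TestOccupancy:
    def test_fixed_larva_in_zone(self, arena):
        traj = static_traj(x=50.0)
        m = occupancy_footprint([traj], arena)
        assert m.zone_fractions["stimulus"] == pytest.approx(1.0)
        assert m.delta_mirror == pytest.approx(1.0)
        assert abs(sum(m.zone_fractions.values()) - 1.0) < 1e-9

    def test_uniform_positions_match_area_fraction(self, rng, arena):
        n = 60000
        traj = make_traj(rng.uniform(0, 60, n), rng.uniform(0, 30, n),
                         np.zeros(n))
        m = occupancy_footprint([traj], arena)
        area_frac = (60 - arena.border_x) / 60.0
        assert m.zone_fractions["stimulus"] == pytest.approx(area_frac, abs=0.02)
        assert abs(m.delta_mirror) < 0.02

    def test_mirrored_trajectory_zero_delta(self, arena):
        n = 1000
        x = np.linspace(5, 55, n)
        traj = make_traj(x, np.full(n, 15.0), np.zeros(n))
        mirrored = make_traj(60.0 - x, np.full(n, 15.0), np.zeros(n))
        m = occupancy_footprint([traj, mirrored], arena)
        assert m.delta_mirror == pytest.approx(0.0, abs=1e-9)

    def test_grid_nonnegative_and_sem(self, arena):
        maps = [
            occupancy_footprint([static_traj(x=50.0)], arena),
            occupancy_footprint([static_traj(x=30.0)], arena),
        ]
        assert all((m.grid >= 0).all() for m in maps)
        sem = zone_fraction_sem(maps)
        assert sem["stimulus_mean"] == pytest.approx(0.5)
        assert sem["stimulus_sem"] > 0


class TestProximityExclusion:
    def test_center_alone_unmasked(self, arena):
        masks = proximity_exclusion([static_traj()], arena)
        assert not masks[0].any()

    def test_near_wall_masked(self, arena):
        masks = proximity_exclusion([static_traj(y=3.0)], arena)
        assert masks[0].all()

    def test_converging_pair_masked_from_contact(self, arena):
        n = 100
        a = make_traj(np.linspace(20, 30, n), np.full(n, 15.0), np.zeros(n))
        b = make_traj(np.linspace(40, 30, n), np.full(n, 15.0), np.zeros(n))
        masks = proximity_exclusion([a, b], arena)
        dist = np.abs(a.x - b.x)
        expected = dist <= arena.exclusion_distance
        assert np.array_equal(masks[0], expected)
        assert np.array_equal(masks[1], expected)


class TestTail:
    def test_tail_angle_on_axis_zero(self):
        assert compute_tail_angle((1, 0), (0, 0), (-2, 0)) == pytest.approx(0.0)

    def test_tail_angle_perpendicular(self):
        assert compute_tail_angle((1, 0), (0, 0), (0, 1)) == pytest.approx(90.0)

    def test_tail_angle_diagonal(self):
        assert compute_tail_angle((1, 0), (0, 0), (-1, 1)) == pytest.approx(45.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            compute_tail_angle((1, 0), (1, 1), (1, 1))

    def test_flat_trace_no_events(self):
        res = tail_events(np.zeros(2000))
        assert res["frequency_hz"] == 0.0
        assert res["event_times"].size == 0

    def test_single_flick(self):
        trace = np.zeros(2000)
        trace[500:520] = 30.0
        res = tail_events(trace)
        assert res["event_times"].size == 1
        assert res["event_times"][0] == pytest.approx(2.5)

    def test_poisson_rate_recovery(self):
        from chemonav.synthetic import gen_tail

        lam, dur = 0.33, 600.0
        active, times = gen_tail(lam, dur, seed=8)
        angles = np.where(active, 45.0, 2.0)
        res = tail_events(angles)
        se = np.sqrt(lam / dur)
        assert abs(res["frequency_hz"] - lam) < 3 * se
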