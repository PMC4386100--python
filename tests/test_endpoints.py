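"""Endpoint extraction: distances, freeze/burst detection with brute-force
oracles, spatial occupancy against geometry, and pair averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fishtrack3d import (BehavioralEndpoints,
                         DetectorThresholds, SimulationConfig, ValidationError,
                         classify_spatial, compute_endpoints, detect_bursts,
                         detect_freezes, simulate_pair_recording,
                         summarize_pair, travel_distances)

from conftest import make_trajectory


# ---------------------------------------------------------------------------
# independent oracles

def freeze_oracle(times, positions, speed_thr, min_dur):
    """Run-length enumeration over forward-difference speeds."""
    episodes = []
    start = None
    for i in range(len(times) - 1):
        step = np.linalg.norm(positions[i + 1] - positions[i])
        speed = step / (times[i + 1] - times[i])
        if speed < speed_thr:
            if start is None:
                start = times[i]
        else:
            if start is not None and times[i] - start >= min_dur:
                episodes.append((start, times[i]))
            start = None
    if start is not None and times[-1] - start >= min_dur:
        episodes.append((start, times[-1]))
    return episodes


def burst_oracle(times, positions, accel_thr_m_s2, refractory):
    """Hand enumeration of refractory-merged upward accel crossings."""
    crossings = []
    prev_above = False
    for i in range(1, len(times) - 1):
        dt0 = times[i] - times[i - 1]
        dt1 = times[i + 1] - times[i]
        acc = 2.0 * (dt0 * (positions[i + 1] - positions[i])
                     - dt1 * (positions[i] - positions[i - 1])) \
            / (dt0 * dt1 * (dt0 + dt1))
        above = np.linalg.norm(acc) > accel_thr_m_s2 * 1000.0
        if above and not prev_above:
            crossings.append(times[i])
        prev_above = above
    count = 0
    last = -np.inf
    for t in crossings:
        if t - last >= refractory:
            count += 1
            last = t
    return count


# ---------------------------------------------------------------------------


class TestTravelDistances:
    def test_stationary_is_zero(self):
        traj = make_trajectory([0, 0.1, 0.2], np.tile([5.0, 5, 5], (3, 1)))
        assert travel_distances(traj) == (0.0, 0.0, 0.0)

    def test_3_4_5_right_triangle_step(self):
        traj = make_trajectory([0.0, 1.0], [[0, 0, 0], [3.0, 0.0, 4.0]])
        d3, dh, dv = travel_distances(traj)
        assert (d3, dh, dv) == (5.0, 3.0, 4.0)

    def test_matches_bruteforce_summation(self, control_trajectory):
        d3, dh, dv = travel_distances(control_trajectory)
        p = control_trajectory.positions_mm
        ref3 = sum(float(np.linalg.norm(p[i + 1] - p[i]))
                   for i in range(len(p) - 1))
        refh = sum(float(np.hypot(*(p[i + 1, :2] - p[i, :2])))
                   for i in range(len(p) - 1))
        refv = sum(float(abs(p[i + 1, 2] - p[i, 2]))
                   for i in range(len(p) - 1))
        assert d3 == pytest.approx(ref3, rel=1e-9)
        assert dh == pytest.approx(refh, rel=1e-9)
        assert dv == pytest.approx(refv, rel=1e-9)

    def test_gaps_joined_across_missing_samples(self):
        pos = np.array([[0, 0, 0], [np.nan] * 3, [3.0, 4.0, 0.0]])
        traj = make_trajectory([0.0, 0.1, 0.2], pos)
        assert travel_distances(traj)[0] == pytest.approx(5.0)


class TestDetectFreezes:
    def test_uniform_subthreshold_single_episode(self):
        t = np.arange(0, 10.025, 0.025)
        pos = np.column_stack([t * 1.0, np.zeros_like(t), np.zeros_like(t)])
        episodes = detect_freezes(make_trajectory(t, pos + 50))
        assert len(episodes) == 1
        start, end = episodes[0]
        assert end - start == pytest.approx(10.0, abs=0.05)

    def test_suprathreshold_no_episode(self):
        t = np.arange(0, 10.0, 0.025)
        pos = np.column_stack([t * 3.0, np.zeros_like(t), np.zeros_like(t)])
        assert detect_freezes(make_trajectory(t, pos + 50)) == []

    def test_planted_alternation_recovered(self):
        """2 s still / 2 s cruise alternation for 60 s with sub-threshold
        noise: every planted episode recovered, onsets within one frame."""
        rng = np.random.default_rng(21)
        dt = 0.025
        t = np.arange(0, 60.0, dt)
        moving = (t // 2).astype(int) % 2 == 1
        vel = np.where(moving, 20.0, 0.0)
        x = 50 + np.cumsum(vel * dt)
        # still-phase jitter at ~0.5 mm/s keeps speed below the 2 mm/s cut
        jitter = np.cumsum(np.where(moving, 0.0,
                                    rng.uniform(-1, 1, t.size) * 0.5 * dt))
        pos = np.column_stack([x + jitter, np.full(t.size, 50.0),
                               np.full(t.size, 50.0)])
        episodes = detect_freezes(make_trajectory(t, pos))
        planted_starts = [0.0] + [4.0 * k for k in range(1, 15)]
        assert len(episodes) == len(planted_starts)
        for (start, _), expected in zip(episodes, planted_starts):
            assert abs(start - expected) <= dt + 1e-9

    def test_matches_runlength_oracle(self, control_trajectory):
        thr = DetectorThresholds()
        got = detect_freezes(control_trajectory, thr)
        ref = freeze_oracle(control_trajectory.times_s,
                            control_trajectory.positions_mm,
                            thr.freeze_speed_mm_s, thr.freeze_min_duration_s)
        assert got == pytest.approx(ref)

    def test_threshold_monotonicity(self, geometry):
        rec = simulate_pair_recording(
            SimulationConfig(duration_s=60.0, freeze_rate_scale=5.0),
            geometry, 31)
        durations = []
        for thr_speed in (1.0, 2.0, 4.0, 8.0):
            eps = detect_freezes(rec.fish_a,
                                 DetectorThresholds(freeze_speed_mm_s=thr_speed))
            durations.append(sum(e - s for s, e in eps))
        assert np.all(np.diff(durations) >= 0)


class TestDetectBursts:
    def test_constant_velocity_no_bursts(self):
        t = np.arange(0, 5.0, 0.025)
        pos = np.column_stack([t * 30.0, t * 10.0, np.zeros_like(t)])
        assert detect_bursts(make_trajectory(t, pos + 20)) == 0

    def test_planted_pulse_detected(self):
        """One 100 ms pulse peaking at 3 m/s² in a smooth path → 1 burst."""
        dt = 0.025
        t = np.arange(0, 10.0, dt)
        accel = np.zeros_like(t)
        pulse = (t >= 5.0) & (t < 5.1)
        accel[pulse] = 3000.0  # mm/s^2
        vel = np.cumsum(accel * dt) + 10.0
        pos = np.column_stack([5 + np.cumsum(vel * dt),
                               np.full(t.size, 50.0), np.full(t.size, 50.0)])
        assert detect_bursts(make_trajectory(t, pos)) == 1

    @pytest.mark.parametrize("gap_s,expected", [(0.2, 1), (1.0, 2)])
    def test_refractory_merging(self, gap_s, expected):
        """Two pulses 0.2 s apart merge under a 0.5 s refractory; 1.0 s
        apart they count separately."""
        dt = 0.025
        t = np.arange(0, 10.0, dt)
        accel = np.zeros_like(t)
        for t0 in (4.0, 4.0 + gap_s):
            accel[(t >= t0) & (t < t0 + 0.05)] = 3000.0
        vel = np.cumsum(accel * dt) + 5.0
        pos = np.column_stack([5 + np.cumsum(vel * dt),
                               np.full(t.size, 50.0), np.full(t.size, 50.0)])
        assert detect_bursts(make_trajectory(t, pos)) == expected

    def test_matches_enumeration_oracle(self, control_trajectory):
        thr = DetectorThresholds()
        assert detect_bursts(control_trajectory, thr) == burst_oracle(
            control_trajectory.times_s, control_trajectory.positions_mm,
            thr.burst_accel_m_s2, thr.burst_refractory_s)

    def test_threshold_monotonicity(self, control_trajectory):
        counts = [detect_bursts(control_trajectory,
                                DetectorThresholds(burst_accel_m_s2=a))
                  for a in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(counts) <= 0)


class TestClassifySpatial:
    def test_center_point(self, geometry):
        pos = np.tile([125.0, 125.0, 67.5], (10, 1))
        traj = make_trajectory(np.arange(10) * 0.1, pos)
        mh, depth, mcd, radial, quad = classify_spatial(traj, geometry)
        assert depth == (0.0, 1.0, 0.0)
        assert radial == (1.0, 0.0, 0.0, 0.0)
        assert mcd == 0.0
        assert mh == pytest.approx(67.5)

    def test_corner_point_near_bottom(self, geometry):
        pos = np.tile([1.0, 1.0, 5.0], (10, 1))
        traj = make_trajectory(np.arange(10) * 0.1, pos)
        _, depth, mcd, radial, _ = classify_spatial(traj, geometry)
        assert depth == (1.0, 0.0, 0.0)
        assert radial == (0.0, 0.0, 0.0, 1.0)
        assert mcd == pytest.approx(np.hypot(124.0, 124.0))

    def test_uniform_positions_match_area_fractions(self, geometry):
        """Uniform footprint occupancy → radial fractions approach the
        analytic circle-area fractions (pi/36, 3pi/36, 5pi/36, 1 - pi/4)
        and quadrants approach 0.25, all within 3 binomial SE."""
        n = 10 ** 6
        rng = np.random.default_rng(99)
        pos = rng.uniform([0, 0, 0], [250, 250, 135], size=(n, 3))
        traj = make_trajectory(np.arange(n) * 0.025, pos)
        _, _, _, radial, quad = classify_spatial(traj, geometry)
        expected = np.array([np.pi / 36, 3 * np.pi / 36, 5 * np.pi / 36,
                             1 - np.pi / 4])
        for got, exp in zip(radial, expected):
            se = np.sqrt(exp * (1 - exp) / n)
            assert abs(got - exp) < 3 * se
        for got in quad:
            se = np.sqrt(0.25 * 0.75 / n)
            assert abs(got - 0.25) < 3 * se

    def test_quadrant_numbering_convention(self, geometry):
        # one point per quadrant: FL, FR, BR, BL
        pts = [(60, 60), (190, 60), (190, 190), (60, 190)]
        for expected_q, (x, y) in enumerate(pts):
            traj = make_trajectory([0, 0.1], np.tile([x, y, 50.0], (2, 1)))
            quad = classify_spatial(traj, geometry)[4]
            assert quad[expected_q] == 1.0

    def test_fractions_sum_to_one(self, control_trajectory, geometry):
        _, depth, _, radial, quad = classify_spatial(control_trajectory,
                                                     geometry)
        for fracs in (depth, radial, quad):
            assert sum(fracs) == pytest.approx(1.0, abs=1e-9)


class TestSummarizePair:
    def _endpoints(self, **over):
        base = dict(
            dist3d_mm=100.0, dist_h_mm=80.0, dist_v_mm=40.0,
            freeze_duration_s=10.0, freeze_count=3.0, burst_count=2.0,
            mean_height_mm=50.0, depth_fracs=(0.5, 0.3, 0.2),
            mean_center_dist_mm=60.0, radial_fracs=(0.1, 0.2, 0.3, 0.4),
            quadrant_fracs=(0.25, 0.25, 0.25, 0.25), duration_s=600.0)
        base.update(over)
        return BehavioralEndpoints(**base)

    def test_idempotent_on_identical_inputs(self):
        a = self._endpoints()
        out = summarize_pair(a, a)
        assert out == a

    def test_arithmetic_mean(self):
        out = summarize_pair(
            self._endpoints(dist3d_mm=100.0, dist_h_mm=80.0, dist_v_mm=40.0),
            self._endpoints(dist3d_mm=200.0, dist_h_mm=160.0, dist_v_mm=80.0))
        assert out.dist3d_mm == 150.0

    def test_duration_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="durations differ"):
            summarize_pair(self._endpoints(duration_s=600.0),
                           self._endpoints(duration_s=500.0))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariants_preserved_under_pair_mean(self, seed):
        """The pair mean of two random valid endpoint vectors satisfies all
        endpoint invariants (convex combination preserves them)."""
        rng = np.random.default_rng(seed)

        def rand_ep():
            dh, dv = rng.uniform(0, 500, 2)
            d3 = rng.uniform(max(dh, dv), dh + dv)
            duration = 600.0

            def simplex(k):
                v = rng.dirichlet(np.ones(k))
                return tuple(v)

            return BehavioralEndpoints(
                dist3d_mm=d3, dist_h_mm=dh, dist_v_mm=dv,
                freeze_duration_s=rng.uniform(0, duration),
                freeze_count=float(rng.integers(0, 50)),
                burst_count=float(rng.integers(0, 50)),
                mean_height_mm=rng.uniform(0, 135),
                depth_fracs=simplex(3),
                mean_center_dist_mm=rng.uniform(0, 175),
                radial_fracs=simplex(4),
                quadrant_fracs=simplex(4),
                duration_s=duration)

        out = summarize_pair(rand_ep(), rand_ep())
        out.check_invariants()


class TestComputeEndpoints:
    def test_full_vector_invariants_on_simulated_fish(self, geometry):
        rec = simulate_pair_recording(SimulationConfig(duration_s=30.0),
                                      geometry, 44)
        for fish in (rec.fish_a, rec.fish_b):
            ep = compute_endpoints(fish, geometry)
            ep.check_invariants()
            assert ep.dist3d_mm > 0
            assert ep.duration_s == pytest.approx(30.0, rel=0.01)
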