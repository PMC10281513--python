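"""Displacement-analysis geometry, occupancy and the intersection score."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_traj
from flysearch.analysis import (
    analyze_displacement_condition,
    analyze_pheromone_condition,
    fictive_zone,
    fraction_in_zone,
    initial_direction,
    intersection_score,
    mean_trajectory_vector,
    occupancy_histogram,
    to_fictive_frame,
    visited,
    PheromoneTrial,
)
from flysearch.trajectory import Trajectory, Zone


class TestFictiveGeometry:
    def test_zero_vector_is_identity(self):
        z = Zone((-9.8, 6.7), 2.8)
        assert fictive_zone(z, (0.0, 0.0)) == z

    def test_mean_displacement_example(self):
        # the actual stimulation zone shifted by a 9.2 cm pull along +x
        z = fictive_zone(Zone((-9.8, 6.7), 2.8), (9.2, 0.0))
        assert z.center == pytest.approx((-0.6, 6.7))
        assert z.radius == 2.8

    @given(dx=st.floats(-20, 20), dy=st.floats(-20, 20))
    def test_radius_always_preserved(self, dx, dy):
        assert fictive_zone(Zone((1.0, 2.0), 2.8), (dx, dy)).radius == 2.8

    @given(dx=st.floats(-10, 10), dy=st.floats(-10, 10),
           seed=st.integers(0, 20))
    def test_translating_data_equals_translating_zone(self, dx, dy, seed):
        rng = np.random.default_rng(seed)
        traj = make_traj(rng.uniform(-20, 20, 30), rng.uniform(-20, 20, 30))
        actual = Zone((-9.8, 6.7), 2.8)
        fict = fictive_zone(actual, (dx, dy))
        moved = to_fictive_frame(traj, (dx, dy))
        d_fict = np.hypot(traj.x - fict.center[0], traj.y - fict.center[1])
        d_actual = np.hypot(moved.x - actual.center[0],
                            moved.y - actual.center[1])
        np.testing.assert_allclose(d_fict, d_actual, atol=1e-9)
        assert moved.frame == "fictive"

    def test_double_application_with_inverse_is_identity(self):
        traj = make_traj([1.0, 2.0], [3.0, 4.0])
        back = to_fictive_frame(to_fictive_frame(traj, (2.0, -1.0)),
                                (-2.0, 1.0))
        np.testing.assert_allclose(back.x, traj.x)
        np.testing.assert_allclose(back.y, traj.y)


class TestOccupancy:
    def test_sitting_fly_gives_single_unit_cell(self):
        traj = make_traj(np.full(100, 3.5), np.full(100, -2.5))
        h = occupancy_histogram([traj], mode="residency")
        assert h.grid.sum() == pytest.approx(1.0)
        assert np.count_nonzero(h.grid) == 1
        assert h.grid.max() == pytest.approx(1.0)

    def test_walking_mode_ignores_the_stop(self):
        xw = np.arange(0, 5.0, 0.05)
        walk = make_traj(np.concatenate([xw, 5.0 + xw]),
                         np.zeros(2 * len(xw)), dt=0.1)
        stop = np.full(600, xw[-1])
        with_stop = make_traj(np.concatenate([xw, stop, 5.0 + xw]),
                              np.zeros(2 * len(xw) + 600), dt=0.1)
        extent = (0.0, 11.0, -1.0, 1.0)
        a = occupancy_histogram([walk], mode="walking", extent=extent)
        b = occupancy_histogram([with_stop], mode="walking", extent=extent)
        np.testing.assert_allclose(a.grid, b.grid)

    def test_per_trial_averaging_of_disjoint_cells(self):
        t1 = make_traj(np.full(10, 0.5), np.full(10, 0.5))
        t2 = make_traj(np.full(30, 5.5), np.full(30, 5.5))
        h = occupancy_histogram([t1, t2], average="trials",
                                extent=(0, 6, 0, 6))
        occupied = h.grid[h.grid > 0]
        assert occupied == pytest.approx([0.5, 0.5])

    def test_grids_always_sum_to_one(self, rng):
        trajs = [make_traj(rng.uniform(-5, 5, 50), rng.uniform(-5, 5, 50))
                 for _ in range(3)]
        for mode in ("residency", "walking"):
            for avg in ("pooled", "trials"):
                h = occupancy_histogram(trajs, mode=mode, average=avg)
                assert h.grid.sum() == pytest.approx(1.0)

    def test_mixed_frames_rejected(self):
        a = make_traj([0.0], [0.0])
        b = to_fictive_frame(make_traj([0.0], [0.0]), (1.0, 1.0))
        with pytest.raises(ValueError, match="frame"):
            occupancy_histogram([a, b])


class TestZoneFractions:
    zone = Zone((0.0, 0.0), 1.0)

    def test_always_inside(self):
        traj = make_traj(np.zeros(100), np.zeros(100), dt=0.1)
        assert fraction_in_zone(traj, self.zone) == 1.0
        assert visited(traj, self.zone)

    def test_never_inside(self):
        traj = make_traj(np.full(100, 5.0), np.zeros(100), dt=0.1)
        assert fraction_in_zone(traj, self.zone) == 0.0
        assert not visited(traj, self.zone)

    def test_half_inside_matches_point_in_circle_count(self, rng):
        # half the 0.1 s samples sit at the center, half far outside
        n = 200
        x = np.where(np.arange(n) % 2 == 0, 0.0, 9.0)
        traj = make_traj(x, np.zeros(n), dt=0.1)
        frac = fraction_in_zone(traj, self.zone)
        oracle = np.mean(np.hypot(x, 0.0) <= self.zone.radius)
        assert frac == pytest.approx(oracle) == pytest.approx(0.5)

    def test_boundary_sample_counts_as_inside(self):
        traj = make_traj([1.0], [0.0])
        assert visited(traj, self.zone)

    @given(seed=st.integers(0, 30))
    def test_visited_iff_positive_fraction(self, seed):
        rng = np.random.default_rng(seed)
        traj = make_traj(rng.uniform(-3, 3, 40), rng.uniform(-3, 3, 40),
                         dt=0.1)
        assert visited(traj, self.zone) == (
            fraction_in_zone(traj, self.zone) > 0)

    def test_empty_window_is_an_error(self):
        traj = make_traj(np.zeros(10), np.zeros(10), dt=0.1)
        with pytest.raises(ValueError, match="window"):
            fraction_in_zone(traj, self.zone, window=(100.0, 200.0))


class TestInitialDirection:
    def test_due_north_endpoint(self):
        traj = make_traj([0.0, 0.0, 0.0], [0.0, 1.0, 2.0], dt=1.0)
        ang = initial_direction(traj, (0.0, 0.0), t_release=0.0, window_s=5)
        assert ang == pytest.approx(math.pi / 2)

    def test_endpoint_is_last_sample_in_window(self):
        # samples at t = 0..9 s; the 5 s window ends on the t = 5 sample
        x = np.arange(10.0)
        traj = make_traj(x, np.zeros(10), dt=1.0)
        ang = initial_direction(traj, (0.0, 0.0), t_release=0.0, window_s=5)
        assert ang == pytest.approx(0.0)

    def test_stationary_fly_is_excluded_with_warning(self):
        traj = make_traj(np.zeros(5), np.zeros(5), dt=1.0)
        with pytest.warns(UserWarning, match="stationary"):
            assert initial_direction(traj, (0.0, 0.0)) is None

    def test_mean_trajectory_vector_sums_endpoints(self):
        v = mean_trajectory_vector(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert v == pytest.approx((1.0, 1.0))
        assert math.atan2(v[1], v[0]) == pytest.approx(math.pi / 4)


class TestIntersectionScore:
    def _straight(self, x0, x1, n, y=0.0):
        return make_traj(np.linspace(x0, x1, n), np.full(n, y), dt=0.04)

    def test_exact_retrace_scores_its_length(self):
        before = self._straight(-1.8, 0.0, 80)
        after = self._straight(0.0, -1.5, 70)
        score = intersection_score(before, after, (0.0, 0.0))
        assert score == pytest.approx(1.5, abs=0.05)

    def test_perpendicular_crossing_is_bounded_by_proximity(self):
        before = self._straight(-1.8, 1.8, 160)
        after = make_traj(np.zeros(160), np.linspace(-1.8, 1.8, 160), dt=0.04)
        score = intersection_score(before, after, (0.0, 0.0))
        assert score < 2 * 0.25

    def test_disjoint_paths_score_zero(self):
        before = self._straight(-1.5, 1.5, 100, y=0.0)
        after = self._straight(-1.5, 1.5, 100, y=1.0)  # 10 mm apart
        assert intersection_score(before, after, (0.0, 0.0)) == 0.0

    def test_rigid_motion_invariance(self, rng):
        before = make_traj(np.cumsum(rng.normal(0, 0.05, 120)),
                           np.cumsum(rng.normal(0, 0.05, 120)))
        after = make_traj(np.cumsum(rng.normal(0, 0.05, 120)),
                          np.cumsum(rng.normal(0, 0.05, 120)))
        center = (0.0, 0.0)
        base = intersection_score(before, after, center)
        th, tx, ty = 0.83, 4.2, -1.7
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])

        def rigid(tr):
            xy = tr.xy @ R.T + (tx, ty)
            return make_traj(xy[:, 0], xy[:, 1])

        moved = intersection_score(rigid(before), rigid(after),
                                   tuple(np.array(center) @ R.T + (tx, ty)))
        assert moved == pytest.approx(base, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            before = make_traj(rng.uniform(-2.5, 2.5, n),
                               rng.uniform(-2.5, 2.5, n))
            after = make_traj(rng.uniform(-2.5, 2.5, n),
                              rng.uniform(-2.5, 2.5, n))
            got = intersection_score(before, after, (0.0, 0.0))
            assert got == pytest.approx(
                _oracle_score(before, after, (0.0, 0.0)))

    def test_empty_rejected(self):
        t = self._straight(0, 1, 10)
        empty = Trajectory(np.empty(0), np.empty(0), np.empty(0))
        with pytest.raises(ValueError):
            intersection_score(t, empty, (0.0, 0.0))


def _oracle_score(before, after, center, window_radius=2.0, prox=0.25):
    """Quadratic-time reference implementation."""
    bpts = [(x, y) for x, y in zip(before.x, before.y)
            if math.hypot(x - center[0], y - center[1]) <= window_radius]
    flags = []
    for x, y in zip(after.x, after.y):
        inwin = math.hypot(x - center[0], y - center[1]) <= window_radius
        near = any(math.hypot(x - bx, y - by) < prox for bx, by in bpts)
        flags.append(inwin and near)
    best = 0.0
    run = []
    for i, f in enumerate(flags + [False]):
        if f:
            run.append(i)
        elif run:
            d = math.hypot(after.x[run[-1]] - after.x[run[0]],
                           after.y[run[-1]] - after.y[run[0]])
            best = max(best, d)
            run = []
    return best


class TestEndToEnd:
    def test_empty_trial_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            analyze_displacement_condition([])
        with pytest.raises(ValueError, match="empty"):
            analyze_pheromone_condition([], Zone((0, 0), 1.0))

    def test_pheromone_exclusion_longer_than_recording(self):
        traj = make_traj(np.zeros(100), np.zeros(100), dt=0.1)  # 10 s long
        trials = [PheromoneTrial([traj], "without-emitter")]
        report = analyze_pheromone_condition(trials, Zone((0, 0), 1.0),
                                             exclude_initial_s=300.0)
        assert "error" in report.per_trial[0]
        assert "exclusion" in report.per_trial[0]["error"]
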