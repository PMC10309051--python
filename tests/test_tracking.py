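"""Tracking: Kalman filter against direct matrix arithmetic and closed-form
constant-velocity motion, assignment against a brute-force permutation
oracle, and whole-run identity conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hetrack import synthetic as syn
from hetrack import tracking as trk
from hetrack.config import Config
from hetrack.detection import Detection
from hetrack.tracking import (build_cost_matrix, hungarian_assign, kalman_init,
                              kalman_predict, kalman_update, link_tracks)

F = np.array([[1., 0., 1., 0.], [0., 1., 0., 1.],
              [0., 0., 1., 0.], [0., 0., 0., 1.]])
Q_UNIT = np.array([[0.25, 0., 0.5, 0.], [0., 0.25, 0., 0.5],
                   [0.5, 0., 1., 0.], [0., 0.5, 0., 1.]])


def brute_force_assignment(cost):
    """Exhaustive minimum over all permutations (oracle, n <= 7)."""
    n_rows, n_cols = cost.shape
    k = min(n_rows, n_cols)
    best = np.inf
    if n_rows <= n_cols:
        for perm in itertools.permutations(range(n_cols), k):
            best = min(best, sum(cost[i, j] for i, j in enumerate(perm)))
    else:
        for perm in itertools.permutations(range(n_rows), k):
            best = min(best, sum(cost[i, j] for j, i in enumerate(perm)))
    return best


class TestKalmanInit:
    def test_state_and_covariance_construction(self):
        t = kalman_init(Detection(0, 5.0, 7.0, 0.9), 4.0, 9.0)
        np.testing.assert_array_equal(t.state, [5, 7, 0, 0])
        np.testing.assert_array_equal(np.linalg.eigvalsh(t.covariance),
                                      sorted([4, 4, 9, 9]))
        assert t.skipped == 0

    def test_fresh_ids_are_distinct(self):
        a = kalman_init(Detection(0, 0, 0, 1), 1, 1)
        b = kalman_init(Detection(0, 0, 0, 1), 1, 1)
        assert a.id != b.id

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            kalman_init(Detection(0, 0, 0, 1), -1.0, 1.0)


class TestKalmanPredict:
    def test_noiseless_linear_motion(self):
        t = kalman_init(Detection(0, 0.0, 0.0, 1), 1, 1)
        t.state[:] = [0, 0, 1, 2]
        p = kalman_predict(t, process_noise_q=0.0)
        np.testing.assert_allclose(p.state, [1, 2, 1, 2])

    def test_zero_velocity_zero_q_is_stationary(self):
        t = kalman_init(Detection(0, 3.0, 4.0, 1), 2.0, 0.0)
        p = kalman_predict(t, 0.0)
        np.testing.assert_allclose(p.state, t.state)
        np.testing.assert_allclose(p.covariance, t.covariance)

    @pytest.mark.parametrize("seed", range(5))
    def test_covariance_propagation_matches_matrix_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 4))
        p0 = a @ a.T  # random PSD
        q = float(rng.uniform(0.1, 5))
        t = kalman_init(Detection(0, 0, 0, 1), 1, 1)
        t.covariance[...] = p0
        out = kalman_predict(t, q)
        np.testing.assert_allclose(out.covariance, F @ p0 @ F.T + q * Q_UNIT,
                                   atol=1e-12)

    def test_covariance_stays_symmetric_psd(self):
        t = kalman_init(Detection(0, 0, 0, 1), 1, 10)
        for _ in range(20):
            t = kalman_predict(t, 0.5)
            np.testing.assert_allclose(t.covariance, t.covariance.T)
            assert np.linalg.eigvalsh(t.covariance).min() >= -1e-9


class TestKalmanUpdate:
    def test_zero_measurement_noise_snaps_to_measurement(self):
        t = kalman_init(Detection(0, 0.0, 0.0, 1), 5.0, 5.0)
        u = kalman_update(t, (3.0, -2.0), measurement_noise_r=0.0)
        np.testing.assert_allclose(u.state[:2], [3, -2], atol=1e-12)

    def test_zero_innovation_keeps_position_and_shrinks_covariance(self):
        t = kalman_init(Detection(0, 1.0, 2.0, 1), 5.0, 5.0)
        u = kalman_update(t, (1.0, 2.0), measurement_noise_r=2.0)
        np.testing.assert_allclose(u.state[:2], [1, 2], atol=1e-12)
        assert np.trace(u.covariance) < np.trace(t.covariance)

    def test_huge_noise_ignores_measurement(self):
        t = kalman_init(Detection(0, 1.0, 2.0, 1), 5.0, 5.0)
        u = kalman_update(t, (100.0, 100.0), measurement_noise_r=1e12)
        np.testing.assert_allclose(u.state, t.state, atol=1e-6)

    def test_negative_noise_rejected(self):
        t = kalman_init(Detection(0, 0, 0, 1), 1, 1)
        with pytest.raises(ValueError):
            kalman_update(t, (0, 0), -1.0)

    def test_constant_velocity_convergence_closed_form(self):
        """Exact position measurements pin the state after two corrections:
        one-step prediction then matches the true motion to within 1e-6."""
        v = np.array([1.5, -0.5])
        pos = lambda t: np.array([10.0, 20.0]) + v * t
        track = kalman_init(Detection(0, *pos(0), 1.0), 10.0, 100.0)
        for t in (1, 2, 3):
            track = kalman_predict(track, process_noise_q=0.0)
            track = kalman_update(track, pos(t), measurement_noise_r=0.0)
        predicted = kalman_predict(track, 0.0)
        np.testing.assert_allclose(predicted.state[:2], pos(4), atol=1e-6)

    def test_posterior_trace_nonincreasing_with_fixed_r(self):
        track = kalman_init(Detection(0, 0.0, 0.0, 1.0), 10.0, 100.0)
        traces = []
        for t in range(1, 8):
            track = kalman_predict(track, 0.0)
            track = kalman_update(track, (2.0 * t, 0.0), 1.0)
            traces.append(np.trace(track.covariance))
        assert all(b <= a + 1e-12 for a, b in zip(traces, traces[1:]))


class TestAssignment:
    def test_cost_matrix_345_triangle(self):
        c = build_cost_matrix([(0, 0)], [(3, 4)])
        np.testing.assert_allclose(c, [[5.0]])

    def test_identical_point_sets_zero_diagonal(self):
        pts = [(1.0, 2.0), (5.0, 6.0), (9.0, 1.0)]
        c = build_cost_matrix(pts, pts)
        np.testing.assert_allclose(np.diag(c), 0.0)
        np.testing.assert_allclose(c, build_cost_matrix(pts, pts).T)

    def test_obvious_optimum(self):
        pairs, ur, uc = hungarian_assign(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert set(pairs) == {(0, 0), (1, 1)} and not ur and not uc

    def test_gate_demotes_expensive_match(self):
        pairs, ur, uc = hungarian_assign(np.array([[7.0]]), gate=5.0)
        assert pairs == [] and ur == [0] and uc == [0]

    def test_empty_inputs(self):
        pairs, ur, uc = hungarian_assign(np.zeros((0, 3)))
        assert pairs == [] and ur == [] and uc == [0, 1, 2]

    def test_rectangular_leaves_surplus_unmatched(self):
        cost = np.array([[1.0, 10.0, 10.0], [10.0, 1.0, 10.0]])
        pairs, ur, uc = hungarian_assign(cost)
        assert set(pairs) == {(0, 0), (1, 1)} and uc == [2]

    def test_equal_cost_ties_resolved_lexicographically(self):
        pairs, _, _ = hungarian_assign(np.ones((3, 3)))
        assert pairs == [(0, 0), (1, 1), (2, 2)]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 7), st.integers(2, 7))
    def test_total_cost_matches_brute_force(self, seed, n_rows, n_cols):
        rng = np.random.default_rng(seed)
        cost = rng.uniform(0, 100, size=(n_rows, n_cols))
        pairs, _, _ = hungarian_assign(cost)
        total = sum(cost[i, j] for i, j in pairs)
        assert total == pytest.approx(brute_force_assignment(cost), abs=1e-9)


def detections_frame(rows):
    return pd.DataFrame(rows, columns=["frame", "x", "y", "prob"])


class TestLinkTracks:
    def cfg(self, **kw):
        base = dict(box_size=21, threshold_low=0, threshold_high=100)
        base.update(kw)
        return Config(**base)

    def test_stationary_detection_keeps_one_id(self):
        rows = [(f, 50.0, 60.0, 0.9) for f in range(30)]
        table = link_tracks(detections_frame(rows), self.cfg())
        assert len(table) == 30
        assert table["id"].nunique() == 1

    def test_two_separated_constant_velocity_tracks(self):
        rows = []
        for f in range(40):
            rows.append((f, 10.0 + 2.0 * f, 10.0, 0.9))
            rows.append((f, 10.0 + 2.0 * f, 400.0, 0.9))
        table = link_tracks(detections_frame(rows), self.cfg())
        assert table["id"].nunique() == 2
        for _, g in table.groupby("id"):
            assert g["y"].nunique() == 1  # no switches across the two lines
            assert len(g) == 40

    def test_gap_of_max_skipped_keeps_id_one_more_loses_it(self):
        cfg = self.cfg(max_skipped=3, min_track_length=1)
        for gap, expect_ids in ((3, 1), (4, 2)):
            rows = [(f, 50.0, 50.0, 0.9) for f in range(10)]
            rows += [(f, 50.0, 50.0, 0.9) for f in range(10 + gap, 25)]
            table = link_tracks(detections_frame(rows), cfg)
            assert table["id"].nunique() == expect_ids, f"gap={gap}"

    def test_short_tracks_pruned(self):
        rows = [(0, 10.0, 10.0, 0.9), (1, 10.0, 10.0, 0.9)]  # 2-frame flicker
        rows += [(f, 200.0, 200.0, 0.9) for f in range(20)]
        rows.sort(key=lambda r: r[0])
        table = link_tracks(detections_frame(rows), self.cfg(min_track_length=3))
        assert table["id"].nunique() == 1
        assert (table["x"] == 200.0).all()

    def test_unsorted_input_rejected(self):
        rows = [(1, 0.0, 0.0, 0.9), (0, 0.0, 0.0, 0.9)]
        with pytest.raises(ValueError, match="sorted"):
            link_tracks(detections_frame(rows), self.cfg())

    def test_id_conservation_and_uniqueness(self):
        rng = np.random.default_rng(4)
        rows = []
        for f in range(20):
            for _ in range(int(rng.integers(0, 4))):
                rows.append((f, float(rng.uniform(0, 500)),
                             float(rng.uniform(0, 500)), 0.9))
        table = link_tracks(detections_frame(rows), self.cfg(min_track_length=1))
        assert not table.duplicated(["frame", "id"]).any()
        # every output row corresponds to exactly one input detection
        assert len(table) <= len(rows)

    @pytest.mark.parametrize("n_animals", [2, 5, 10])
    def test_track_recovery_on_separated_animals(self, n_animals):
        scene = syn.SyntheticScene(width=1000, height=700, n_animals=n_animals,
                                   n_frames=60, speed=2.0, seed=17)
        cfg = self.cfg()
        truth = syn.generate_separated_trajectories(scene,
                                                    min_gap=2.5 * cfg.max_gate)
        dets = truth.rename(columns={"id": "tid"})
        dets = detections_frame(
            [(int(r["frame"]), r["x"], r["y"], 1.0) for _, r in dets.iterrows()])
        table = link_tracks(dets, cfg)
        assert table["id"].nunique() == n_animals
        # the truth id <-> tracker id mapping is constant over all frames
        merged = table.merge(truth, on=["frame", "x", "y"], suffixes=("_trk", "_gt"))
        assert len(merged) == len(truth)
        mapping = merged.groupby("id_gt")["id_trk"].nunique()
        assert (mapping == 1).all()


class TestOverlay:
    def test_empty_table_leaves_frames_unchanged(self):
        frames = [np.full((40, 40), 7, np.uint8)]
        out = trk.render_overlay(frames, pd.DataFrame(columns=["frame", "id", "x", "y"]),
                                 box_size=11)
        np.testing.assert_array_equal(out[0][..., 0], frames[0])

    def test_same_id_same_colour_across_frames(self):
        assert trk.id_color(3) == trk.id_color(3)
        assert trk.id_color(3) != trk.id_color(4)

    def test_box_drawn_around_track_position(self):
        frames = [np.zeros((60, 60), np.uint8)]
        table = pd.DataFrame([(0, 1, 30.0, 30.0)], columns=["frame", "id", "x", "y"])
        out = trk.render_overlay(frames, table, box_size=11)
        painted = np.argwhere((out[0] != 0).any(axis=-1))
        center = painted.mean(axis=0)
        assert abs(center[1] - 30) <= 2  # x centred; text above skews y slightly
        assert painted[:, 1].min() >= 30 - 6 and painted[:, 1].max() <= 30 + 6

    def test_track_beyond_video_rejected(self):
        frames = [np.zeros((40, 40), np.uint8)]
        table = pd.DataFrame([(5, 1, 10.0, 10.0)], columns=["frame", "id", "x", "y"])
        with pytest.raises(ValueError, match="beyond"):
            trk.render_overlay(frames, table, box_size=11)
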