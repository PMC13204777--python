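"""Mushroom-body stage: thresholding, linking, contrast SD, confirmation."""

import numpy as np
import pandas as pd
import pytest

from msod.mushroom_body import (
    Detection,
    Trajectory,
    attach_contrast,
    confirm_objects,
    contrast_sd,
    link_trajectories,
    threshold_detections,
)


def _dets(points):
    """[(frame, x, y)] grouped into the per-frame list structure."""
    T = max(p[0] for p in points) + 1
    out = [[] for _ in range(T)]
    for t, x, y in points:
        out[t].append(Detection(t, x, y, 1.0))
    return out


class TestThreshold:
    def test_empty_map(self):
        assert threshold_detections(np.zeros((2, 10, 10))) == [[], []]

    def test_single_peak(self):
        stack = np.zeros((1, 20, 20))
        stack[0, 7, 11] = 1.0
        (dets,) = threshold_detections(stack, th=0.2)
        assert len(dets) == 1 and (dets[0].x, dets[0].y) == (11, 7)

    def test_two_distant_maxima_survive_nms(self):
        stack = np.zeros((1, 30, 40))
        stack[0, 15, 10] = 1.0
        stack[0, 15, 22] = 1.0  # 12 px apart, NMS window 5: both kept
        (dets,) = threshold_detections(stack, th=0.2, nms_window=5)
        assert len(dets) == 2

    def test_close_maxima_suppressed(self):
        stack = np.zeros((1, 30, 40))
        stack[0, 15, 10] = 1.0
        stack[0, 15, 12] = 0.9
        (dets,) = threshold_detections(stack, th=0.2, nms_window=5)
        assert len(dets) == 1 and dets[0].x == 10

    def test_border_margin_excludes_edges(self):
        stack = np.zeros((1, 30, 30))
        stack[0, 2, 2] = 1.0
        stack[0, 15, 15] = 0.5
        (dets,) = threshold_detections(stack, th=0.2, border_margin=10)
        assert [(d.x, d.y) for d in dets] == [(15, 15)]

    def test_normalization_scale_free(self):
        stack = np.zeros((1, 20, 20))
        stack[0, 10, 10] = 1e-6  # tiny absolute scale still detected
        (dets,) = threshold_detections(stack, th=0.2, normalize=True)
        assert len(dets) == 1


class TestLinking:
    def test_nearby_detections_link(self):
        trajs = link_trajectories(_dets([(0, 100, 50), (1, 105, 52)]), link_radius=10)
        assert len(trajs) == 1 and len(trajs[0]) == 2

    def test_distant_detections_stay_separate(self):
        trajs = link_trajectories(_dets([(0, 100, 50), (1, 150, 50)]), link_radius=10)
        assert sorted(len(t) for t in trajs) == [1, 1]

    def test_equidistant_tie_goes_to_older_trajectory(self):
        # two one-point trajectories, one new detection equidistant to both
        dets = _dets([(0, 100, 50), (0, 110, 50), (1, 105, 50)])
        trajs = link_trajectories(dets, link_radius=10)
        assert trajs[0].frames == [0, 1]  # creation index 0 wins the tie
        assert trajs[1].frames == [0]

    def test_gap_tolerance(self):
        pts = _dets([(0, 100, 50), (2, 104, 50)])
        assert len(link_trajectories(pts, link_radius=10, gap_max=0)) == 2
        assert len(link_trajectories(pts, link_radius=10, gap_max=1)) == 1

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        dets = [
            [Detection(t, int(rng.integers(0, 50)), int(rng.integers(0, 50)), 1.0)
             for _ in range(3)]
            for t in range(6)
        ]
        trajs = link_trajectories(dets, link_radius=8)
        assert sum(len(t) for t in trajs) == sum(len(d) for d in dets)


class TestContrastSeries:
    def _traj(self, frames, xs, ys):
        tr = Trajectory(traj_id=0)
        tr.frames, tr.xs, tr.ys = list(frames), list(xs), list(ys)
        tr.scores = [1.0] * len(tr.frames)
        return tr

    def test_attach_constant_field(self):
        tr = self._traj([0, 1, 2], [3, 4, 5], [6, 6, 6])
        attach_contrast(tr, np.full((3, 10, 10), 7.0))
        assert np.array_equal(tr.ct, [7.0, 7.0, 7.0])

    def test_attach_out_of_bounds(self):
        tr = self._traj([0], [99], [0])
        with pytest.raises(IndexError):
            attach_contrast(tr, np.zeros((1, 10, 10)))

    def test_sd_constant_series_zero(self):
        tr = self._traj([0, 1, 2], [0, 0, 0], [0, 0, 0])
        tr.ct = np.array([5.0, 5.0, 5.0])
        contrast_sd(tr)
        assert np.allclose(tr.sd, 0.0)

    def test_sd_worked_example(self):
        tr = self._traj(range(4), [0] * 4, [0] * 4)
        tr.ct = np.array([0.0, 10.0, 20.0, 30.0])
        contrast_sd(tr)
        assert tr.sd[3] == pytest.approx(12.910, abs=1e-3)
        assert tr.sd[0] == 0.0

    def test_sd_single_point(self):
        tr = self._traj([0], [0], [0])
        tr.ct = np.array([3.0])
        contrast_sd(tr)
        assert np.array_equal(tr.sd, [0.0])

    def test_sd_matches_numpy_cumulative(self):
        rng = np.random.default_rng(4)
        tr = self._traj(range(20), [0] * 20, [0] * 20)
        tr.ct = rng.normal(size=20)
        contrast_sd(tr)
        expect = [0.0] + [np.std(tr.ct[: i + 1], ddof=1) for i in range(1, 20)]
        assert np.allclose(tr.sd, expect, atol=1e-9)


class TestConfirmation:
    def _noisy_traj(self, tid=0, n=10, spread=10.0, seed=0):
        tr = Trajectory(traj_id=tid)
        tr.frames = list(range(n))
        tr.xs = [5] * n
        tr.ys = [5] * n
        tr.scores = [1.0] * n
        rng = np.random.default_rng(seed)
        tr.ct = rng.normal(0.0, spread, n)
        return contrast_sd(tr)

    def test_flat_trajectory_never_confirmed(self):
        tr = self._noisy_traj(spread=0.0)
        out = confirm_objects([tr], th2=4.0)
        assert out.empty and tr.status == "rejected"

    def test_variable_trajectory_confirmed(self):
        tr = self._noisy_traj(spread=10.0)
        out = confirm_objects([tr], th2=4.0)
        assert not out.empty and tr.status == "confirmed"

    def test_min_length_gate(self):
        tr = self._noisy_traj(n=2, spread=100.0)
        assert confirm_objects([tr], th2=0.001, min_length=3).empty

    def test_tiny_threshold_confirms_any_noise(self):
        tr = self._noisy_traj(spread=1.0)
        assert not confirm_objects([tr], th2=1e-9).empty

    def test_monotone_in_th2(self):
        trajs = [self._noisy_traj(tid=i, seed=i) for i in range(5)]
        sizes = []
        for th2 in (0.5, 2.0, 8.0, 32.0):
            sizes.append(len(confirm_objects(trajs, th2=th2)))
        assert sizes == sorted(sizes, reverse=True)

    def test_rejects_nonpositive_th2(self):
        with pytest.raises(ValueError):
            confirm_objects([], th2=0.0)
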