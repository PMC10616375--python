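"""Flow-field targets and instance recovery by gradient tracking."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse

from henuclei.flow_postprocess import (
    FlowField,
    assign_types,
    cluster_terminals,
    compute_flow_targets,
    follow_flows,
    remove_small,
)
from henuclei.panoptic_eval import match_instances, panoptic_quality


def _disk_map(center, radius, shape=(64, 64), label=1, base=None):
    lab = np.zeros(shape, dtype=np.int32) if base is None else base
    rr, cc = disk(center, radius, shape=shape)
    lab[rr, cc] = label
    return lab


class TestComputeFlowTargets:
    def test_empty_map_gives_zero_fields(self):
        ff = compute_flow_targets(np.zeros((32, 32), dtype=int))
        assert not ff.dist.any() and not ff.flow.any()

    def test_disk_distance_peaks_at_center(self):
        lab = _disk_map((32, 32), 15)
        ff = compute_flow_targets(lab)
        peak = np.unravel_index(np.argmax(ff.dist), ff.dist.shape)
        assert abs(ff.dist.max() - 15) <= 1  # EDT max ~ radius
        assert np.hypot(peak[0] - 32, peak[1] - 32) <= 1.5

    def test_disk_flow_points_inward(self):
        lab = _disk_map((32, 32), 15)
        ff = compute_flow_targets(lab)
        ys, xs = np.nonzero(lab)
        dy, dx = 32 - ys, 32 - xs
        rad = np.hypot(dy, dx)
        sel = rad > 2
        cos = (ff.flow[0, ys[sel], xs[sel]] * dy[sel] / rad[sel]
               + ff.flow[1, ys[sel], xs[sel]] * dx[sel] / rad[sel])
        assert cos.mean() > 0.95

    def test_flow_zero_on_background_unit_on_foreground(self, default_scene):
        ff = compute_flow_targets(default_scene.instances)
        norm = np.hypot(ff.flow[0], ff.flow[1])
        assert np.all(norm[default_scene.instances == 0] == 0)
        fg_norm = norm[default_scene.instances > 0]
        assert np.allclose(fg_norm[fg_norm > 0], 1.0, atol=1e-3)


class TestFollowFlows:
    def test_zero_flow_leaves_pixels_in_place(self):
        fg = np.zeros((16, 16), dtype=bool)
        fg[4:8, 4:8] = True
        ff = FlowField(dist=np.zeros((16, 16)), flow=np.zeros((2, 16, 16)))
        term = follow_flows(ff, fg)
        yy, xx = np.mgrid[0:16, 0:16]
        assert np.array_equal(term[0], yy) and np.array_equal(term[1], xx)

    def test_disk_pixels_terminate_near_center(self):
        lab = _disk_map((32, 32), 15)
        ff = compute_flow_targets(lab)
        term = follow_flows(ff, lab > 0)
        ys, xs = np.nonzero(lab)
        d = np.hypot(term[0, ys, xs] - 32, term[1, ys, xs] - 32)
        assert (d < 3).mean() >= 0.99

    def test_two_disks_do_not_cross(self):
        lab = _disk_map((16, 16), 9)
        lab = _disk_map((48, 48), 9, base=lab, label=2)
        ff = compute_flow_targets(lab)
        term = follow_flows(ff, lab > 0)
        for label, (cy, cx) in [(1, (16, 16)), (2, (48, 48))]:
            ys, xs = np.nonzero(lab == label)
            d = np.hypot(term[0, ys, xs] - cy, term[1, ys, xs] - cx)
            other = np.hypot(term[0, ys, xs] - (64 - cy), term[1, ys, xs] - (64 - cx))
            assert d.max() < 6 and other.min() > 20


class TestClusterTerminals:
    def test_single_disk_recovered_as_one_instance(self):
        lab = _disk_map((32, 32), 12)
        ff = compute_flow_targets(lab)
        term = follow_flows(ff, lab > 0)
        out = cluster_terminals(term, lab > 0)
        assert out.max() == 1
        assert np.array_equal(out > 0, lab > 0)

    def test_touching_ellipses_split_with_good_iou(self):
        lab = np.zeros((64, 96), dtype=np.int32)
        rr, cc = ellipse(32, 30, 14, 18, shape=lab.shape)
        lab[rr, cc] = 1
        rr, cc = ellipse(32, 62, 14, 18, shape=lab.shape)
        lab[rr, cc] = 2  # touches / slightly overlaps instance 1
        ff = compute_flow_targets(lab)
        term = follow_flows(ff, lab > 0)
        out = cluster_terminals(term, lab > 0)
        assert out.max() == 2
        for pred_lab in (1, 2):
            ious = []
            for gt_lab in (1, 2):
                p = out == pred_lab
                g = lab == gt_lab
                ious.append((p & g).sum() / (p | g).sum())
            assert max(ious) > 0.8

    def test_empty_foreground_gives_empty_labeling(self):
        term = follow_flows(
            FlowField(np.zeros((8, 8)), np.zeros((2, 8, 8))), np.zeros((8, 8), bool)
        )
        out = cluster_terminals(term, np.zeros((8, 8), bool))
        assert out.max() == 0

    def test_partition_every_fg_pixel_labeled_once(self, default_scene):
        ff = compute_flow_targets(default_scene.instances)
        fg = default_scene.instances > 0
        out = cluster_terminals(follow_flows(ff, fg), fg)
        assert np.array_equal(out > 0, fg)


class TestRoundTrip:
    def test_gt_flow_round_trip_reaches_high_pq(self, default_scene):
        """Instances recovered from their own flow targets score PQ >= 0.95."""
        gt = default_scene.instances
        fg = gt > 0
        ff = compute_flow_targets(gt)
        inst = remove_small(cluster_terminals(follow_flows(ff, fg), fg))
        ones_p = {int(l): 1 for l in np.unique(inst) if l > 0}
        ones_g = {int(l): 1 for l in np.unique(gt) if l > 0}
        res = panoptic_quality(
            match_instances(inst, ones_p, gt, ones_g, class_aware=False)
        )["all"]
        assert res.pq >= 0.95

    def test_deterministic(self, default_scene):
        fg = default_scene.instances > 0
        ff = compute_flow_targets(default_scene.instances)
        a = cluster_terminals(follow_flows(ff, fg), fg)
        b = cluster_terminals(follow_flows(ff, fg), fg)
        assert np.array_equal(a, b)


class TestGiantNuclei:
    def test_giant_nucleus_detected_possibly_fragmented(self):
        """A very large nucleus may split into several detections (a known
        failure mode of flow-based post-processing), but is never lost."""
        lab = np.zeros((160, 160), dtype=np.int32)
        rr, cc = ellipse(80, 80, 60, 28, shape=lab.shape, rotation=0.4)
        lab[rr, cc] = 1
        ff = compute_flow_targets(lab)
        fg = lab > 0
        inst = remove_small(cluster_terminals(follow_flows(ff, fg), fg))
        assert inst.max() >= 1
        # every recovered piece lies inside the giant nucleus
        assert not np.any((inst > 0) & ~fg)


class TestAssignTypes:
    def _probs(self, weights, shape=(8, 8)):
        p = np.zeros((6, *shape))
        for ci, w in weights.items():
            p[ci] = w
        return p / p.sum(axis=0, keepdims=True)

    def test_one_hot_probabilities(self):
        inst = np.zeros((8, 8), dtype=int)
        inst[2:6, 2:6] = 1
        probs = self._probs({1: 1.0})
        assert assign_types(inst, probs) == {1: 1}

    def test_majority_vote_on_mixed_pixels(self):
        inst = np.zeros((8, 10), dtype=int)
        inst[:, :10] = 1
        probs = np.zeros((6, 8, 10))
        probs[2, :, :6] = 1.0  # 60% of pixels class 2
        probs[3, :, 6:] = 1.0  # 40% class 3
        assert assign_types(inst, probs) == {1: 2}

    def test_exact_tie_breaks_to_lowest_class_index(self):
        inst = np.zeros((8, 8), dtype=int)
        inst[2:6, 2:6] = 1
        probs = self._probs({1: 0.5, 3: 0.5})
        assert assign_types(inst, probs) == {1: 1}


class TestRemoveSmall:
    def test_large_instances_untouched(self):
        lab = _disk_map((20, 20), 8)
        lab = _disk_map((45, 45), 8, base=lab, label=2)
        out = remove_small(lab, min_area=10)
        assert np.array_equal(out, lab)

    def test_speck_removed_entirely(self):
        lab = np.zeros((16, 16), dtype=int)
        lab[3:5, 3:5] = 1  # 4 px
        assert remove_small(lab, min_area=10).max() == 0

    def test_mixed_sizes_drop_count_matches(self):
        lab = np.zeros((64, 64), dtype=np.int32)
        lab[0:1, 0:4] = 1  # 4 px speck
        rr, cc = disk((20, 20), 6)
        lab[rr, cc] = 2
        lab[40:41, 40:43] = 3  # 3 px speck
        rr, cc = disk((50, 12), 5)
        lab[rr, cc] = 4
        out = remove_small(lab, min_area=10)
        assert out.max() == 2  # 2 small instances removed, survivors relabeled 1..2
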