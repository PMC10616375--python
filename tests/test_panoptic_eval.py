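"""Instance matching, DQ/SQ/PQ, and bootstrap CIs.

The matcher is checked against an exhaustive oracle that enumerates every
one-to-one assignment of candidate pairs and maximises (TP count, summed
IoU); IoUs for the oracle are recomputed naively from boolean masks.
"""

import numpy as np
import pytest

from henuclei.panoptic_eval import (
    bootstrap_metrics,
    match_instances,
    panoptic_quality,
)


# ---------------------------------------------------------------------------
# oracle helpers (independent of the implementation under test)
# ---------------------------------------------------------------------------


def naive_ious(pred, gt):
    out = {}
    for p in np.unique(pred[pred > 0]):
        for g in np.unique(gt[gt > 0]):
            pm, gm = pred == p, gt == g
            inter = (pm & gm).sum()
            if inter:
                out[(int(p), int(g))] = inter / (pm | gm).sum()
    return out


def oracle_match(pred, pcls, gt, gcls, thr=0.5, class_aware=True):
    """Brute-force optimal assignment: maximise TP, then total IoU."""
    cand = [
        ((p, g), i)
        for (p, g), i in naive_ious(pred, gt).items()
        if i > thr and (not class_aware or pcls[p] == gcls[g])
    ]
    best = [0, 0.0]

    def rec(k, used_p, used_g, tp, s):
        if [tp, s] > best:
            best[0], best[1] = tp, s
        if k == len(cand):
            return
        rec(k + 1, used_p, used_g, tp, s)
        (p, g), i = cand[k]
        if p not in used_p and g not in used_g:
            rec(k + 1, used_p | {p}, used_g | {g}, tp + 1, s + i)

    rec(0, set(), set(), 0, 0.0)
    return best[0], best[1]


def random_typed_map(rng, n_max=8, shape=(64, 64)):
    lab = np.zeros(shape, dtype=np.int32)
    n = int(rng.integers(0, n_max + 1))
    for i in range(1, n + 1):
        r, c = rng.integers(8, shape[0] - 8, 2)
        rad = int(rng.integers(3, 9))
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        lab[(yy - r) ** 2 + (xx - c) ** 2 <= rad**2] = i
    present = [int(v) for v in np.unique(lab) if v > 0]
    cls = {v: int(rng.integers(1, 6)) for v in present}
    # relabel to consecutive ids
    remap = {v: i + 1 for i, v in enumerate(present)}
    out = np.zeros_like(lab)
    for v, i in remap.items():
        out[lab == v] = i
    return out, {remap[v]: cls[v] for v in present}


def two_strip_fixture():
    """TP=2 with IoUs 0.8 and 0.6, plus one FP and one FN."""
    gt = np.zeros((40, 60), dtype=np.int32)
    pred = np.zeros_like(gt)
    gt[0:9, 0:10] = 1       # 90 px
    pred[1:10, 0:10] = 1    # 90 px, inter 80, union 100 -> IoU 0.8
    gt[0:8, 20:30] = 2      # 80 px
    pred[2:10, 20:30] = 2   # 80 px, inter 60, union 100 -> IoU 0.6
    pred[20:30, 40:50] = 3  # FP
    gt[25:35, 0:10] = 3     # FN
    ones = {1: 1, 2: 1, 3: 1}
    return pred, ones, gt, ones


class TestMatchInstances:
    def test_identical_maps_all_tp_iou_one(self, default_scene):
        m = match_instances(
            default_scene.instances,
            default_scene.classes,
            default_scene.instances,
            default_scene.classes,
        )
        total_tp = sum(cm.tp for cm in m.per_class.values())
        assert total_tp == len(default_scene.classes)
        assert all(iou == 1.0 for cm in m.per_class.values() for iou in cm.ious)
        assert all(cm.fp == cm.fn == 0 for cm in m.per_class.values())

    def test_missing_prediction_counts_fn(self):
        gt = np.zeros((64, 64), dtype=np.int32)
        for i, c in enumerate((12, 32, 52), start=1):
            yy, xx = np.mgrid[:64, :64]
            gt[(yy - c) ** 2 + (xx - 32) ** 2 <= 36] = i
        pred = np.where(gt == 3, 0, gt)
        cls = {1: 1, 2: 1, 3: 1}
        m = match_instances(pred, {1: 1, 2: 1}, gt, cls, class_aware=False)
        cm = m.per_class["all"]
        assert (cm.tp, cm.fp, cm.fn) == (2, 0, 1)

    def test_iou_exactly_half_is_not_a_match(self):
        # two 6x4 strips shifted by 2 rows: |I| = 16, |U| = 32, IoU = 0.5 exactly
        gt = np.zeros((10, 10), dtype=np.int32)
        pred = np.zeros_like(gt)
        gt[0:6, 0:4] = 1
        pred[2:8, 0:4] = 1
        assert naive_ious(pred, gt)[(1, 1)] == 0.5
        m = match_instances(pred, {1: 1}, gt, {1: 1}, class_aware=False)
        cm = m.per_class["all"]
        assert (cm.tp, cm.fp, cm.fn) == (0, 1, 1)

    def test_class_mismatch_blocks_match_when_aware(self):
        gt = np.zeros((12, 12), dtype=np.int32)
        gt[2:10, 2:10] = 1
        pred = gt.copy()
        aware = match_instances(pred, {1: 2}, gt, {1: 1}, class_aware=True)
        agnostic = match_instances(pred, {1: 2}, gt, {1: 1}, class_aware=False)
        assert sum(cm.tp for cm in aware.per_class.values()) == 0
        assert agnostic.per_class["all"].tp == 1

    def test_class_subset_excludes_instances_entirely(self):
        gt = np.zeros((20, 40), dtype=np.int32)
        gt[2:10, 2:10] = 1   # neoplastic
        gt[2:10, 20:28] = 2  # dead, to be excluded
        pred = np.where(gt == 1, 1, 0)
        m = match_instances(
            pred, {1: 1}, gt, {1: 1, 2: 4},
            class_subset=("neoplastic", "inflammatory", "connective", "epithelial"),
        )
        assert sum(cm.fn for cm in m.per_class.values()) == 0  # dead gt not counted as FN
        assert sum(cm.tp for cm in m.per_class.values()) == 1

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="canvas"):
            match_instances(np.zeros((4, 4), int), {}, np.zeros((5, 5), int), {})

    def test_matches_exhaustive_oracle_on_random_maps(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            pred, pcls = random_typed_map(rng)
            gt, gcls = random_typed_map(rng)
            m = match_instances(pred, pcls, gt, gcls)
            tp = sum(cm.tp for cm in m.per_class.values())
            s = sum(sum(cm.ious) for cm in m.per_class.values())
            otp, os_ = oracle_match(pred, pcls, gt, gcls)
            assert tp == otp
            assert s == pytest.approx(os_, abs=1e-12)


class TestPanopticQuality:
    def test_perfect_prediction_all_ones(self, default_scene):
        m = match_instances(
            default_scene.instances, default_scene.classes,
            default_scene.instances, default_scene.classes, class_aware=False,
        )
        r = panoptic_quality(m)["all"]
        assert (r.dq, r.sq, r.pq) == (1.0, 1.0, 1.0)

    def test_worked_arithmetic_case(self):
        """TP=2 (IoUs 0.8, 0.6), FP=1, FN=1 -> DQ=2/3, SQ=0.7, PQ=7/15."""
        pred, pcls, gt, gcls = two_strip_fixture()
        m = match_instances(pred, pcls, gt, gcls, class_aware=False)
        cm = m.per_class["all"]
        assert (cm.tp, cm.fp, cm.fn) == (2, 1, 1)
        assert sorted(cm.ious) == [0.6, 0.8]
        r = panoptic_quality(m)["all"]
        assert r.dq == pytest.approx(2 / 3, abs=1e-12)
        assert r.sq == pytest.approx(0.7, abs=1e-12)
        assert r.pq == pytest.approx(7 / 15, abs=1e-12)

    def test_pq_equals_dq_times_sq(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pred, pcls = random_typed_map(rng)
            gt, gcls = random_typed_map(rng)
            for r in panoptic_quality(match_instances(pred, pcls, gt, gcls)).values():
                if r.defined:
                    assert abs(r.pq - r.dq * r.sq) < 1e-12

    def test_empty_class_reported_undefined_not_zero(self):
        m = match_instances(np.zeros((8, 8), int), {}, np.zeros((8, 8), int), {})
        for r in panoptic_quality(m).values():
            assert r.dq is None and r.sq is None and r.pq is None
            assert not r.defined

    def test_swapping_pred_and_gt_swaps_fp_fn(self):
        rng = np.random.default_rng(3)
        pred, pcls = random_typed_map(rng, n_max=6)
        gt, gcls = random_typed_map(rng, n_max=6)
        a = panoptic_quality(match_instances(pred, pcls, gt, gcls, class_aware=False))["all"]
        b = panoptic_quality(match_instances(gt, gcls, pred, pcls, class_aware=False))["all"]
        assert (a.fp, a.fn) == (b.fn, b.fp)
        assert a.sq == b.sq

    def test_adding_pure_fp_never_increases_dq_or_pq(self):
        pred, pcls, gt, gcls = two_strip_fixture()
        base = panoptic_quality(match_instances(pred, pcls, gt, gcls, class_aware=False))["all"]
        pred2 = pred.copy()
        pred2[32:38, 50:56] = 4
        pcls2 = {**pcls, 4: 1}
        more = panoptic_quality(match_instances(pred2, pcls2, gt, gcls, class_aware=False))["all"]
        assert more.dq < base.dq and more.pq < base.pq


def jittered_roi(seed):
    """A heterogeneous ROI: prediction = ground truth with per-instance
    jitter and occasional misses, giving a spread of IoUs and FNs."""
    rng = np.random.default_rng(seed)
    gt, gcls = random_typed_map(rng, n_max=8)
    pred = np.zeros_like(gt)
    pcls = {}
    for lab in np.unique(gt[gt > 0]):
        if rng.uniform() < 0.15:
            continue  # missed detection
        dy, dx = rng.integers(-2, 3, 2)
        shifted = np.roll(np.roll(gt == lab, dy, axis=0), dx, axis=1)
        pred[shifted] = lab
        pcls[int(lab)] = gcls[int(lab)]
    return match_instances(pred, pcls, gt, gcls, class_aware=False)


class TestBootstrap:
    def _roi(self, seed):
        return jittered_roi(seed)

    def test_identical_rois_zero_width_ci(self):
        pred, pcls, gt, gcls = two_strip_fixture()
        roi = match_instances(pred, pcls, gt, gcls, class_aware=False)
        cis = bootstrap_metrics([roi] * 5, n_rounds=200, seed=1)
        for metric in ("dq", "sq", "pq"):
            ci = cis["all"][metric]
            assert ci.lower == ci.upper == ci.point

    def test_fixed_seed_reproduces_cis(self):
        rois = [self._roi(s) for s in range(10)]
        a = bootstrap_metrics(rois, n_rounds=200, seed=9)
        b = bootstrap_metrics(rois, n_rounds=200, seed=9)
        assert a["all"]["pq"].lower == b["all"]["pq"].lower
        assert a["all"]["pq"].upper == b["all"]["pq"].upper

    def test_ci_width_shrinks_with_more_rois(self):
        rois = [self._roi(s) for s in range(20)]
        narrow = bootstrap_metrics(rois * 4, n_rounds=200, seed=2)
        wide = bootstrap_metrics(rois, n_rounds=200, seed=2)
        for metric in ("dq", "pq"):
            w_wide = wide["all"][metric].upper - wide["all"][metric].lower
            w_narrow = narrow["all"][metric].upper - narrow["all"][metric].lower
            assert w_narrow < w_wide

    def test_too_few_rois_or_rounds_rejected(self):
        roi = self._roi(0)
        with pytest.raises(ValueError):
            bootstrap_metrics([roi], n_rounds=10, seed=0)
        with pytest.raises(ValueError):
            bootstrap_metrics([roi, roi], n_rounds=0, seed=0)
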