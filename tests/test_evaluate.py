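"""Reference evaluation: formulas, exclusions, oracle equivalence."""

import numpy as np
import pytest

from airtree import (
    BinaryMask,
    DataError,
    branch_detection,
    corrupt_segmentation,
    evaluate_segmentation,
    false_positive_rate,
    leakage_stats,
    overlap_counts,
    tree_length_detected,
)
from eval_oracle import (
    o_branch_detection,
    o_false_positive_rate,
    o_leakage_stats,
    o_overlap_counts,
    o_tree_length_detected,
    random_reference_case,
)


class TestFormulas:
    @pytest.mark.parametrize("nc,nw,expected", [
        (99, 1, 1.0), (100, 0, 0.0), (930, 70, 7.0)])
    def test_false_positive_rate(self, nc, nw, expected):
        assert false_positive_rate(nc, nw) == pytest.approx(expected)

    def test_empty_after_exclusions(self):
        with pytest.raises(DataError, match="empty segmentation"):
            false_positive_rate(0, 0)


class TestOverlapCounts:
    def test_perfect_segmentation(self, phantom4):
        ref = phantom4.labels
        nc, nw = overlap_counts(phantom4.lumen_mask, ref)
        excl = ref.trachea_mask.data | ref.main_bronchi_mask.data
        assert nw == 0
        assert nc == int((ref.correct_mask & ~excl).sum())

    def test_segmentation_inside_unknown_counts_nothing(self, phantom4):
        ref = phantom4.labels
        seg = phantom4.lumen_mask.like(ref.unknown_mask.copy())
        nc, nw = overlap_counts(seg, ref)
        assert nc == 0 and nw == 0

    def test_constructed_leaks_counted_as_wrong(self, phantom4):
        seg = corrupt_segmentation(phantom4, 99, leak_blobs=3,
                                   leak_voxels_each=10, seed=2)
        _, nw = overlap_counts(seg, phantom4.labels)
        assert nw == 30

    def test_dimension_mismatch(self, phantom4):
        small = BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(DataError):
            overlap_counts(small, phantom4.labels)


class TestBranchDetection:
    def test_identity(self, phantom4):
        nseg, nref, pct = branch_detection(phantom4.tree, phantom4.labels,
                                           phantom4.tree)
        assert nseg == nref == 14  # 15 branches minus the trachea
        assert pct == pytest.approx(100.0)

    def test_truncated_tree(self, phantom4):
        sub = phantom4.tree.subtree_to_generation(3)
        nseg, nref, pct = branch_detection(sub, phantom4.labels, phantom4.tree)
        assert (nseg, nref) == (6, 14)
        assert pct == pytest.approx(100.0 * 6 / 14)

    def test_empty_candidate_tree(self, phantom4):
        from airtree import CenterlineTree
        nseg, nref, pct = branch_detection(CenterlineTree([]), phantom4.labels,
                                           phantom4.tree)
        assert nseg == 0 and pct == 0.0


class TestTreeLength:
    def test_full_coverage(self, phantom4):
        lseg, lref, pct = tree_length_detected(phantom4.lumen_mask,
                                               phantom4.tree, phantom4.labels)
        assert pct == pytest.approx(100.0)
        assert lseg == pytest.approx(lref)

    def test_half_arclength_coverage(self, phantom4):
        """A mask covering the proximal half of every non-trachea branch
        detects 50% of the tree length (up to one inter-point spacing)."""
        ref = phantom4.labels
        seg = np.zeros(ref.shape, bool)
        step = 0.0
        for b in phantom4.tree.branches:
            pts = b.points
            cum = np.concatenate([[0], np.cumsum(
                np.linalg.norm(np.diff(pts, axis=0), axis=1))])
            half = pts[cum <= b.length_mm / 2.0 + 1e-9]
            idx = ref.world_to_index(half)
            seg[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            step = max(step, np.diff(cum).max())
        lseg, lref, pct = tree_length_detected(
            phantom4.lumen_mask.like(seg), phantom4.tree, ref)
        slack = 100.0 * 14 * step / (lref * 10.0)
        assert pct == pytest.approx(50.0, abs=max(slack, 1.0))

    def test_empty_segmentation_zero_pct(self, phantom4):
        empty = phantom4.lumen_mask.like(np.zeros(phantom4.labels.shape, bool))
        _, _, pct = tree_length_detected(empty, phantom4.tree, phantom4.labels)
        assert pct == 0.0


class TestLeakage:
    def test_no_leak_when_inside_correct_or_unknown(self, phantom4):
        ref = phantom4.labels
        seg = phantom4.lumen_mask.like(ref.correct_mask | ref.unknown_mask)
        assert leakage_stats(seg, ref) == (0, 0.0)

    def test_corner_adjacent_blobs_merge(self, phantom4):
        ref = phantom4.labels
        wrongs = np.argwhere(ref.wrong_mask)
        # two single-voxel blobs sharing only a corner are 26-adjacent
        base = None
        for v in wrongs:
            w = v + 1
            if (w < ref.shape).all() and ref.wrong_mask[tuple(w)]:
                base = v
                break
        seg = np.zeros(ref.shape, bool)
        seg[tuple(base)] = seg[tuple(base + 1)] = True
        count, _ = leakage_stats(phantom4.lumen_mask.like(seg), ref)
        assert count == 1


class TestEvaluateSegmentation:
    def test_self_evaluation_identity(self, phantom4):
        r = evaluate_segmentation(phantom4.lumen_mask, phantom4.tree,
                                  phantom4.labels, phantom4.tree)
        assert r.branch_detected_pct == pytest.approx(100.0)
        assert r.tree_length_pct == pytest.approx(100.0)
        assert r.false_positive_rate_pct == 0.0
        assert r.leakage_count == 0 and r.leakage_volume_mm3 == 0.0

    def test_corrupt_case_composes(self, phantom4):
        seg = corrupt_segmentation(phantom4, 3, leak_blobs=3,
                                   leak_voxels_each=10, seed=3)
        sub = phantom4.tree.subtree_to_generation(3)
        r = evaluate_segmentation(seg, sub, phantom4.labels, phantom4.tree)
        assert r.branch_detected_pct == pytest.approx(100 * 6 / 14)
        assert r.leakage_count == 3
        assert r.n_wrong_voxels == 30

    def test_empty_segmentation_errors(self, phantom4):
        from airtree import CenterlineTree
        empty = phantom4.lumen_mask.like(np.zeros(phantom4.labels.shape, bool))
        with pytest.raises(DataError):
            evaluate_segmentation(empty, CenterlineTree([]), phantom4.labels,
                                  phantom4.tree)

    def test_trachea_voxels_do_not_change_metrics(self, phantom4):
        seg = corrupt_segmentation(phantom4, 3, 0)
        flipped = phantom4.lumen_mask.like(
            seg.data ^ phantom4.labels.trachea_mask.data)
        sub = phantom4.tree.subtree_to_generation(3)
        a = evaluate_segmentation(seg, sub, phantom4.labels, phantom4.tree)
        b = evaluate_segmentation(flipped, sub, phantom4.labels, phantom4.tree)
        assert (a.false_positive_rate_pct, a.branch_detected_pct,
                a.leakage_count) == (b.false_positive_rate_pct,
                                     b.branch_detected_pct, b.leakage_count)

    def test_adding_correct_voxels_is_monotone(self, phantom4):
        rng = np.random.default_rng(4)
        seg = corrupt_segmentation(phantom4, 3, 0)
        add = phantom4.labels.correct_mask & ~seg.data \
            & (rng.random(phantom4.labels.shape) < 0.5)
        bigger = phantom4.lumen_mask.like(seg.data | add)
        sub = phantom4.tree.subtree_to_generation(3)
        a = evaluate_segmentation(seg, sub, phantom4.labels, phantom4.tree)
        b = evaluate_segmentation(bigger, sub, phantom4.labels, phantom4.tree)
        assert b.tree_length_pct >= a.tree_length_pct
        assert b.false_positive_rate_pct <= a.false_positive_rate_pct


class TestBruteForceEquivalence:
    def test_random_small_grids_match_oracle(self):
        rng = np.random.default_rng(12345)
        for _ in range(10):
            seg, seg_tree, ref, ref_tree = random_reference_case(rng)
            assert overlap_counts(seg, ref) == o_overlap_counts(seg, ref)
            nc, nw = overlap_counts(seg, ref)
            if nc + nw:
                assert false_positive_rate(nc, nw) == pytest.approx(
                    o_false_positive_rate(nc, nw))
            assert branch_detection(seg_tree, ref, ref_tree) == \
                o_branch_detection(seg_tree, ref, ref_tree)
            a = tree_length_detected(seg, ref_tree, ref)
            b = o_tree_length_detected(seg, ref_tree, ref)
            assert a == pytest.approx(b)
            assert leakage_stats(seg, ref)[0] == o_leakage_stats(seg, ref)[0]
            assert leakage_stats(seg, ref)[1] == pytest.approx(
                o_leakage_stats(seg, ref)[1])
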