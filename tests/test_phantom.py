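"""Phantom generator: geometry, ground truth, determinism, corruption."""

import numpy as np
import pytest

from airtree import (
    AirtreeError,
    ParameterError,
    PhantomSpec,
    corrupt_segmentation,
    generate_phantom,
)
from airtree.phantom import _branch_axes
from airtree.tree_metrics import branches_per_generation
from airtree.tree import validate_tree


class TestGeometry:
    def test_single_generation_is_one_tube(self, phantom1):
        h = branches_per_generation(phantom1.tree)
        assert h.counts == {1: 1}
        assert h.max_generation == 1

    def test_full_binary_tree_counts(self, phantom4):
        h = branches_per_generation(phantom4.tree)
        assert h.counts == {1: 1, 2: 2, 3: 4, 4: 8}
        assert h.total_branches == 15

    def test_radius_taper(self):
        spec = PhantomSpec(generations=3)
        assert spec.radius(3) == pytest.approx(9.0 * 0.7 ** 2)

    def test_unresolvable_tube_rejected(self):
        with pytest.raises(ParameterError, match="generation 6"):
            PhantomSpec(generations=6, spacing_mm=(1.0, 1.0, 1.0))

    def test_branch_lengths_match_construction(self, phantom3):
        spec = phantom3.spec
        for b in phantom3.tree.branches:
            assert b.length_mm == pytest.approx(spec.length(b.generation),
                                                abs=min(spec.spacing_mm) / 2)

    def test_lumen_volume_close_to_analytic_union(self, phantom3):
        """Voxelized lumen volume vs the capsule union sampled at subvoxel
        resolution (independent geometric oracle)."""
        spec = phantom3.spec
        axes = _branch_axes(spec)
        vol = phantom3.volume
        lo = np.asarray(vol.origin)
        fine = 0.25
        shape = (np.asarray(vol.shape) * np.asarray(vol.spacing) / fine).astype(int)
        zz = (np.arange(shape[0]) * fine + lo[0])[:, None, None]
        yy = (np.arange(shape[1]) * fine + lo[1])[None, :, None]
        xx = (np.arange(shape[2]) * fine + lo[2])[None, None, :]
        inside = np.zeros(tuple(shape), bool)
        for ax in axes:
            a = ax["start"]
            b = a + ax["dir"] * ax["length"]
            ab = b - a
            t = ((zz - a[0]) * ab[0] + (yy - a[1]) * ab[1] + (xx - a[2]) * ab[2]) \
                / float(ab @ ab)
            t = np.clip(t, 0, 1)
            d2 = (zz - a[0] - t * ab[0]) ** 2 + (yy - a[1] - t * ab[1]) ** 2 \
                + (xx - a[2] - t * ab[2]) ** 2
            inside |= d2 <= ax["radius"] ** 2
        analytic = inside.sum() * fine ** 3
        voxelized = phantom3.lumen_mask.data.sum() * vol.voxel_volume_mm3
        assert voxelized == pytest.approx(analytic, rel=0.05)


class TestGroundTruth:
    def test_tree_points_inside_lumen(self, phantom4):
        idx = phantom4.lumen_mask.world_to_index(phantom4.tree.all_points())
        assert phantom4.lumen_mask.data[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_labels_partition_and_correct_equals_lumen(self, phantom3):
        ref = phantom3.labels
        assert np.array_equal(ref.correct_mask, phantom3.lumen_mask.data)
        n = np.prod(ref.shape)
        assert (ref.correct_mask.sum() + ref.wrong_mask.sum()
                + ref.unknown_mask.sum() + (ref.labels == 0).sum()) == n

    def test_submasks_are_generation_1_and_2(self, phantom3):
        ref = phantom3.labels
        g1 = {i for i, g in ref.branch_generation.items() if g == 1}
        assert set(np.unique(ref.branch_id[ref.trachea_mask.data])) == g1
        assert ref.trachea_mask.data.sum() > 0
        assert ref.main_bronchi_mask.data.sum() > 0
        assert not (ref.trachea_mask.data & ref.main_bronchi_mask.data).any()

    def test_noise_free_hu_separability(self, phantom3):
        spec = phantom3.spec
        hu = phantom3.volume.data
        lumen = phantom3.lumen_mask.data
        wall = (hu > spec.hu_parenchyma) & ~lumen
        assert (hu[lumen] < spec.hu_parenchyma).all()
        assert (hu[wall] > spec.hu_parenchyma).all()
        assert wall.sum() > 0

    def test_tree_validates(self, phantom4):
        validate_tree(phantom4.tree)

    def test_same_seed_bit_identical(self):
        spec = dict(generations=2, noise_sigma_hu=15.0, seed=42)
        a = generate_phantom(PhantomSpec(**spec))
        b = generate_phantom(PhantomSpec(**spec))
        assert np.array_equal(a.volume.data, b.volume.data)
        assert np.array_equal(a.lumen_mask.data, b.lumen_mask.data)
        assert np.array_equal(a.labels.branch_id, b.labels.branch_id)


class TestCorruptSegmentation:
    def test_identity_when_nothing_dropped(self, phantom4):
        m = corrupt_segmentation(phantom4, 99, 0)
        assert np.array_equal(m.data, phantom4.lumen_mask.data)

    def test_drop_above_two_keeps_three_branches(self, phantom4):
        m = corrupt_segmentation(phantom4, 2, 0)
        ref = phantom4.labels
        keep = [i for i, g in ref.branch_generation.items() if g <= 2]
        expect = phantom4.lumen_mask.data & np.isin(ref.branch_id, keep)
        assert len(keep) == 3
        assert np.array_equal(m.data, expect)

    def test_leak_blobs_are_separate_and_sized(self, phantom4):
        from airtree.evaluate import leakage_stats
        m = corrupt_segmentation(phantom4, 3, leak_blobs=3, leak_voxels_each=10, seed=5)
        count, volume = leakage_stats(m, phantom4.labels)
        assert count == 3
        assert volume == pytest.approx(30 * phantom4.volume.voxel_volume_mm3)

    def test_blobs_avoid_correct_and_unknown(self, phantom4):
        m = corrupt_segmentation(phantom4, 2, leak_blobs=2, leak_voxels_each=8, seed=1)
        ref = phantom4.labels
        blobs = m.data & ~ref.correct_mask
        assert not (blobs & ref.unknown_mask).any()

    def test_invalid_drop_generation(self, phantom4):
        with pytest.raises(ParameterError):
            corrupt_segmentation(phantom4, 0)
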