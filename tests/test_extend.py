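"""Tissue extension: histogram matching, junction blending, region filling
and annotation merging."""
import numpy as np
import pytest

import atlasforge as af
from atlasforge.extend import (blend_junction, extend_region, histogram_match,
                               merge_annotations)


@pytest.fixture(scope="module")
def extension_setup(bundle):
    """Region 111 with its six most rostral populated planes removed from a
    pristine target; the donor is the complete warped anatomy."""
    full = bundle.ann_v3.labels == 111
    planes = np.where(full.any(axis=(1, 2)))[0]
    trunc = full.copy()
    trunc[planes[:6]] = False
    target_vals = bundle.intensity_true.values.copy()
    target_vals[full & ~trunc] = 0.0
    target = af.IntensityVolume(target_vals, bundle.intensity_true.meta)
    donor = af.IntensityVolume(bundle.nissl_clean.values, bundle.nissl.meta)
    return target, donor, full, trunc, planes


@pytest.fixture(scope="module")
def extension_run(extension_setup):
    target, donor, full, trunc, planes = extension_setup
    extended, transforms, report = extend_region(target, donor, full, trunc)
    return extended, transforms, report


class TestHistogramMatch:
    def test_identical_volumes_identity_mapping(self, bundle):
        out = histogram_match(bundle.nissl, bundle.nissl)
        fg = bundle.nissl.values != 0
        bin_w = np.ptp(bundle.nissl.values[fg]) / 256
        assert np.abs(out.values - bundle.nissl.values)[fg].mean() < bin_w

    def test_offset_recovered_within_one_bin(self, bundle):
        fg = bundle.nissl.values != 0
        shifted = af.IntensityVolume(
            np.where(fg, bundle.nissl.values + 50.0, 0.0), bundle.nissl.meta)
        out = histogram_match(shifted, bundle.nissl, mask=fg, ref_mask=fg)
        bin_w = np.ptp(bundle.nissl.values[fg]) / 256
        assert np.abs(out.values - bundle.nissl.values)[fg].mean() < 2 * bin_w

    def test_monotone_distortion_recovered(self, bundle):
        """KS distance to the reference < 0.02 after matching an arbitrary
        monotone intensity distortion."""
        from scipy.stats import ks_2samp
        fg = bundle.nissl.values != 0
        distorted = af.IntensityVolume(
            np.where(fg, 5.0 * np.sqrt(bundle.nissl.values) + 10.0, 0.0),
            bundle.nissl.meta)
        out = histogram_match(distorted, bundle.nissl, mask=fg, ref_mask=fg)
        stat = ks_2samp(out.values[fg], bundle.nissl.values[fg]).statistic
        assert stat < 0.02

    def test_order_preserved(self, bundle):
        fg = bundle.nissl.values != 0
        distorted = af.IntensityVolume(
            np.where(fg, bundle.nissl.values ** 1.3, 0.0), bundle.nissl.meta)
        out = histogram_match(distorted, bundle.nissl, mask=fg, ref_mask=fg)
        x = distorted.values[fg]
        y = out.values[fg]
        order = np.argsort(x)
        assert (np.diff(y[order]) >= -1e-9).all()

    def test_constant_source_rejected(self, bundle):
        flat = af.IntensityVolume(np.ones_like(bundle.nissl.values),
                                  bundle.nissl.meta)
        with pytest.raises(ValueError):
            histogram_match(flat, bundle.nissl)


class TestBlendJunction:
    def test_constant_sources_forced_mean(self, small_meta):
        base = af.IntensityVolume(np.full((10, 6, 6), 100.0), small_meta)
        add = af.IntensityVolume(np.full((10, 6, 6), 50.0), small_meta)
        out = blend_junction(base, add, axis=0, plane_index=5)
        assert (out.values[4:7] == 75.0).all()
        assert (out.values[:4] == 100.0).all()
        assert (out.values[7:] == 100.0).all()

    def test_identical_sources_unchanged(self, small_meta):
        base = af.IntensityVolume(np.full((10, 6, 6), 42.0), small_meta)
        out = blend_junction(base, base, axis=0, plane_index=5)
        assert np.array_equal(out.values, base.values)

    def test_changed_voxel_count_is_three_planes(self, small_meta, rng):
        base = af.IntensityVolume(rng.random((12, 5, 5)) + 1.0, small_meta)
        add = af.IntensityVolume(rng.random((12, 5, 5)) + 3.0, small_meta)
        out = blend_junction(base, add, axis=0, plane_index=6)
        changed = (out.values != base.values).sum()
        assert changed == 3 * 5 * 5

    def test_out_of_bounds_slab_rejected(self, small_meta):
        base = af.IntensityVolume(np.ones((4, 4, 4)), small_meta)
        with pytest.raises(ValueError):
            blend_junction(base, base, axis=0, plane_index=0)


class TestExtendRegion:
    def test_self_extension_is_identity(self, bundle):
        full = bundle.ann_v3.labels == 111
        target = af.IntensityVolume(
            np.where(full, bundle.intensity_true.values, 0.0),
            bundle.intensity_true.meta)
        out, _, rep = extend_region(target, target, full, full)
        assert rep.filled_voxels == 0
        fg = target.values != 0
        assert np.abs(out.values - target.values)[fg].mean() \
            < 0.01 * np.ptp(target.values)

    def test_filled_region_matches_ground_truth(self, bundle, extension_run):
        extended, _, report = extension_run
        full = bundle.ann_v3.labels == 111
        planes = np.where(full.any(axis=(1, 2)))[0]
        trunc = full.copy()
        trunc[planes[:6]] = False
        fill = full & ~trunc
        err = np.abs(extended.values - bundle.intensity_true.values)[fill].mean()
        assert err < 0.10 * np.ptp(bundle.intensity_true.values)
        assert report.filled_voxels == int((fill & (extended.values != 0)).sum())

    def test_junction_has_no_step(self, bundle, extension_run):
        extended, _, report = extension_run
        full = bundle.ann_v3.labels == 111
        planes = np.where(full.any(axis=(1, 2)))[0]
        jp = planes[6]
        g = np.abs(np.diff(extended.values, axis=0))
        fm = full[:-1] & full[1:]
        slab = np.zeros_like(fm)
        slab[jp - 2:jp + 1] = fm[jp - 2:jp + 1]
        interior = fm & ~slab
        assert g[slab].mean() <= 1.5 * g[interior].mean()

    def test_untouched_outside_full_mask(self, bundle, extension_setup,
                                         extension_run):
        target = extension_setup[0]
        extended = extension_run[0]
        outside = ~(bundle.ann_v3.labels == 111)
        assert (extended.values[outside] == target.values[outside]).all()

    def test_empty_donor_rejected(self, small_meta, rng):
        full = np.zeros((16, 8, 8), bool)
        full[2:12] = True
        trunc = full.copy()
        trunc[2:6] = False
        target = af.IntensityVolume(
            np.where(trunc, 5.0 + rng.random((16, 8, 8)), 0.0), small_meta)
        donor = af.IntensityVolume(np.zeros((16, 8, 8)), small_meta)
        with pytest.raises((ValueError, RuntimeError)):
            extend_region(target, donor, full, trunc)

    def test_truncated_mask_must_be_subset(self, small_meta):
        full = np.zeros((8, 8, 8), bool)
        full[2:5] = True
        trunc = np.ones_like(full)
        vol = af.IntensityVolume(np.ones((8, 8, 8)), small_meta)
        with pytest.raises(ValueError, match="subset"):
            extend_region(vol, vol, full, trunc)


class TestMergeAnnotations:
    def test_empty_addon_base_unchanged(self, bundle, small_meta):
        empty = af.LabeledVolume(np.zeros_like(bundle.ann_v3.labels),
                                 bundle.ann_v3.meta)
        merged, overlap = merge_annotations(bundle.ann_v3, empty)
        assert np.array_equal(merged.labels, bundle.ann_v3.labels)
        assert overlap == 0

    def test_caudal_concatenation_conserves_voxels(self, small_meta):
        base = af.LabeledVolume(np.full((6, 4, 4), 2), small_meta)
        addon = af.LabeledVolume(np.full((3, 4, 4), 9), small_meta)
        merged, _ = merge_annotations(
            base, addon, {"mode": "concat", "axis": 0, "end": "caudal"})
        assert merged.labels.shape == (9, 4, 4)
        assert (merged.labels != 0).sum() == 6 * 16 + 3 * 16

    def test_overlay_precedence_and_count(self, small_meta, rng):
        base = af.LabeledVolume(
            (rng.random((8, 8, 8)) > 0.5).astype(int) * 3, small_meta)
        addon = af.LabeledVolume(
            (rng.random((8, 8, 8)) > 0.5).astype(int) * 9, small_meta)
        merged, overlap = merge_annotations(base, addon, precedence="addon")
        brute = int(((base.labels != 0) & (addon.labels != 0)).sum())
        assert overlap == brute
        both = (base.labels != 0) & (addon.labels != 0)
        assert (merged.labels[both] == 9).all()
        labeled_union = (base.labels != 0) | (addon.labels != 0)
        assert ((merged.labels != 0) == labeled_union).all()

    def test_id_collision_without_remap_rejected(self, small_meta):
        base = af.LabeledVolume(np.full((4, 4, 4), 3), small_meta)
        addon = af.LabeledVolume(np.full((4, 4, 4), 3), small_meta)
        with pytest.raises(ValueError, match="collision"):
            merge_annotations(base, addon)

    def test_remap_resolves_collision(self, small_meta):
        base = af.LabeledVolume(np.full((4, 4, 4), 3), small_meta)
        addon_labels = np.zeros((4, 4, 4), int)
        addon_labels[0] = 3
        addon = af.LabeledVolume(addon_labels, small_meta)
        merged, _ = merge_annotations(base, addon, remap={3: 77})
        assert (merged.labels[0] == 77).all()
        assert (merged.labels[1:] == 3).all()
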