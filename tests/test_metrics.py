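"""Similarity and overlap metrics: NMI, TRE, Dice, reports, volume accounting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import atlasforge as af
from atlasforge.metrics import (joint_histogram, mean_label_dice, tre_summary,
                                volume_report)


def _all_mask(a):
    return np.ones(np.shape(a), bool)


class TestJointHistogram:
    def test_identical_images_diagonal(self, rng):
        a = rng.random((6, 6, 6))
        jh = joint_histogram(a, a, bins=16, mask=_all_mask(a))
        off_diag = jh.counts.sum() - np.trace(jh.counts)
        assert off_diag == 0

    def test_marginals_match_per_image_histograms(self, rng):
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        jh = joint_histogram(a, b, bins=12, mask=_all_mask(a))
        ma, mb = jh.marginals()
        np.testing.assert_array_equal(ma, np.histogram(a, bins=jh.edges_a)[0])
        np.testing.assert_array_equal(mb, np.histogram(b, bins=jh.edges_b)[0])
        assert jh.total == a.size

    def test_independent_images_roughly_uniform(self, rng):
        n = 40_000
        a = rng.random(n)
        b = rng.random(n)
        jh = joint_histogram(a, b, bins=4, mask=_all_mask(a))
        expected = n / 16
        chi2 = ((jh.counts - expected) ** 2 / expected).sum()
        assert chi2 < 50  # 15 dof; far below any plausible dependence

    def test_empty_mask_rejected(self, rng):
        a = rng.random((4, 4, 4))
        with pytest.raises(ValueError):
            joint_histogram(a, a, mask=np.zeros_like(a, bool))


class TestNMI:
    def test_self_similarity_is_one(self, rng):
        a = rng.random((8, 8, 8))
        assert af.nmi(a, a, bins=32, mask=_all_mask(a)) == pytest.approx(1.0)

    def test_independent_two_bin_example(self):
        a = np.array([0., 0., 1., 1.])
        b = np.array([0., 1., 0., 1.])
        assert af.nmi(a, b, bins=2, mask=_all_mask(a)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_four_voxel_example(self):
        # joint histogram [[2,1],[0,1]]: I = 0.3113 bits, H = 1 + 0.8113 bits
        a = np.array([0., 0., 1., 1.])
        b = np.array([0., 0., 0., 1.])
        assert af.nmi(a, b, bins=2, mask=_all_mask(a)) == pytest.approx(0.3437, abs=1e-3)

    def test_symmetry(self, rng):
        a = rng.random((6, 6, 6))
        b = rng.random((6, 6, 6))
        m = _all_mask(a)
        assert af.nmi(a, b, mask=m) == pytest.approx(af.nmi(b, a, mask=m))

    def test_monotone_rescaling_invariance(self, rng):
        """A strictly monotone intensity map that preserves bin assignment
        leaves NMI unchanged."""
        a = rng.integers(0, 8, (10, 10, 10)).astype(float)
        b = rng.integers(0, 8, (10, 10, 10)).astype(float)
        m = _all_mask(a)
        base = af.nmi(a, b, bins=8, mask=m)
        assert af.nmi(3 * a + 7, b, bins=8, mask=m) == pytest.approx(base)

    def test_constant_image_rejected(self):
        a = np.zeros((4, 4, 4))
        b = np.ones((4, 4, 4))
        with pytest.raises(ValueError):
            af.nmi(a, b, mask=_all_mask(a))

    def test_bounded_unit_interval(self, rng):
        for _ in range(5):
            a = rng.random((6, 6, 6))
            b = rng.random((6, 6, 6))
            v = af.nmi(a, b, bins=16, mask=_all_mask(a))
            assert 0.0 <= v <= 1.0


def _points(ref, reg):
    return pd.DataFrame({
        "name": [f"p{i}" for i in range(len(ref))],
        "x_ref": [r[0] for r in ref], "y_ref": [r[1] for r in ref],
        "z_ref": [r[2] for r in ref],
        "x_reg": [r[0] for r in reg], "y_reg": [r[1] for r in reg],
        "z_reg": [r[2] for r in reg]})


class TestTRE:
    def test_identical_coordinates_zero(self):
        pts = _points([(1., 2., 3.)], [(1., 2., 3.)])
        assert af.tre(pts)["tre_um"].iloc[0] == 0.0

    def test_pythagorean_quadruple(self):
        pts = _points([(0., 0., 0.)], [(3., 4., 12.)])
        assert af.tre(pts)["tre_um"].iloc[0] == pytest.approx(13.0)

    def test_mean_summary(self):
        pts = _points([(0., 0., 0.), (0., 0., 0.)],
                      [(0., 0., 0.), (3., 4., 12.)])
        summary = tre_summary(pts)
        overall = summary[summary["group_by"] == "all"].iloc[0]
        assert overall["mean"] == pytest.approx(6.5)

    def test_missing_pair_rejected(self):
        pts = _points([(0., 0., 0.)], [(1., 1., 1.)]).drop(columns=["z_reg"])
        with pytest.raises(ValueError):
            af.tre(pts)


class TestDice:
    def test_identity_one(self, rng):
        a = rng.random((5, 5, 5)) > 0.5
        assert af.dice(a, a) == 1.0

    def test_disjoint_zero(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[1] = True, True
        assert af.dice(a, b) == 0.0

    def test_partial_overlap(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4] = True          # |A| = 4
        b[2:8] = True         # |B| = 6, |A∩B| = 2
        assert af.dice(a, b) == pytest.approx(0.4)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            af.dice(np.zeros(4, bool), np.zeros(4, bool))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10))
    def test_removing_intersection_never_increases(self, k):
        a = np.zeros(30, bool)
        b = np.zeros(30, bool)
        a[:20] = True
        b[10:25] = True
        base = af.dice(a, b)
        b2 = b.copy()
        inter = np.where(a & b)[0]
        b2[inter[:min(k, len(inter))]] = False
        assert af.dice(a, b2) <= base + 1e-12


class TestPerRegionAndSlice:
    def test_identical_volumes_all_one(self, bundle):
        ids = sorted(bundle.comparable_leaf_ids)
        table = af.per_region_nmi(bundle.nissl, bundle.nissl, bundle.ann_v2,
                                  bundle.graph, ids)
        scored = table[~table["flagged"]]
        assert len(scored) > 0
        assert np.allclose(scored["nmi"], 1.0)

    def test_single_region_equals_masked_nmi(self, bundle):
        rid = 211
        mask = af.region_mask(bundle.ann_v3, bundle.graph, rid)
        table = af.per_region_nmi(bundle.template, bundle.intensity_true,
                                  bundle.ann_v3, bundle.graph, [rid])
        direct = af.nmi(bundle.template, bundle.intensity_true, mask=mask)
        assert table["nmi"].iloc[0] == pytest.approx(direct)

    def test_small_regions_flagged(self, bundle):
        table = af.per_region_nmi(bundle.template, bundle.intensity_true,
                                  bundle.ann_v3, bundle.graph, [111],
                                  min_voxels=10**9)
        assert table["flagged"].all()

    def test_per_slice_identity_and_length(self, bundle):
        series = af.per_slice_nmi(bundle.template, bundle.template, "coronal")
        assert len(series) == bundle.template.values.shape[0]
        scored = series[~series["flagged"]]
        assert np.allclose(scored["nmi"], 1.0)


class TestVolumeAccounting:
    def test_mm3_conversion_exact(self):
        assert af.voxels_to_mm3(1, 25.0) == pytest.approx(0.025 ** 3)
        assert round(af.voxels_to_mm3(30870, 25.0), 4) == 0.4823

    def test_no_change_all_zero(self, bundle):
        ids = sorted(set(np.unique(bundle.ann_v3.labels)) - {0})
        rep = volume_report(bundle.ann_v3, bundle.ann_v3, bundle.graph, ids)
        assert (rep["added_voxels"] == 0).all()
        assert (rep["modified_voxels"] == 0).all()

    def test_added_modified_and_conservation(self, bundle, small_meta):
        before = bundle.ann_v3
        after_labels = before.labels.copy()
        # add: grow region 111 into 10 background voxels
        bg = np.argwhere(before.labels == 0)[:10]
        after_labels[tuple(bg.T)] = 111
        # modify: flip 7 voxels of region 211 to 111
        src = np.argwhere(before.labels == 211)[:7]
        after_labels[tuple(src.T)] = 111
        after = af.LabeledVolume(after_labels, before.meta)
        rep = volume_report(before, after, bundle.graph, [111])
        row = rep[rep["region"] == 111].iloc[0]
        assert row["added_voxels"] == 10
        assert row["modified_voxels"] == 7
        assert row["total_voxels"] == 17
        assert row["total_mm3"] == pytest.approx(17 * 0.025 ** 3)
        total = rep[rep["region"] == "TOTAL"].iloc[0]
        assert (total["total_voxels"]
                == total["added_voxels"] + total["modified_voxels"])

    def test_relative_increase(self):
        assert round(af.relative_increase_percent(504.9, 511.7), 2) == 1.35


def test_mean_label_dice_identity(bundle):
    ids = sorted(bundle.comparable_leaf_ids)
    assert mean_label_dice(bundle.ann_v3, bundle.ann_v3, ids) == 1.0
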