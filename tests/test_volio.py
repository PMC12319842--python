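"""Volume I/O round-trips and grid-level preprocessing operators."""
import numpy as np
import pytest

import atlasforge as af
from atlasforge.phantom import inject_asymmetry, inject_stray_voxels
from atlasforge.transforms import DeformationField
from atlasforge.volio import GridMeta, bounding_box, crop


@pytest.mark.parametrize("ext", ["nii.gz", "nii", "nrrd"])
class TestRoundTrip:
    def test_intensity(self, tmp_path, rng, ext):
        meta = GridMeta((25., 25., 25.), origin=(-350., 0., 12.5))
        vol = af.IntensityVolume(rng.random((10, 10, 10)).astype(np.float32),
                                 meta)
        path = tmp_path / f"v.{ext}"
        af.write_volume(vol, path)
        back = af.read_volume(path)
        assert isinstance(back, af.IntensityVolume)
        np.testing.assert_allclose(back.values, vol.values, atol=1e-6)
        np.testing.assert_allclose(back.meta.voxel_size, (25., 25., 25.),
                                   atol=1e-3)
        np.testing.assert_allclose(back.meta.origin, meta.origin, atol=1e-3)

    def test_labels_exact(self, tmp_path, rng, ext):
        meta = GridMeta((10., 10., 10.))
        vol = af.LabeledVolume(rng.integers(0, 997, (9, 8, 7)), meta)
        path = tmp_path / f"l.{ext}"
        af.write_volume(vol, path)
        back = af.read_volume(path)
        assert isinstance(back, af.LabeledVolume)
        assert np.array_equal(back.labels, vol.labels)

    def test_labels_refuse_float_dtype(self, tmp_path, rng, ext):
        vol = af.LabeledVolume(rng.integers(0, 5, (4, 4, 4)),
                               GridMeta((25., 25., 25.)))
        with pytest.raises(ValueError, match="integer"):
            af.write_volume(vol, tmp_path / f"l.{ext}", dtype=np.float32)


def test_negative_spacing_rejected():
    with pytest.raises(ValueError):
        GridMeta((25., -25., 25.))


class TestDownsample:
    def test_constant_labels_invariant(self, small_meta):
        vol = af.LabeledVolume(np.full((8, 8, 8), 7), small_meta)
        out = af.downsample_labels(vol, 2)
        assert (out.labels == 7).all()
        assert out.meta.voxel_size == (50., 50., 50.)

    def test_forced_majority(self, small_meta):
        block = np.array([7, 7, 7, 7, 3, 3, 0, 0]).reshape(2, 2, 2)
        out = af.downsample_labels(af.LabeledVolume(block, small_meta), 2)
        assert out.labels[0, 0, 0] == 7

    def test_tie_breaks_toward_smallest_id(self, small_meta):
        block = np.array([5, 5, 5, 5, 3, 3, 3, 3]).reshape(2, 2, 2)
        out = af.downsample_labels(af.LabeledVolume(block, small_meta), 2)
        assert out.labels[0, 0, 0] == 3

    def test_majority_matches_bruteforce(self, rng, small_meta):
        labels = rng.integers(0, 4, (12, 12, 12))
        out = af.downsample_labels(af.LabeledVolume(labels, small_meta), 3)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    block = labels[3*i:3*i+3, 3*j:3*j+3, 3*k:3*k+3].ravel()
                    ids, counts = np.unique(block, return_counts=True)
                    expect = ids[counts == counts.max()].min()
                    assert out.labels[i, j, k] == expect

    def test_never_invents_labels(self, rng, small_meta):
        labels = rng.integers(0, 6, (10, 10, 10))
        out = af.downsample_labels(af.LabeledVolume(labels, small_meta), 2)
        assert set(np.unique(out.labels)) <= set(np.unique(labels))

    def test_intensity_block_mean(self, small_meta):
        vals = np.zeros((2, 2, 2))
        vals[1, 1, 1] = 8.0
        out = af.downsample_intensity(af.IntensityVolume(vals, small_meta), 2)
        assert out.values[0, 0, 0] == 1.0

    def test_intensity_matches_bruteforce(self, rng, small_meta):
        vals = rng.random((8, 8, 8))
        out = af.downsample_intensity(af.IntensityVolume(vals, small_meta), 2)
        expect = vals.reshape(4, 2, 4, 2, 4, 2).mean(axis=(1, 3, 5))
        np.testing.assert_allclose(out.values, expect)


class TestCleanBorderVoxels:
    def test_single_stray_removed_body_conserved(self, small_meta):
        labels = np.zeros((20, 20, 20), int)
        labels[5:10, 5:10, 5:10] = 3
        labels[18, 18, 18] = 3  # isolated stray
        cleaned, removed = af.clean_border_voxels(
            af.LabeledVolume(labels, small_meta), min_component=5)
        assert removed == 1
        assert cleaned.labels[18, 18, 18] == 0
        assert (cleaned.labels == 3).sum() == 125

    def test_adjacent_small_component_kept(self, small_meta):
        labels = np.zeros((20, 20, 20), int)
        labels[5:10, 5:10, 5:10] = 3
        labels[10, 5, 5] = 3  # face-adjacent to the body, same label
        cleaned, removed = af.clean_border_voxels(
            af.LabeledVolume(labels, small_meta), min_component=5,
            connectivity=6)
        assert removed == 0

    def test_injected_strays_exactly_removed(self, bundle):
        ann, placed = inject_stray_voxels(bundle.ann_v3, 7, seed=3)
        cleaned, removed = af.clean_border_voxels(ann, min_component=5)
        assert removed == len(placed) == 7
        assert np.array_equal(cleaned.labels, bundle.ann_v3.labels)


class TestSymmetrize:
    def test_symmetric_input_unchanged(self, small_meta):
        data = np.zeros((4, 4, 6), int)
        data[:, :, [0, 5]] = 2
        vol = af.LabeledVolume(data, small_meta)
        out = af.symmetrize(vol, "right")
        assert np.array_equal(out.labels, data)

    def test_output_is_its_own_mirror(self, bundle):
        out = af.symmetrize(bundle.ann_v3, "right")
        axis = out.meta.axis_of("leftright")
        assert np.array_equal(out.labels, np.flip(out.labels, axis=axis))

    def test_injected_asymmetry_resolved(self, bundle):
        ann, n = inject_asymmetry(bundle.ann_v3, 433, seed=5)
        assert n == 433
        out = af.symmetrize(ann, "right")
        axis = out.meta.axis_of("leftright")
        assert (out.labels != np.flip(out.labels, axis=axis)).sum() == 0

    def test_wrong_axis_rejected(self, bundle):
        with pytest.raises(ValueError, match="left-right"):
            af.symmetrize(bundle.ann_v3, "right", midplane_axis=0)


class TestPad:
    def test_rostral_pad_shifts_origin(self, small_meta):
        vol = af.IntensityVolume(np.ones((4, 4, 4)), small_meta)
        out = af.pad(vol, [(14, 0), (0, 0), (0, 0)])
        assert out.meta.origin[0] == -350.0
        assert out.values.shape == (18, 4, 4)

    def test_zero_pad_is_identity(self, small_meta):
        vol = af.IntensityVolume(np.ones((4, 4, 4)), small_meta)
        out = af.pad(vol, [(0, 0)] * 3)
        assert np.array_equal(out.values, vol.values)
        assert out.meta.origin == vol.meta.origin

    def test_world_coordinates_preserved(self, rng, small_meta):
        vol = af.IntensityVolume(rng.random((4, 4, 4)), small_meta)
        out = af.pad(vol, [(3, 1), (0, 2), (5, 0)])
        # voxel (0,0,0) of the original sits at padded index (3,0,5)
        np.testing.assert_allclose(out.meta.world((3, 0, 5)),
                                   vol.meta.world((0, 0, 0)))
        assert out.values[3, 0, 5] == vol.values[0, 0, 0]

    def test_negative_slabs_rejected(self, small_meta):
        vol = af.IntensityVolume(np.ones((4, 4, 4)), small_meta)
        with pytest.raises(ValueError):
            af.pad(vol, [(-1, 0), (0, 0), (0, 0)])


class TestUpsampleField:
    def test_zero_field_stays_zero(self, small_meta):
        fld = DeformationField(np.zeros((6, 6, 6, 3)),
                               small_meta.with_shape((6, 6, 6)))
        out = af.upsample_field(fld, 2)
        assert np.all(out.displacements == 0)

    def test_uniform_translation_preserved(self, small_meta):
        disp = np.zeros((8, 8, 8, 3))
        disp[..., 1] = 50.0  # µm
        fld = DeformationField(disp, small_meta.with_shape((8, 8, 8)))
        out = af.upsample_field(fld, 2.5)
        np.testing.assert_allclose(out.displacements[..., 1], 50.0)
        assert out.shape == (20, 20, 20)
        np.testing.assert_allclose(out.meta.voxel_size, (10., 10., 10.))

    def test_coarse_and_fine_application_agree(self, bundle):
        """Applying the generating field at 25 µm vs its 2x upsampled version
        at 12.5 µm yields consistent images."""
        from atlasforge.register import apply_transform
        coarse = apply_transform(bundle.intensity_true, bundle.true_field,
                                 interpolation="linear")
        fine_field = af.upsample_field(bundle.true_field, 2)
        fine = apply_transform(bundle.intensity_true, fine_field,
                               interpolation="linear")
        back = af.downsample_intensity(fine, 2)
        fg = (coarse.values != 0) & (back.values != 0)
        err = np.abs(coarse.values - back.values)[fg].mean()
        assert err < 0.02 * np.ptp(bundle.intensity_true.values)


class TestCropAndBBox:
    def test_crop_keeps_world_coordinates(self, rng, small_meta):
        vol = af.IntensityVolume(rng.random((8, 8, 8)), small_meta)
        sub = crop(vol, (slice(2, 6), slice(1, 7), slice(0, 8)))
        np.testing.assert_allclose(sub.meta.world((0, 0, 0)),
                                   vol.meta.world((2, 1, 0)))

    def test_bounding_box_tight_and_margin(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[3:5, 4:7, 2:3] = True
        assert bounding_box(mask) == (slice(3, 5), slice(4, 7), slice(2, 3))
        grown = bounding_box(mask, margin=2, shape=mask.shape)
        assert grown == (slice(1, 7), slice(2, 9), slice(0, 5))
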