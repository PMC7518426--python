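"""Volume I/O, resampling, patch decomposition, and MIP rendering."""

import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angioseg.volume_io import (FormatError, LabelVolume, Volume,
                                extract_patches, make_patch_grid, mip,
                                normalize_resolution, read_label_volume,
                                read_volume, stitch, write_volume)


class TestNiftiRoundTrip:
    def test_volume_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = Volume(rng.normal(size=(16, 16, 16)).astype(np.float32),
                     spacing=(0.5, 0.7, 0.7))
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, vol.data)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_label_round_trip_preserves_dtype_and_values(self, tmp_path):
        rng = np.random.default_rng(1)
        lab = LabelVolume(rng.integers(0, 5, size=(12, 10, 8)).astype(np.int16))
        path = tmp_path / "l.nii.gz"
        write_volume(lab, path)
        back = read_label_volume(path)
        assert np.issubdtype(back.data.dtype, np.integer)
        np.testing.assert_array_equal(back.data, lab.data)
        assert set(np.unique(back.data)) == set(np.unique(lab.data))

    def test_4d_payload_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32),
                                 np.eye(4)), str(path))
        with pytest.raises(FormatError):
            read_volume(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_non_3d_array_rejected_at_construction(self):
        with pytest.raises(FormatError):
            Volume(np.zeros((4, 4)))
        with pytest.raises(FormatError):
            Volume(np.full((4, 4, 4), np.nan))


class TestNormalizeResolution:
    def test_same_spacing_is_identity_on_dims(self):
        vol = Volume(np.random.default_rng(2).random((10, 12, 14)), (1, 1, 1))
        out = normalize_resolution(vol, 1.0)
        assert out.shape == vol.shape
        np.testing.assert_allclose(out.data, vol.data)

    def test_downsampling_dim_arithmetic(self):
        vol = Volume(np.zeros((64, 64, 64), dtype=np.float32), (1, 1, 1))
        out = normalize_resolution(vol, 2.0)
        assert out.shape == (32, 32, 32)
        assert out.spacing == (2.0, 2.0, 2.0)

    def test_constant_volume_stays_constant(self):
        vol = Volume(np.full((20, 20, 20), 7.5, dtype=np.float32), (1, 1, 1))
        out = normalize_resolution(vol, 0.8)
        np.testing.assert_allclose(out.data, 7.5, rtol=1e-6)

    def test_label_resampling_stays_integer(self):
        lab = LabelVolume(np.random.default_rng(3).integers(0, 5, (16, 16, 16),
                                                            dtype=np.int16))
        out = normalize_resolution(lab, 2.0)
        assert np.issubdtype(out.data.dtype, np.integer)
        assert set(np.unique(out.data)) <= set(np.unique(lab.data))

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_spacing_rejected(self, bad):
        vol = Volume(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError):
            normalize_resolution(vol, bad)


class TestPatchGrid:
    def test_exact_fit_single_patch(self):
        grid = make_patch_grid((256, 256, 256), 256, 256)
        assert grid.n_patches == 1

    def test_overlap_count_formula(self):
        grid = make_patch_grid((300, 300, 300), 256, 128)
        assert grid.n_patches == 8  # 2 per axis

    def test_volume_smaller_than_patch(self):
        grid = make_patch_grid((64, 64, 64), 256)
        assert grid.n_patches == 1
        patches = extract_patches(np.ones((64, 64, 64)), grid)
        assert patches[0].shape == (256, 256, 256)

    def test_stride_larger_than_patch_rejected(self):
        with pytest.raises(ValueError):
            make_patch_grid((64, 64, 64), 32, 48)

    @settings(max_examples=30, deadline=None)
    @given(dim=st.integers(17, 90), patch=st.integers(8, 32),
           stride_frac=st.floats(0.25, 1.0))
    def test_every_voxel_covered(self, dim, patch, stride_frac):
        stride = max(int(patch * stride_frac), 1)
        grid = make_patch_grid((dim, 8, 8), patch, stride)
        covered = np.zeros(dim, dtype=bool)
        for z, _, _ in grid.origins:
            covered[z:z + patch] = True
        assert covered.all()


class TestExtractStitch:
    def test_partition_round_trip_bit_identical(self):
        data = np.random.default_rng(4).random((64, 64, 64))
        grid = make_patch_grid(data.shape, 32, 32)
        out = stitch(extract_patches(data, grid), grid)
        np.testing.assert_array_equal(out, data)

    def test_overlapping_constant_reconstruction(self):
        data = np.full((48, 48, 48), 3.25)
        grid = make_patch_grid(data.shape, 32, 16)
        np.testing.assert_allclose(stitch(extract_patches(data, grid), grid), 3.25)

    def test_mean_reduce_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(5)
        data = rng.random((20, 20, 20))
        grid = make_patch_grid(data.shape, 12, 6)
        patches = extract_patches(data, grid)
        # independent oracle: accumulate every covering patch per voxel
        acc = np.zeros(data.shape)
        cnt = np.zeros(data.shape)
        for patch, origin in zip(patches, grid.origins):
            sl = grid.patch_slices(origin)
            valid = tuple(slice(0, s.stop - s.start) for s in sl)
            acc[sl] += patch[valid]
            cnt[sl] += 1
        np.testing.assert_allclose(stitch(patches, grid, "mean"), acc / cnt)

    def test_max_reduce(self):
        data = np.random.default_rng(6).random((20, 20, 20))
        grid = make_patch_grid(data.shape, 12, 6)
        out = stitch(extract_patches(data, grid), grid, "max")
        np.testing.assert_allclose(out, data)  # all overlaps hold equal values

    def test_patch_grid_mismatch_rejected(self):
        grid = make_patch_grid((16, 16, 16), 8, 8)
        with pytest.raises(ValueError):
            stitch([np.zeros((4, 4, 4))] * grid.n_patches, grid)


class TestMip:
    def test_constant_volume_gives_constant_plane(self):
        assert (mip(np.full((5, 6, 7), 2.0), 0) == 2.0).all()

    def test_single_bright_voxel_projection(self):
        data = np.zeros((8, 8, 8))
        data[3, 5, 2] = 9.0
        img = mip(data, axis=0)
        assert img[5, 2] == 9.0
        assert img.sum() == 9.0

    def test_matches_loop_oracle(self):
        data = np.random.default_rng(7).random((8, 8, 8))
        for axis in range(3):
            img = mip(data, axis)
            moved = np.moveaxis(data, axis, 0)
            for i in range(img.shape[0]):
                for j in range(img.shape[1]):
                    assert img[i, j] == max(moved[k, i, j] for k in range(8))

    def test_result_dominates_every_slice(self):
        data = np.random.default_rng(8).random((6, 6, 6))
        img = mip(data, 1)
        for k in range(6):
            assert (img >= data[:, k, :]).all()

    def test_invalid_axis(self):
        with pytest.raises(ValueError):
            mip(np.zeros((4, 4, 4)), 3)
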