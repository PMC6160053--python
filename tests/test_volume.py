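import numpy as np
import pytest

from trabnet.volume import (BinaryVolume, VoxelVolume, denoise_contrast,
                            extract_subvolume, preprocess, read_volume,
                            remove_small_components, threshold_band,
                            write_volume)


def brute_force_components(mask, connectivity):
    """Flood-fill component labelling, the slow independent oracle."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if (connectivity == 6 and order == 1) or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offs.append((dz, dy, dx))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if seen[idx]:
            continue
        stack, comp = [idx], []
        seen[idx] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offs:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[k] < mask.shape[k] for k in range(3)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


class TestIO:
    @pytest.mark.parametrize("fmt,suffix", [("tiff-stack", ".tif"),
                                            ("nrrd", ".nrrd")])
    def test_round_trip(self, tmp_path, rng, fmt, suffix):
        data = rng.integers(0, 256, size=(30, 30, 30), dtype=np.uint8)
        vol = VoxelVolume(data, 3.0)
        path = tmp_path / ("v" + suffix)
        write_volume(vol, path, fmt)
        back = read_volume(path, fmt, voxel_size=3.0)
        assert back.shape == (30, 30, 30)
        assert back.voxel_size == 3.0
        np.testing.assert_array_equal(back.data, data)

    def test_formats_agree(self, tmp_path, rng):
        data = rng.integers(0, 256, size=(8, 9, 10), dtype=np.uint8)
        vol = VoxelVolume(data, 3.0)
        write_volume(vol, tmp_path / "v.tif", "tiff-stack")
        write_volume(vol, tmp_path / "v.nrrd", "nrrd")
        a = read_volume(tmp_path / "v.tif", voxel_size=3.0)
        b = read_volume(tmp_path / "v.nrrd")
        np.testing.assert_array_equal(a.data, b.data)
        assert b.voxel_size == 3.0  # from NRRD spacings metadata

    def test_2d_image_rejected(self, tmp_path):
        import tifffile
        tifffile.imwrite(tmp_path / "flat.tif",
                         np.zeros((16, 16), dtype=np.uint8))
        with pytest.raises(ValueError, match="not a 3D volume"):
            read_volume(tmp_path / "flat.tif")

    def test_non_8bit_needs_rescale(self, tmp_path):
        import tifffile
        tifffile.imwrite(tmp_path / "deep.tif",
                         np.zeros((4, 4, 4), dtype=np.uint16))
        with pytest.raises(ValueError, match="8-bit"):
            read_volume(tmp_path / "deep.tif")
        vol = read_volume(tmp_path / "deep.tif", rescale=True)
        assert vol.data.dtype == np.uint8


class TestSubvolume:
    def test_90um_cube_is_30_voxels(self, rng):
        vol = VoxelVolume(rng.integers(0, 255, (40, 40, 40), dtype=np.uint8), 3.0)
        sub = extract_subvolume(vol, (0, 0, 0), 90.0)
        assert sub.shape == (30, 30, 30)
        np.testing.assert_array_equal(sub.data, vol.data[:30, :30, :30])

    def test_full_extent_is_identity(self, rng):
        vol = VoxelVolume(rng.integers(0, 255, (10, 10, 10), dtype=np.uint8), 3.0)
        sub = extract_subvolume(vol, (0, 0, 0), 30.0)
        np.testing.assert_array_equal(sub.data, vol.data)

    def test_out_of_bounds(self, rng):
        vol = VoxelVolume(rng.integers(0, 255, (10, 10, 10), dtype=np.uint8), 3.0)
        with pytest.raises(ValueError, match="bounds"):
            extract_subvolume(vol, (15.0, 0.0, 0.0), 30.0)
        with pytest.raises(ValueError, match="bounds"):
            extract_subvolume(vol, (-30.0, 0.0, 0.0), 15.0)

    def test_origin_updated(self, rng):
        vol = VoxelVolume(rng.integers(0, 255, (10, 10, 10), dtype=np.uint8), 3.0)
        sub = extract_subvolume(vol, (6.0, 3.0, 9.0), 9.0)
        np.testing.assert_allclose(sub.origin, [6.0, 3.0, 9.0])


class TestDenoise:
    def test_constant_volume_unchanged(self):
        vol = VoxelVolume(np.full((8, 8, 8), 120, dtype=np.uint8), 3.0)
        out = denoise_contrast(vol)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_salt_voxel_suppressed_to_local_median(self):
        data = np.zeros((7, 7, 7), dtype=np.uint8)
        data[:, :, 4:] = 255          # two-phase volume
        data[3, 3, 1] = 255           # one voxel of salt noise
        vol = VoxelVolume(data, 3.0)
        out = denoise_contrast(vol, size_px=3, neighborhood=26)
        # oracle: median over the 3x3x3 neighborhood of the noisy voxel
        block = data[2:5, 2:5, 0:3]
        assert out.data[3, 3, 1] == np.median(block)
        assert out.data[3, 3, 1] == 0

    def test_idempotent_on_two_valued(self):
        data = np.zeros((8, 8, 8), dtype=np.uint8)
        data[:, :, 4:] = 255
        vol = VoxelVolume(data, 3.0)
        once = denoise_contrast(vol)
        twice = denoise_contrast(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_invalid_parameters(self):
        vol = VoxelVolume(np.zeros((4, 4, 4), dtype=np.uint8), 3.0)
        with pytest.raises(ValueError):
            denoise_contrast(vol, size_px=0)
        with pytest.raises(ValueError):
            denoise_contrast(vol, neighborhood=7)


class TestThreshold:
    def test_band_membership(self):
        data = np.array([[[50, 76], [172, 200]]], dtype=np.uint8)
        out = threshold_band(VoxelVolume(data, 3.0), 76, 172)
        np.testing.assert_array_equal(
            out.mask, np.array([[[False, True], [True, False]]]))

    @pytest.mark.parametrize("value,expected", [(100, True), (200, False)])
    def test_constant_volumes(self, value, expected):
        vol = VoxelVolume(np.full((5, 5, 5), value, dtype=np.uint8), 3.0)
        out = threshold_band(vol, 76, 172)
        assert out.mask.all() == expected
        assert out.mask.any() == expected

    def test_inverted_band_rejected(self):
        vol = VoxelVolume(np.zeros((4, 4, 4), dtype=np.uint8), 3.0)
        with pytest.raises(ValueError):
            threshold_band(vol, 172, 76)


class TestRemoveSmallComponents:
    def test_size_rule(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[:3, :20, :20] = True    # 1200 voxels
        mask[10:18, 0:10, 0:10] = False
        mask[5:13, 5:15, 5:15] = True  # 800 voxels
        mask[4, :, :] = False        # separate the blobs
        big = mask[:3].sum()
        out = remove_small_components(BinaryVolume(mask, 3.0), 1000, 26)
        assert out.mask[:3].sum() == big
        assert out.mask[5:].sum() == 0

    def test_boundary_inclusive(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:4, 2:4, 2:4] = True   # exactly 8 voxels
        out = remove_small_components(BinaryVolume(mask, 3.0), 8, 26)
        assert out.mask.sum() == 8
        out2 = remove_small_components(BinaryVolume(mask, 3.0), 9, 26)
        assert out2.mask.sum() == 0

    def test_diagonal_chain_connectivity(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        for i in range(3):
            mask[i + 1, i + 1, i + 1] = True
        for conn in (6, 26):
            comps = brute_force_components(mask, conn)
            out = remove_small_components(BinaryVolume(mask, 3.0), 2, conn)
            # oracle: chain is one 3-voxel component at 26, three singles at 6
            expected = sum(len(c) for c in comps if len(c) >= 2)
            assert out.mask.sum() == expected
        assert len(brute_force_components(mask, 26)) == 1
        assert len(brute_force_components(mask, 6)) == 3

    def test_idempotent_and_monotone(self, rng):
        mask = rng.random((15, 15, 15)) < 0.2
        bv = BinaryVolume(mask, 3.0)
        once = remove_small_components(bv, 5, 26)
        twice = remove_small_components(once, 5, 26)
        np.testing.assert_array_equal(once.mask, twice.mask)
        assert once.mask.sum() <= mask.sum()


class TestChainProperties:
    def test_threshold_then_removal_commutes_with_interior_crop(self, rng):
        data = np.zeros((24, 24, 24), dtype=np.uint8)
        data[6:10, 6:10, 6:10] = 100          # interior blob, 64 vox
        data[14:16, 14:16, 14:16] = 100       # interior blob, 8 vox
        vol = VoxelVolume(data, 1.0)
        full = remove_small_components(threshold_band(vol, 76, 172), 20, 26)
        crop = extract_subvolume(vol, (4.0, 4.0, 4.0), 16.0)
        cropped_then = remove_small_components(
            threshold_band(crop, 76, 172), 20, 26)
        np.testing.assert_array_equal(cropped_then.mask,
                                      full.mask[4:20, 4:20, 4:20])

    def test_full_chain_monotone_vs_threshold(self, rng):
        data = rng.integers(0, 256, size=(20, 20, 20), dtype=np.uint8)
        vol = VoxelVolume(data, 3.0)
        thresholded = threshold_band(vol, 76, 172)
        chained = preprocess(vol, denoise=False, min_size_vox=10)
        assert chained.mask.sum() <= thresholded.mask.sum()

    def test_degenerate_result_rejected(self):
        vol = VoxelVolume(np.full((6, 6, 6), 200, dtype=np.uint8), 3.0)
        with pytest.raises(ValueError, match="degenerate"):
            preprocess(vol, denoise=False)
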