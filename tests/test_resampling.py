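"""Voxel averaging, mask erosion and 3×3 down-sampling."""

import numpy as np
import pytest

from xepcv.grids import DynamicWindow, GridGeometry, sagittal_slab_grid
from xepcv.phantom import AnalyticFlowField, TubePhantom
from xepcv.resampling import (
    EmptyMaskError,
    VoxelVelocityMap,
    downsample_blocks,
    erode_mask,
    resample_to_voxels,
)


def brute_erode(mask2d):
    """Enumeration oracle: keep a pixel iff it and its 4 neighbours are set."""
    out = np.zeros_like(mask2d)
    n0, n1 = mask2d.shape
    for i in range(n0):
        for j in range(n1):
            if not mask2d[i, j]:
                continue
            ok = True
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if not (0 <= ii < n0 and 0 <= jj < n1) or not mask2d[ii, jj]:
                    ok = False
                    break
            out[i, j] = ok
    return out


def brute_downsample(values, mask, block, min_count):
    """Loop oracle for non-overlapping block means."""
    nb0 = values.shape[0] // block[0]
    nb1 = values.shape[1] // block[1]
    means = np.full((nb0, nb1), np.nan)
    out_mask = np.zeros((nb0, nb1), dtype=bool)
    for a in range(nb0):
        for b in range(nb1):
            vs, ms = [], 0
            for i in range(a * block[0], (a + 1) * block[0]):
                for j in range(b * block[1], (b + 1) * block[1]):
                    if mask[i, j]:
                        vs.append(values[i, j])
                        ms += 1
            if ms >= min_count:
                out_mask[a, b] = True
                means[a, b] = np.mean(vs)
    return means, out_mask


def make_map(values, mask, in_plane_mm=1.25):
    """Wrap in-plane arrays into a single-slab VoxelVelocityMap."""
    values = np.asarray(values, dtype=float)[None, ...]
    mask = np.asarray(mask, dtype=bool)[None, ...]
    grid = GridGeometry(
        shape=values.shape, affine=np.diag([10.0, in_plane_mm, in_plane_mm, 1.0])
    )
    return VoxelVelocityMap(
        grid=grid,
        velocity={"FH": values},
        mask=mask,
        window=DynamicWindow(0.0, 1.0),
    )


class TestResample:
    def test_constant_field(self, stub_constant, small_grid, window):
        vmap = resample_to_voxels(stub_constant, small_grid, window)
        assert vmap.mask.all()
        np.testing.assert_allclose(vmap.velocity["FH"], 50.0, rtol=1e-12)  # cm/s
        np.testing.assert_allclose(vmap.velocity["RL"], 0.0)

    def test_linear_field_gives_centroid_value(self, stub_linear, small_grid, window):
        """Midpoint supersampling integrates a linear field exactly."""
        vmap = resample_to_voxels(stub_linear, small_grid, window)
        centers_mm = small_grid.voxel_centers_mm()
        expect_cms = (3.0 * centers_mm[..., 2] / 1000.0 + 0.1) * 100.0
        np.testing.assert_allclose(vmap.velocity["FH"], expect_cms, rtol=1e-10)

    def test_poiseuille_row_flux(self, steady_field, small_grid, window):
        """Voxel row spanning the cross-section recovers the flow rate to 2%."""
        vmap = resample_to_voxels(steady_field, small_grid, window)
        dx_m = 20.0 / 1000.0  # slab
        dy_m = 1.25 / 1000.0
        k = small_grid.shape[2] // 2
        row = vmap.velocity["FH"][0, :, k] / 100.0  # m/s, zeros outside lumen
        flux = np.sum(row) * dx_m * dy_m
        assert flux == pytest.approx(-8e-5, rel=0.02)

    def test_empty_overlap_raises(self, steady_field, window):
        far_grid = sagittal_slab_grid(
            fov_ap_mm=10, fov_fh_mm=10, center_mm=(0.0, 500.0, 0.0)
        )
        with pytest.raises(EmptyMaskError):
            resample_to_voxels(steady_field, far_grid, window)

    def test_supersampling_convergence(self, steady_field, window):
        """Grid-independence: successive supersampling doublings change the
        voxel means less and less, reaching < 0.1% (lumen-edge sampling is the
        slowest-converging part, so a small voxel patch suffices)."""
        grid = sagittal_slab_grid(fov_ap_mm=20, fov_fh_mm=5, slab_mm=20.0)
        changes = []
        prev = None
        for s in (8, 16, 32):
            vmap = resample_to_voxels(
                steady_field, grid, window, supersampling=s, slab_supersampling=2 * s + 1
            )
            vals = vmap.velocity["FH"].ravel()
            if prev is not None:
                changes.append(np.linalg.norm(vals - prev) / np.linalg.norm(prev))
            prev = vals
        assert changes[1] < changes[0]
        assert changes[-1] < 1e-3

    def test_minimum_supersampling_enforced(self, steady_field, small_grid, window):
        with pytest.raises(ValueError):
            resample_to_voxels(steady_field, small_grid, window, supersampling=1)


class TestErode:
    def test_thin_strip_vanishes(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3:5, :] = True  # 2-voxel-wide strip
        assert not erode_mask(mask, 1).any()

    def test_square_interior(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        expect = np.zeros_like(mask)
        expect[3:6, 3:6] = True
        np.testing.assert_array_equal(erode_mask(mask, 1), expect)

    def test_composition(self):
        rng = np.random.default_rng(0)
        mask = rng.random((12, 12)) < 0.7
        np.testing.assert_array_equal(
            erode_mask(erode_mask(mask, 1), 1), erode_mask(mask, 2)
        )

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            mask = rng.random((10, 10)) < rng.uniform(0.3, 0.9)
            np.testing.assert_array_equal(erode_mask(mask, 1), brute_erode(mask))

    def test_result_subset_of_input(self):
        rng = np.random.default_rng(2)
        mask = rng.random((1, 10, 10)) < 0.6
        out = erode_mask(mask, 1)
        assert not np.any(out & ~mask)

    def test_slices_independent(self):
        """No erosion coupling across the slab axis."""
        mask = np.zeros((2, 5, 5), dtype=bool)
        mask[0, 1:4, 1:4] = True
        out = erode_mask(mask, 1)
        assert out[0, 2, 2] and out.sum() == 1


class TestDownsample:
    def test_constant_map_shrinks(self):
        vmap = make_map(np.full((9, 12), 7.0), np.ones((9, 12), dtype=bool))
        out = downsample_blocks(vmap)
        assert out.mask.shape == (1, 3, 4)
        np.testing.assert_allclose(out.velocity["FH"][out.mask], 7.0)

    def test_single_block_mean(self):
        vals = np.arange(1.0, 10.0).reshape(3, 3)
        vmap = make_map(vals, np.ones((3, 3), dtype=bool))
        out = downsample_blocks(vmap)
        assert out.velocity["FH"][0, 0, 0] == pytest.approx(5.0)

    def test_out_of_mask_block(self):
        vals = np.ones((3, 6))
        mask = np.zeros((3, 6), dtype=bool)
        mask[:, 3:] = True
        out = downsample_blocks(make_map(vals, mask))
        assert not out.mask[0, 0, 0] and out.mask[0, 0, 1]

    def test_min_count_threshold(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask.flat[:4] = True  # 4 of 9 in-mask < default min_count 5
        out = downsample_blocks(make_map(np.ones((3, 3)), mask))
        assert not out.mask.any()
        out2 = downsample_blocks(make_map(np.ones((3, 3)), mask), min_count=4)
        assert out2.mask.all()

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = rng.normal(size=(10, 11))
            mask = rng.random((10, 11)) < 0.7
            out = downsample_blocks(make_map(vals, mask))
            means, omask = brute_downsample(vals, mask, (3, 3), 5)
            np.testing.assert_array_equal(out.mask[0], omask)
            np.testing.assert_allclose(
                out.velocity["FH"][0][omask], means[omask], rtol=1e-12
            )

    def test_mean_preserved_over_full_blocks(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(9, 9))
        vmap = make_map(vals, np.ones((9, 9), dtype=bool))
        out = downsample_blocks(vmap)
        assert np.mean(out.velocity["FH"][out.mask]) == pytest.approx(
            np.mean(vals), rel=1e-12
        )

    def test_downsampled_grid_geometry(self):
        """Output voxels are 3× larger and centred on their source blocks."""
        vmap = make_map(np.zeros((9, 9)), np.ones((9, 9), dtype=bool))
        out = downsample_blocks(vmap)
        np.testing.assert_allclose(out.grid.voxel_size_mm, [10.0, 3.75, 3.75])
        # centre of output voxel (0,0,0) = centre of input voxel (0,1,1)
        np.testing.assert_allclose(
            out.grid.index_to_mm(np.zeros(3))[0],
            vmap.grid.index_to_mm(np.array([0.0, 1.0, 1.0]))[0],
        )

    def test_overlapping_variant_keeps_shape(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(9, 9))
        vmap = make_map(vals, np.ones((9, 9), dtype=bool))
        out = downsample_blocks(vmap, overlapping=True)
        assert out.mask.shape == vmap.mask.shape
        # interior pixel equals its 3×3 neighbourhood mean
        assert out.velocity["FH"][0, 4, 4] == pytest.approx(np.mean(vals[3:6, 3:6]))

    def test_block_too_small_rejected(self):
        vmap = make_map(np.ones((6, 6)), np.ones((6, 6), dtype=bool))
        with pytest.raises(ValueError):
            downsample_blocks(vmap, block=(1, 3))


def test_nifti_round_trip(tmp_path, stub_constant, small_grid, window):
    vmap = resample_to_voxels(stub_constant, small_grid, window)
    vmap.to_nifti(tmp_path / "ref")
    back = VoxelVelocityMap.from_nifti(tmp_path / "ref")
    np.testing.assert_array_equal(back.mask, vmap.mask)
    np.testing.assert_allclose(
        back.velocity["FH"][back.mask], vmap.velocity["FH"][vmap.mask], rtol=1e-6
    )
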