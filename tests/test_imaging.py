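"""Segmentation, spot and marker quantification from 3D stacks."""

import numpy as np
import pytest

from burststage import imaging as im
from burststage import simulate as sim
from burststage.errors import SegmentationError


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestSegmentation:
    def test_noiseless_three_level_stack_recovered_exactly(self, noiseless_render):
        m = im.segment_two_step_kmeans(noiseless_render.stack)
        assert np.array_equal(m.cell_mask, noiseless_render.cell_mask)
        assert np.array_equal(m.nuclear_mask, noiseless_render.nuclear_mask)

    def test_snr5_masks_overlap_ground_truth(self, snr5_render):
        m = im.segment_two_step_kmeans(snr5_render.stack)
        assert iou(m.cell_mask, snr5_render.cell_mask) >= 0.9
        assert iou(m.nuclear_mask, snr5_render.nuclear_mask) >= 0.85

    def test_masks_nest(self, snr5_render):
        m = im.segment_two_step_kmeans(snr5_render.stack)
        assert not np.any(m.nuclear_mask & ~m.cell_mask)

    def test_uniform_stack_raises_segmentation_error(self):
        stack = im.ImageStack(voxels=np.full((10, 20, 20), 7.0))
        with pytest.raises(SegmentationError):
            im.segment_two_step_kmeans(stack)

    def test_centroid_outside_bounds_rejected(self, noiseless_render):
        with pytest.raises(ValueError):
            im.segment_two_step_kmeans(noiseless_render.stack, centroid=(1e4, 0))


class TestQuantifySpot:
    def make_stack(self, fill=200.0):
        return np.full((30, 120, 120), fill)  # 10.2 x 10.2 x 15 um

    def test_uniform_spot_and_background_regions(self):
        vox = self.make_stack(200.0)
        stack = im.ImageStack(voxels=vox)
        spot = (3.0, 3.0, 7.5)
        vox2 = vox.copy()
        mask = im._ovoid_mask(stack, spot, (0.5, 0.5, 1.5))
        vox2[mask] = 1000.0
        stack2 = im.ImageStack(voxels=vox2, voxel_size_nm=stack.voxel_size_nm)
        meas = im.quantify_spot(stack2, spot, (6.0, 3.0, 7.5))
        assert meas.raw_mean == 1000.0
        assert meas.background_mean == 200.0
        assert meas.corrected == 800.0

    def test_self_subtraction_with_identical_region_sizes(self):
        stack = im.ImageStack(voxels=self.make_stack())
        spot = (3.0, 3.0, 7.5)
        a = im.quantify_spot(stack, spot, spot, ovoid_um=(3.0, 3.0, 3.0),
                             background_um=(3.0, 3.0, 3.0))
        # same centre, flat field: raw and background agree exactly
        assert a.corrected == 0.0

    def test_out_of_bounds_region_rejected(self):
        stack = im.ImageStack(voxels=self.make_stack())
        with pytest.raises(ValueError):
            im.quantify_spot(stack, (0.1, 0.1, 0.1), (3.0, 3.0, 7.5))

    def test_gaussian_spot_matches_quadrature_oracle(self):
        # corrected intensity of a noiseless rendered Gaussian spot equals the
        # analytic Gaussian averaged over the ovoid's voxel centres
        r = sim.render_stack(sim.StackSpec(noise_sd=0.0), seed=1)
        bg_center = im.default_background_center(r.stack, r.spot_center_um, r.nuclear_mask)
        meas = im.quantify_spot(r.stack, r.spot_center_um, bg_center)
        mask = im._ovoid_mask(r.stack, r.spot_center_um, (0.5, 0.5, 1.5))
        x, y, z = sim._coordinate_grids_um(r.spec.shape, r.spec.voxel_size_nm)
        cx, cy, cz = r.spot_center_um
        gauss = r.spec.spot_amplitude * np.exp(
            -((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) / (2 * r.spec.spot_sigma_um**2)
        )
        oracle = float(gauss[mask].mean())
        assert abs(meas.corrected - oracle) / oracle < 0.05

    def test_shift_and_scale_equivariance(self):
        r = sim.render_stack(sim.StackSpec(noise_sd=0.0), seed=1)
        bg = im.default_background_center(r.stack, r.spot_center_um, r.nuclear_mask)
        base = im.quantify_spot(r.stack, r.spot_center_um, bg).corrected
        shifted = im.ImageStack(voxels=r.stack.voxels + 123.0,
                                voxel_size_nm=r.stack.voxel_size_nm)
        scaled = im.ImageStack(voxels=r.stack.voxels * 2.5,
                               voxel_size_nm=r.stack.voxel_size_nm)
        assert np.isclose(im.quantify_spot(shifted, r.spot_center_um, bg).corrected, base)
        assert np.isclose(im.quantify_spot(scaled, r.spot_center_um, bg).corrected, 2.5 * base)


class TestDetectSpot:
    def test_noiseless_spot_found_within_one_voxel(self):
        r = sim.render_stack(sim.StackSpec(noise_sd=0.0), seed=1)
        found = im.detect_spot(r.stack, r.nuclear_mask)
        assert found is not None
        vx, vy, vz = r.stack.voxel_size_um
        diff = np.abs(np.array(found) - np.array(r.spot_center_um))
        assert diff[0] <= vx and diff[1] <= vy and diff[2] <= vz

    def test_spotless_stack_returns_none(self, noiseless_render):
        assert im.detect_spot(noiseless_render.stack, noiseless_render.nuclear_mask) is None

    def test_brighter_of_two_spots_wins_at_snr5(self):
        spec = sim.StackSpec(noise_sd=0.0, spot_amplitude=0.0)
        r = sim.render_stack(spec, seed=3)
        x, y, z = sim._coordinate_grids_um(spec.shape, spec.voxel_size_nm)
        vox = r.stack.voxels.copy()
        bright_um = np.array(r.spot_center_um) + np.array([-2.5, -1.5, 0.0])
        dim_um = np.array(r.spot_center_um)
        for c_um, amp in [(bright_um, 800.0), (dim_um, 400.0)]:
            d2 = (x - c_um[0]) ** 2 + (y - c_um[1]) ** 2 + (z - c_um[2]) ** 2
            vox += amp * np.exp(-d2 / (2 * 0.25**2))
        rng = np.random.default_rng(13)
        vox = np.clip(vox + rng.normal(0, 50.0, vox.shape), 0, None)
        stack = im.ImageStack(voxels=vox, voxel_size_nm=spec.voxel_size_nm)
        found = im.detect_spot(stack, r.nuclear_mask)
        assert found is not None
        assert np.linalg.norm(np.array(found) - bright_um) < np.linalg.norm(
            np.array(found) - dim_um
        )

    def test_empty_nuclear_mask_rejected(self, noiseless_render):
        with pytest.raises(ValueError):
            im.detect_spot(noiseless_render.stack, np.zeros_like(noiseless_render.nuclear_mask))


class TestMeasureMarker:
    def test_flat_background_recovers_added_level(self, noiseless_render):
        mk = sim.render_marker_stack(noiseless_render, 80.0, "CD71")
        assert abs(im.measure_marker(mk, noiseless_render.cell_mask) - 80.0) < 0.5

    def test_linear_gradient_background_within_5_percent(self, noiseless_render):
        zz, yy, xx = np.indices(noiseless_render.spec.shape)
        vox = 100.0 + 0.5 * xx + 0.3 * yy
        vox[noiseless_render.cell_mask] += 60.0
        stack = im.ImageStack(voxels=vox, voxel_size_nm=noiseless_render.spec.voxel_size_nm)
        got = im.measure_marker(stack, noiseless_render.cell_mask)
        assert abs(got - 60.0) / 60.0 < 0.05

    def test_whole_image_mask_rejected(self, noiseless_render):
        mask = np.ones(noiseless_render.spec.shape, dtype=bool)
        with pytest.raises(ValueError):
            im.measure_marker(noiseless_render.stack, mask)

    def test_shift_equivariance(self, noiseless_render):
        mk = sim.render_marker_stack(noiseless_render, 80.0, "CD71")
        shifted = im.ImageStack(voxels=mk.voxels + 50.0, voxel_size_nm=mk.voxel_size_nm)
        a = im.measure_marker(mk, noiseless_render.cell_mask)
        b = im.measure_marker(shifted, noiseless_render.cell_mask)
        assert abs(a - b) < 1e-6


class TestCellSize:
    def test_sphere_area_close_to_circle(self, noiseless_render):
        got = im.cell_size(noiseless_render.cell_mask, noiseless_render.spec.voxel_size_nm)
        r = noiseless_render.spec.cell_radius_um
        vx = noiseless_render.spec.voxel_size_nm[0] / 1000
        ring = 2 * np.pi * r * vx  # one pixel-wide ring
        assert abs(got - np.pi * r**2) <= ring

    def test_single_voxel_mask(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        assert np.isclose(im.cell_size(mask, (86.0, 86.0, 500.0)), 0.086**2)

    def test_z_symmetric_mask_uses_middle_slice(self):
        mask = np.zeros((7, 9, 9), dtype=bool)
        mask[2:5, 3:6, 3:6] = True  # symmetric about z=3
        got = im.cell_size(mask, (1000.0, 1000.0, 1000.0))
        assert got == 9.0  # 3x3 pixels of 1 um^2


class TestStackIO:
    def test_tiff_round_trip_preserves_voxels_and_size(self, tmp_path, noiseless_render):
        path = tmp_path / "stack.tif"
        im.write_stack_tiff(noiseless_render.stack, path)
        back = im.read_stack_tiff(path)
        assert np.allclose(back.voxels, noiseless_render.stack.voxels)
        assert np.allclose(back.voxel_size_nm, noiseless_render.stack.voxel_size_nm, rtol=1e-4)
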