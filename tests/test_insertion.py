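"""Rescale decode, background baseline estimation, insertion maps and
sinogram summation."""

import numpy as np
import pytest

from petinsert import (
    DicomLikeSeries,
    InsertionPlan,
    Sinogram,
    SphereSpec,
    SystemModel,
    VoiSpec,
    VolumeImage,
    VoxelGrid,
    build_insertion_map,
    estimate_background_ac,
    forward_project,
    generate_sphere_mask,
    insert_into_sinogram,
    mlem_reconstruct,
    poisson_realize,
    series_to_activity,
)


class TestSeriesToActivity:
    def test_rescale_arithmetic(self):
        g = VoxelGrid((2, 2, 1))
        s = DicomLikeSeries(
            [np.full((2, 2), 1000.0)], np.array([0.5]), np.array([0.0]), g
        )
        assert np.allclose(series_to_activity(s).values, 500.0)

    def test_unit_slope_zero_intercept_is_identity(self, rng):
        g = VoxelGrid((4, 4, 2))
        slices = [rng.integers(0, 100, (4, 4)).astype(float) for _ in range(2)]
        s = DicomLikeSeries(slices, np.ones(2), np.zeros(2), g)
        out = series_to_activity(s)
        assert np.array_equal(out.values[:, :, 0], slices[0])

    def test_per_slice_tags_applied_per_slice(self):
        g = VoxelGrid((2, 2, 2))
        s = DicomLikeSeries(
            [np.full((2, 2), 10.0), np.full((2, 2), 10.0)],
            np.array([1.0, 2.0]),
            np.array([0.0, 5.0]),
            g,
        )
        out = series_to_activity(s)
        assert np.allclose(out.values[:, :, 0], 10.0)
        assert np.allclose(out.values[:, :, 1], 25.0)


class TestBackgroundEstimate:
    def _vois(self, grid, n=4):
        cx, cy, cz = grid.center_mm()
        offs = [(-10, -10), (-10, 10), (10, -10), (10, 10)][:n]
        return [VoiSpec((cx + dx, cy + dy, cz), 8.0) for dx, dy in offs]

    def test_uniform_image_returns_uniform_value(self, small_grid):
        img = VolumeImage(small_grid, np.full(small_grid.dims, 5520.0), "Bq/mL")
        est = estimate_background_ac(img, self._vois(small_grid))
        assert est == pytest.approx(5520.0, rel=1e-12)

    def test_mean_of_voi_means(self, small_grid):
        """Two VOIs sitting in regions of value 4 and 6 average to 5."""
        g = small_grid
        vals = np.full(g.dims, 4.0)
        vals[16:, :, :] = 6.0  # x >= half: value 6
        img = VolumeImage(g, vals)
        cx, cy, cz = g.center_mm()
        vois = [VoiSpec((cx - 12, cy, cz), 8.0), VoiSpec((cx + 12, cy, cz), 8.0)]
        est = estimate_background_ac(img, vois)
        assert est == pytest.approx(5.0, rel=1e-12)

    def test_empty_voi_list_rejected(self, small_grid):
        img = VolumeImage(small_grid, np.zeros(small_grid.dims))
        with pytest.raises(ValueError):
            estimate_background_ac(img, [])

    def test_out_of_bounds_voi_rejected(self, small_grid):
        img = VolumeImage(small_grid, np.zeros(small_grid.dims))
        with pytest.raises(Exception):
            estimate_background_ac(img, [VoiSpec((0.0, 0.0, 0.0), 10.0)])

    def test_recovers_true_background_on_noisy_reconstruction(self, rng):
        """Seeded noisy baseline acquisition: the VOI estimate lands within
        3 standard errors of the true 5.52 kBq/mL background."""
        grid = VoxelGrid((48, 48, 3), (2.5, 2.5, 2.8))
        model = SystemModel.for_grid(grid, n_angles=48, sensitivity=5e-4)
        cx, cy, _ = grid.center_mm()
        xx, yy = np.meshgrid(grid.centers(0) - cx, grid.centers(1) - cy, indexing="ij")
        disc = (xx**2 + yy**2) <= 50.0**2
        truth = 5520.0
        img = VolumeImage(
            grid, np.where(disc, truth, 0.0)[:, :, None] * np.ones((1, 1, 3)), "Bq/mL"
        )
        ests = []
        for seed in (1, 2, 3):
            sino = poisson_realize(forward_project(img, model, duration_s=300.0), seed)
            rec = mlem_reconstruct(sino, model, grid, iterations=20)
            vois = self._vois(grid)
            ests.append(estimate_background_ac(rec, vois))
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth) < max(3 * se, 0.02 * truth)


class TestInsertionMap:
    def _mask(self, grid, d=8.0):
        c = grid.center_mm()
        return generate_sphere_mask(grid, SphereSpec(c, d), 8)

    def test_interior_concentration_from_printed_filling(self, small_grid):
        """background 5.44 kBq/mL x SBR 3.93 -> 21.38 kBq/mL inside."""
        amap = build_insertion_map([self._mask(small_grid)], 5.44, 3.93)
        interior = amap.values[amap.values == amap.values.max()]
        assert interior[0] == pytest.approx(21.38, abs=0.005)

    def test_zero_sbr_gives_zero_map(self, small_grid):
        amap = build_insertion_map([self._mask(small_grid)], 5440.0, 0.0)
        assert np.all(amap.values == 0)

    def test_surface_voxel_scales_with_fraction(self, small_grid):
        mask = self._mask(small_grid)
        amap = build_insertion_map([mask], 1000.0, 2.0)
        assert np.allclose(amap.values, mask.values * 2000.0)

    def test_overlapping_masks_rejected(self, small_grid):
        m = self._mask(small_grid)
        with pytest.raises(ValueError):
            build_insertion_map([m, m], 1000.0, 2.0)


class TestInsertIntoSinogram:
    def _setup(self, grid, model, rng):
        bg = VolumeImage(grid, rng.uniform(100, 200, grid.dims), "Bq/mL")
        orig = poisson_realize(forward_project(bg, model, duration_s=60.0), 3)
        mask = generate_sphere_mask(grid, SphereSpec(grid.center_mm(), 8.0), 8)
        amap = build_insertion_map([mask], 5000.0, 4.0)
        return orig, amap

    def test_zero_map_returns_identical_sinogram(self, small_grid, small_model, rng):
        orig, _ = self._setup(small_grid, small_model, rng)
        zero = VolumeImage(small_grid, np.zeros(small_grid.dims), "Bq/mL")
        plan = InsertionPlan([], 0.0, 0.0, noise=True, seed=9)
        out = insert_into_sinogram(orig, zero, small_model, plan=plan)
        assert np.array_equal(out.counts, orig.counts)

    def test_noise_off_adds_exact_projection(self, small_grid, small_model, rng):
        orig, amap = self._setup(small_grid, small_model, rng)
        out = insert_into_sinogram(orig, amap, small_model, plan=None)
        expected = forward_project(amap, small_model, duration_s=orig.duration_s)
        assert np.allclose(out.counts - orig.counts, expected.counts)

    def test_insertion_never_decreases_bins(self, small_grid, small_model, rng):
        orig, amap = self._setup(small_grid, small_model, rng)
        plan = InsertionPlan([], 5000.0, 4.0, noise=True, seed=1)
        out = insert_into_sinogram(orig, amap, small_model, plan=plan)
        assert np.all(out.counts >= orig.counts)
        assert out.duration_s == orig.duration_s

    def test_noisy_insertion_mean_matches_expected_projection(self):
        """Binwise Monte-Carlo mean of (output - original) over many seeds
        approaches the expected projection."""
        grid = VoxelGrid((16, 16, 5), (4.0, 4.0, 4.0))
        model = SystemModel.for_grid(grid, n_angles=16, sensitivity=1e-2)
        orig = Sinogram(
            np.zeros(model.sino_shape(grid)), 60.0, model.model_id, is_expected=False
        )
        mask = generate_sphere_mask(grid, SphereSpec(grid.center_mm(), 12.0), 8)
        amap = build_insertion_map([mask], 1000.0, 4.0)
        expected = forward_project(amap, model, duration_s=60.0).counts
        n = 1000
        acc = np.zeros_like(expected)
        for seed in range(n):
            plan = InsertionPlan([], 1000.0, 4.0, noise=True, seed=seed)
            acc += insert_into_sinogram(orig, amap, model, plan=plan).counts
        mean = acc / n
        se = np.sqrt(np.maximum(expected, 1e-12) / n)
        dev = np.abs(mean - expected)
        # per-bin 3-sigma holds for ~99.7% of bins; allow the expected tail
        assert np.mean(dev <= 3 * se + 1e-9) >= 0.99
        assert np.all(dev <= 6 * se + 1e-9)

    def test_image_domain_noise_option(self, small_grid, small_model, rng):
        orig, amap = self._setup(small_grid, small_model, rng)
        plan = InsertionPlan([], 5000.0, 4.0, noise=True, seed=2,
                             noise_domain="image")
        out = insert_into_sinogram(orig, amap, small_model, plan=plan)
        assert np.all(out.counts >= orig.counts)

    def test_linear_regime_recovers_inserted_activity(self):
        """Reconstructing (baseline + noiseless insertion) minus the
        reconstructed baseline recovers >= 90% of the inserted total
        activity for the largest sphere."""
        grid = VoxelGrid((48, 48, 5), (2.5, 2.5, 2.8))
        model = SystemModel.for_grid(grid, n_angles=48)
        cx, cy, cz = grid.center_mm()
        xx, yy = np.meshgrid(grid.centers(0) - cx, grid.centers(1) - cy, indexing="ij")
        disc = (xx**2 + yy**2) <= 50.0**2
        bg = VolumeImage(
            grid, np.where(disc, 5000.0, 0.0)[:, :, None] * np.ones((1, 1, 5)), "Bq/mL"
        )
        baseline = forward_project(bg, model, duration_s=300.0)
        mask = generate_sphere_mask(grid, SphereSpec((cx, cy + 25.0, cz), 13.0), 8)
        amap = build_insertion_map([mask], 5000.0, 4.0)
        modified = insert_into_sinogram(baseline, amap, model, plan=None)
        rec_mod = mlem_reconstruct(modified, model, grid, iterations=100)
        rec_base = mlem_reconstruct(baseline, model, grid, iterations=100)
        diff = rec_mod.values - rec_base.values
        recovered = diff.sum() * grid.voxel_volume * 1e-3
        inserted = amap.total_activity_bq()
        assert recovered >= 0.9 * inserted


class TestInsertionPlanValidation:
    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            InsertionPlan([], -1.0, 2.0)
        with pytest.raises(ValueError):
            InsertionPlan([], 1.0, -2.0)
        with pytest.raises(ValueError):
            InsertionPlan([], 1.0, 2.0, noise_domain="bogus")
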