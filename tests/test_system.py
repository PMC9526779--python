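"""Forward/back projector pair: adjointness, mass conservation,
attenuation closed forms, Poisson realization, resolution blur."""

import numpy as np
import pytest

from petinsert import (
    EfficiencyMap,
    Sinogram,
    SystemModel,
    VolumeImage,
    VoxelGrid,
    attenuation_factors,
    back_project,
    blur_image,
    forward_project,
    poisson_realize,
)
from petinsert.core import GridMismatchError
from petinsert.system import MU_WATER_511KEV


def _rand_image(grid, rng):
    return VolumeImage(grid, rng.uniform(0, 1, grid.dims), "Bq/mL")


class TestForwardProject:
    def test_zero_image_gives_zero_sinogram(self, small_grid, small_model):
        img = VolumeImage(small_grid, np.zeros(small_grid.dims), "Bq/mL")
        sino = forward_project(img, small_model, duration_s=10.0)
        assert np.all(sino.counts == 0)
        assert sino.is_expected

    def test_per_angle_totals_identical(self, small_grid, disc_image):
        """Radon mass conservation: without attenuation/efficiency/blur the
        per-angle total expected counts are angle-independent."""
        model = SystemModel.for_grid(small_grid, n_angles=48, intrinsic_fwhm_mm=0.0)
        sino = forward_project(disc_image, model, duration_s=10.0)
        totals = sino.counts.sum(axis=2)  # (nz, n_angles)
        spread = (totals.max(axis=1) - totals.min(axis=1)) / totals.mean(axis=1)
        assert np.all(spread < 1e-6)

    def test_linearity(self, small_grid, small_model, rng):
        x = _rand_image(small_grid, rng)
        y = _rand_image(small_grid, rng)
        combo = VolumeImage(small_grid, 2.5 * x.values + 0.5 * y.values, "Bq/mL")
        fx = forward_project(x, small_model, duration_s=7.0).counts
        fy = forward_project(y, small_model, duration_s=7.0).counts
        fc = forward_project(combo, small_model, duration_s=7.0).counts
        assert np.allclose(fc, 2.5 * fx + 0.5 * fy, rtol=1e-10, atol=1e-12)

    def test_adjoint_identity_with_all_effects(
        self, small_grid, small_model, water_mu, rng
    ):
        """<A x, y> == <x, A^T y> with attenuation, efficiency and blur."""
        eff = EfficiencyMap(
            rng.uniform(0.5, 1.5, (small_model.n_angles, small_model.n_radial))
        )
        x = _rand_image(small_grid, rng)
        y = rng.uniform(0, 1, small_model.sino_shape(small_grid))
        ax = forward_project(x, small_model, water_mu, eff, duration_s=10.0).counts
        aty = back_project(
            Sinogram(y, 10.0, small_model.model_id, is_expected=True),
            small_model, small_grid, water_mu, eff,
        ).values
        lhs = float((ax * y).sum())
        rhs = float((x.values * aty).sum())
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_grid_mismatch_rejected(self, small_grid, small_model):
        other = VoxelGrid((16, 16, 3), (2.0, 2.0, 2.8))
        img = VolumeImage(other, np.zeros(other.dims), "Bq/mL")
        mu = VolumeImage(small_grid, np.zeros(small_grid.dims), "1/cm")
        with pytest.raises(GridMismatchError):
            forward_project(img, small_model, mu=mu, duration_s=1.0)

    def test_negative_activity_rejected(self, small_grid, small_model):
        img = VolumeImage(small_grid, np.full(small_grid.dims, -1.0), "Bq/mL")
        with pytest.raises(ValueError):
            forward_project(img, small_model, duration_s=1.0)


class TestBackProject:
    def test_zero_sinogram_gives_zero_image(self, small_grid, small_model):
        y = Sinogram(
            np.zeros(small_model.sino_shape(small_grid)), 1.0, is_expected=True
        )
        img = back_project(y, small_model, small_grid)
        assert np.all(img.values == 0)

    def test_one_hot_bin_backprojects_to_one_band(self, small_grid):
        """A single sinogram bin's column is supported on the (blurred)
        strip of its line of response."""
        model = SystemModel.for_grid(small_grid, n_angles=48, intrinsic_fwhm_mm=0.0)
        y = np.zeros(model.sino_shape(small_grid))
        ia, ir = 0, model.n_radial // 2  # angle 0: strips run along y
        y[1, ia, ir] = 1.0
        img = back_project(
            Sinogram(y, 1.0, model.model_id, is_expected=True), model, small_grid
        ).values
        assert np.all(img[:, :, [0, 2]] == 0)  # other slices untouched
        hit_cols = np.unique(np.nonzero(img[:, :, 1])[0])
        assert 1 <= len(hit_cols) <= 3  # strip width ~ pixel size


class TestAttenuation:
    def test_no_attenuation_gives_unit_factors(self, small_grid, small_model):
        mu = VolumeImage(small_grid, np.zeros(small_grid.dims), "1/cm")
        f = attenuation_factors(mu, small_model)
        assert np.allclose(f, 1.0)

    def test_water_disc_chord_closed_form(self, small_grid, small_model, water_mu):
        """Central LOR through a water disc of diameter 40 mm:
        factor = exp(-mu * 4 cm)."""
        f = attenuation_factors(water_mu, small_model)
        central = f[0, 0, (small_model.n_radial - 1) // 2]
        assert central == pytest.approx(np.exp(-MU_WATER_511KEV * 4.0), rel=0.01)

    def test_factors_bounded_and_monotone_in_mu(self, small_grid, small_model, water_mu):
        f1 = attenuation_factors(water_mu, small_model)
        f2 = attenuation_factors(
            VolumeImage(small_grid, 2.0 * water_mu.values, "1/cm"), small_model
        )
        assert np.all(f1 > 0) and np.all(f1 <= 1.0)
        assert np.all(f2 <= f1)

    def test_removing_attenuation_never_decreases_counts(
        self, small_grid, small_model, disc_image, water_mu
    ):
        with_mu = forward_project(disc_image, small_model, mu=water_mu, duration_s=5.0)
        without = forward_project(disc_image, small_model, duration_s=5.0)
        assert np.all(without.counts >= with_mu.counts - 1e-12)

    def test_negative_mu_rejected(self, small_grid, small_model):
        mu = VolumeImage(small_grid, np.full(small_grid.dims, -0.1), "1/cm")
        with pytest.raises(ValueError):
            attenuation_factors(mu, small_model)


class TestPoissonRealize:
    def test_zero_mean_gives_zero_counts(self, small_grid, small_model):
        e = Sinogram(np.zeros((2, 3, 4)), 1.0, is_expected=True)
        r = poisson_realize(e, seed=1)
        assert np.all(r.counts == 0)
        assert not r.is_expected

    def test_same_seed_is_reproducible(self):
        e = Sinogram(np.full((2, 3, 4), 50.0), 1.0, is_expected=True)
        a = poisson_realize(e, seed=42)
        b = poisson_realize(e, seed=42)
        assert np.array_equal(a.counts, b.counts)

    def test_sample_mean_and_variance_match_poisson(self):
        """Over many realizations of a mean-50 bin, the sample mean is
        within 3 CLT standard errors and the variance within 5%."""
        n = 10_000
        e = Sinogram(np.full((1, 1, n), 50.0), 1.0, is_expected=True)
        r = poisson_realize(e, seed=7).counts.ravel()
        assert abs(r.mean() - 50.0) < 3 * np.sqrt(50.0 / n)
        assert abs(r.var(ddof=1) - 50.0) / 50.0 < 0.05

    def test_negative_expected_rejected(self):
        e = Sinogram(np.zeros((1, 1, 1)), 1.0, is_expected=True)
        e.counts = np.array([[[-1.0]]])
        with pytest.raises(ValueError):
            poisson_realize(e, seed=0)


class TestBlur:
    def test_zero_fwhm_is_identity(self, small_grid, rng):
        img = _rand_image(small_grid, rng)
        assert blur_image(img, 0.0) is img

    def test_total_sum_conserved(self, small_grid, rng):
        img = _rand_image(small_grid, rng)
        out = blur_image(img, 5.0)
        assert out.values.sum() == pytest.approx(img.values.sum(), rel=1e-6)

    def test_impulse_response_matches_analytic_gaussian(self):
        g = VoxelGrid((65, 65, 1), (1.0, 1.0, 2.8))
        vals = np.zeros(g.dims)
        vals[32, 32, 0] = 1.0
        fwhm = 6.0
        out = blur_image(VolumeImage(g, vals), fwhm).values[:, :, 0]
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        xx, yy = np.meshgrid(np.arange(65) - 32.0, np.arange(65) - 32.0, indexing="ij")
        analytic = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        analytic /= analytic.sum()
        assert np.abs(out - analytic).max() < 1e-3 * analytic.max()

    def test_negative_fwhm_rejected(self, small_grid, rng):
        with pytest.raises(ValueError):
            blur_image(_rand_image(small_grid, rng), -1.0)
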