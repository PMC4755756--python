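"""Sphere integration, map statistics, periodic wrap."""

import math

import numpy as np
import pytest

from femose.core import MapGrid, Site, UnitCell
from femose.integrate import (IntegrationConfig, OutOfBoundsError,
                              TooFewVoxelsError, ZeroRmsError,
                              gaussian_sphere_response, integrate_sphere,
                              map_rms, peak_sigma_level)
from femose.synthetic import FixtureSpec, SyntheticScene, render_map


def _gaussian_grid(B=9.0, h=0.25, n=64, center=None, mass=1.0):
    """Analytic Gaussian of given total mass sampled on a cubic periodic grid."""
    cell = UnitCell(n * h, n * h, n * h)
    if center is None:
        center = np.array([n // 2 * h + 0.3 * h, n // 2 * h + 0.7 * h,
                           n // 2 * h + 0.2 * h])
    ax = np.arange(n) * h
    amp = mass * (4 * math.pi / B) ** 1.5
    # minimal-image distances so corner placements wrap correctly
    d = [np.minimum(np.abs(ax - c), n * h - np.abs(ax - c)) for c in center]
    dens = amp * np.exp(-4 * math.pi ** 2 *
                        (d[0][:, None, None] ** 2 + d[1][None, :, None] ** 2 +
                         d[2][None, None, :] ** 2) / B)
    return MapGrid(cell=cell, values=dens.astype(np.float32)), np.asarray(center)


def _brute_force_sphere_integral(B, center_offset, R=1.0, fine=10, h=0.25):
    """Dense quadrature of the analytic Gaussian over the sphere (oracle)."""
    hf = h / fine
    m = int(np.ceil(R / hf))
    fx = np.arange(-m, m + 1) * hf
    FX, FY, FZ = np.meshgrid(fx, fx, fx, indexing="ij")
    r2 = FX ** 2 + FY ** 2 + FZ ** 2
    mask = r2 <= R * R
    amp = (4 * math.pi / B) ** 1.5
    return float((amp * np.exp(-4 * math.pi ** 2 * r2[mask] / B)).sum() * hf ** 3)


class TestIntegrateSphere:
    def test_constant_field(self):
        cell = UnitCell(20, 20, 20)
        grid = MapGrid(cell, np.full((40, 40, 40), 2.5, dtype=np.float32))
        sd = integrate_sphere(grid, (10, 10, 10), IntegrationConfig(radius=1.5))
        assert sd.density == pytest.approx(2.5 * sd.n_voxels * grid.voxel_volume)

    def test_zero_map(self):
        cell = UnitCell(20, 20, 20)
        grid = MapGrid(cell, np.zeros((40, 40, 40), dtype=np.float32))
        assert integrate_sphere(grid, (10, 10, 10)).density == 0.0

    def test_voxel_sum_matches_brute_force_quadrature(self):
        """Voxel sum agrees with a 10x-finer quadrature oracle to <0.5%."""
        grid, center = _gaussian_grid(B=9.0, h=0.25)
        got = integrate_sphere(grid, center, IntegrationConfig()).density
        oracle = _brute_force_sphere_integral(9.0, center, h=0.25)
        assert got == pytest.approx(oracle, rel=0.005)

    def test_subgrid_trilinear_low_scatter(self):
        """Trilinear resampling: offset-to-offset scatter well below 1%."""
        vals = []
        for off in ((0.1, 0.4, 0.8), (0.6, 0.2, 0.9), (0.35, 0.75, 0.05)):
            n, h = 40, 0.5333
            center = np.array([n // 2 * h + o * h for o in off])
            grid, c = _gaussian_grid(B=18.0, h=h, n=n, center=center)
            cfg = IntegrationConfig(sampling="subgrid-trilinear")
            vals.append(integrate_sphere(grid, c, cfg).density)
        assert np.std(vals) / np.mean(vals) < 0.01

    def test_out_of_bounds_center(self):
        grid, _ = _gaussian_grid()
        with pytest.raises(OutOfBoundsError):
            integrate_sphere(grid, (100.0, 0.0, 0.0))

    def test_too_few_voxels(self):
        cell = UnitCell(20, 20, 20)
        grid = MapGrid(cell, np.zeros((10, 10, 10), dtype=np.float32))  # h=2 A
        with pytest.raises(TooFewVoxelsError):
            integrate_sphere(grid, (10, 10, 10), IntegrationConfig(radius=1.0))

    def test_translation_equivariance(self):
        """Shifting map and center by whole voxels leaves the integral fixed."""
        grid, center = _gaussian_grid()
        base = integrate_sphere(grid, center).density
        shift = (7, 3, 11)
        rolled = MapGrid(grid.cell, np.roll(grid.values, shift, axis=(0, 1, 2)))
        h = grid.cell.a / grid.dims[0]
        moved = center + np.array(shift) * h
        moved %= grid.cell.a
        assert integrate_sphere(rolled, moved).density == pytest.approx(
            base, rel=1e-6)

    def test_additivity_of_far_apart_peaks(self):
        """Disjoint spheres of a two-peak map match single-peak integrals."""
        n, h = 80, 0.25
        c1 = np.array([5.0, 5.0, 5.0])
        c2 = np.array([15.0, 15.0, 15.0])
        g1, _ = _gaussian_grid(h=h, n=n, center=c1)
        g2, _ = _gaussian_grid(h=h, n=n, center=c2)
        both = MapGrid(g1.cell, g1.values + g2.values)
        s1 = integrate_sphere(g1, c1).density
        s2 = integrate_sphere(g2, c2).density
        got = integrate_sphere(both, c1).density + \
            integrate_sphere(both, c2).density
        assert got == pytest.approx(s1 + s2, rel=1e-3)

    def test_periodic_wrap_peak_at_corner(self):
        """A peak at the cell corner integrates like one at the center."""
        n, h = 64, 0.25
        corner, _ = _gaussian_grid(h=h, n=n, center=np.zeros(3))
        mid = np.array([n // 2 * h] * 3)
        centered, _ = _gaussian_grid(h=h, n=n, center=mid)
        a = integrate_sphere(corner, np.zeros(3)).density
        b = integrate_sphere(centered, mid).density
        assert a == pytest.approx(b, rel=1e-6)


class TestMapStatistics:
    def test_rms_zero_and_constant(self):
        cell = UnitCell(10, 10, 10)
        zeros = MapGrid(cell, np.zeros((20, 20, 20), dtype=np.float32))
        assert map_rms(zeros) == 0.0
        const = MapGrid(cell, np.full((20, 20, 20), -3.0, dtype=np.float32))
        assert map_rms(const) == pytest.approx(3.0)

    def test_rms_of_unit_gaussian_noise(self, rng):
        cell = UnitCell(50, 50, 50)
        vals = rng.normal(0, 1, size=(100, 100, 100)).astype(np.float32)
        grid = MapGrid(cell, vals)
        assert map_rms(grid) == pytest.approx(1.00, abs=0.01)

    def test_sigma_level(self):
        cell = UnitCell(10, 10, 10)
        vals = np.zeros((20, 20, 20), dtype=np.float32)
        vals[10, 10, 10] = 5.0
        grid = MapGrid(cell, vals)
        rms = map_rms(grid)
        center = np.array([5.0, 5.0, 5.0])
        assert peak_sigma_level(grid, center) == pytest.approx(5.0 / rms)
        assert peak_sigma_level(grid, np.array([2.5, 2.5, 2.5])) == \
            pytest.approx(0.0, abs=1e-6)

    def test_sigma_level_zero_rms(self):
        cell = UnitCell(10, 10, 10)
        grid = MapGrid(cell, np.zeros((20, 20, 20), dtype=np.float32))
        with pytest.raises(ZeroRmsError):
            peak_sigma_level(grid, (5, 5, 5))

    def test_rendered_se_peak_detectable_above_5_sigma(self, default_scene):
        """At default noise the full Se2B peak stands far above 5 sigma."""
        x2b = [s for s in default_scene.belt_sites()
               if s.label == "X2B" and s.copy_id == 1][0]
        level = peak_sigma_level(default_scene.map, x2b.position)
        assert level > 5.0


class TestSphereResponse:
    def test_response_tracks_capture_fraction(self):
        """Voxel-sum response approximates the analytic sphere capture."""
        from scipy.stats import chi
        for B in (9.0, 18.0):
            resp = gaussian_sphere_response(B, 0.25, IntegrationConfig())
            sigma = math.sqrt(B / (8 * math.pi ** 2))
            assert resp == pytest.approx(chi.cdf(1.0 / sigma, 3), rel=0.01)

    def test_response_is_cached_and_deterministic(self):
        cfg = IntegrationConfig(sampling="subgrid-trilinear")
        a = gaussian_sphere_response(18.9, 0.5319, cfg)
        b = gaussian_sphere_response(18.9, 0.5319, cfg)
        assert a == b
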