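"""Fe calibration, occupancy conversion, detection floor, copy checks."""

import math

import numpy as np
import pytest

from femose.core import ScatteringTable, default_scattering_table
from femose.integrate import IntegrationConfig, SiteDensity
from femose.occupancy import (Calibration, CalibrationError, PairingError,
                              PeakModel, ScatteringRatioError,
                              SeOccupancyEstimator, calibrate,
                              cross_copy_check, detection_floor,
                              estimate_se_occupancy, quantify_scene)
from femose.synthetic import FixtureSpec, build_fixture, render_map


def _sd(density, label="X2B", **kw):
    return SiteDensity(label=label, density=density, n_voxels=30, peak=1.0, **kw)


class TestCalibrate:
    def test_identical_densities(self):
        cal = calibrate(np.full(30, 0.7))
        assert cal.d_fe_mean == pytest.approx(0.7)
        assert cal.cv_percent == pytest.approx(0.0, abs=1e-10)
        assert cal.n_ref == 30

    def test_small_scatter_cv(self):
        """{1.0, 1.0, 1.04} has a population CV of ~1.9%."""
        cal = calibrate(np.array([1.0, 1.0, 1.04]))
        assert round(cal.cv_percent, 1) == 1.9

    def test_warns_above_quality_bound(self, caplog):
        vals = np.array([1.0] * 15 + [1.12] * 15)  # CV ~ 5.7%
        with caplog.at_level("WARNING"):
            calibrate(vals)
        assert any("quality bound" in r.message for r in caplog.records)

    def test_rejects_gross_scatter(self):
        with pytest.raises(CalibrationError):
            calibrate(np.array([1.0] * 15 + [1.5] * 15))

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(CalibrationError):
            calibrate(np.array([]))
        with pytest.raises(CalibrationError):
            calibrate(np.array([1.0, -1.0]))

    def test_rejects_non_fe_reference(self):
        with pytest.raises(CalibrationError):
            calibrate([_sd(1.0, element="Se")])

    def test_default_noise_fixture_within_bound(self, default_scene):
        """Under the reference noise regime the Fe CV stays at or below 4%."""
        q = quantify_scene(default_scene)
        assert q.calibration.cv_percent <= 4.0


class TestEstimate:
    @pytest.fixture
    def cal(self):
        return calibrate(np.full(30, 1.0))

    @pytest.mark.parametrize("d_norm,mode,expected", [
        (2.56, "mixed", 1.0),   # full Se: 3.84/1.50
        (2.56, "free", 1.0),
        (0.16, "mixed", 0.0),   # pure S limit: 0.24/1.50
        (1.36, "mixed", 0.5),   # midpoint: (1.36-0.16)/(2.56-0.16)
    ])
    def test_known_conversions(self, cal, d_norm, mode, expected):
        res = estimate_se_occupancy(_sd(d_norm), cal, mode=mode)
        assert res.se_occupancy == pytest.approx(expected, abs=1e-12)

    def test_free_mode_ignores_sulfur_complement(self, cal):
        res = estimate_se_occupancy(_sd(1.28), cal, mode="free")
        assert res.se_occupancy == pytest.approx(0.5)

    def test_free_vs_mixed_inequality(self, cal):
        """free >= mixed - r_S/r_Se over the physical range; equal at full Se."""
        t = default_scattering_table()
        r_se, r_s = t.ratio("Se", "Fe"), t.ratio("S", "Fe")
        for d in np.linspace(0.0, r_se, 9):
            free = estimate_se_occupancy(_sd(d), cal, mode="free").raw_estimate
            mixed = estimate_se_occupancy(_sd(d), cal, mode="mixed").raw_estimate
            assert free >= mixed - r_s / r_se - 1e-12
        full = r_se
        assert estimate_se_occupancy(_sd(full), cal, mode="free").raw_estimate \
            == pytest.approx(
                estimate_se_occupancy(_sd(full), cal, mode="mixed").raw_estimate)

    def test_degenerate_scattering_table(self, cal):
        bad = ScatteringTable(12662.0, {"Se": 0.2, "S": 0.24, "Fe": 1.5})
        with pytest.raises(ScatteringRatioError):
            estimate_se_occupancy(_sd(1.0), cal, table=bad)

    def test_clamping_with_flag(self, cal):
        res = estimate_se_occupancy(_sd(2.60), cal, floor=0.02)
        assert res.raw_estimate > 1.0
        assert res.se_occupancy == 1.0
        assert res.clamped and "clamped" in res.flags

    def test_far_out_of_range_flagged_inconsistent(self, cal):
        res = estimate_se_occupancy(_sd(4.0), cal, floor=0.001)
        assert "inconsistent" in res.flags
        assert not res.clamped

    def test_uncertainty_floor(self):
        cal = calibrate(np.array([1.0, 1.0, 1.04]))
        res = estimate_se_occupancy(_sd(1.36), cal, floor=0.02)
        assert res.uncertainty >= 0.02
        expected = math.sqrt((res.raw_estimate * cal.cv) ** 2 + 0.02 ** 2)
        assert res.uncertainty == pytest.approx(expected)


class TestDetectionFloor:
    def _cal_in_mass_units(self):
        # corrected calibration: mean Fe total equals f''(Fe)
        return calibrate(np.full(30, 1.50))

    def test_noiseless_floor_is_zero(self):
        assert detection_floor(0.0, self._cal_in_mass_units()) == 0.0

    def test_two_percent_noise_gives_0_02(self):
        """RMS at 2% of the full Se peak height -> floor 0.02."""
        pm = PeakModel(resolution=1.6)
        se_peak = pm.peak_height(3.84, 9.9)
        floor = detection_floor(0.02 * se_peak, self._cal_in_mass_units(),
                                peak_model=pm)
        assert floor == pytest.approx(0.02, rel=1e-9)

    def test_floor_scales_linearly_with_rms(self):
        pm = PeakModel()
        se_peak = pm.peak_height(3.84, 9.9)
        f10 = detection_floor(0.10 * se_peak, self._cal_in_mass_units(),
                              peak_model=pm)
        assert f10 == pytest.approx(0.10, rel=1e-9)


class TestCrossCopy:
    def _res(self, label, p):
        from femose.occupancy import OccupancyResult
        return OccupancyResult(label=label, se_occupancy=p, uncertainty=0.02)

    def test_identical_copies(self):
        c = {l: self._res(l, 0.4) for l in ("X2B", "X5A")}
        devs, mx = cross_copy_check(c, dict(c))
        assert mx == 0.0

    def test_direct_difference(self):
        c1 = {"X2B": self._res("X2B", 0.50)}
        c2 = {"X2B": self._res("X2B", 0.55)}
        _, mx = cross_copy_check(c1, c2)
        assert mx == pytest.approx(0.05)

    def test_label_mismatch(self):
        with pytest.raises(PairingError):
            cross_copy_check({"X2B": self._res("X2B", 0.5)},
                             {"X5A": self._res("X5A", 0.5)})


class TestRecovery:
    def test_noiseless_recovery_within_0_01(self):
        """Planted mixed occupancies are recovered within 0.01 without noise."""
        for p in (0.0, 0.25, 0.75, 1.0):
            spec = FixtureSpec(seed=3, noise_rms=0.0).with_belt(
                {l: (p, 1 - p) for l in ("X2B", "X5A", "X3A")})
            scene = build_fixture(spec)
            render_map(scene)
            q = quantify_scene(scene)
            for copy in (1, 2):
                for lbl in ("X2B", "X5A", "X3A"):
                    assert q.per_copy[copy][lbl].raw_estimate == \
                        pytest.approx(p, abs=0.01)

    def test_sphere_estimate_agrees_with_quadrature_oracle(self):
        """Dual route: the grid-map pipeline estimate matches the estimate
        built from dense brute-force quadrature of the analytic forward model
        (sphere integrals normalized by analytic capture fractions)."""
        from scipy.stats import chi

        from femose.synthetic import b_eff
        p = 0.6
        spec = FixtureSpec(seed=5, noise_rms=0.0).with_belt(
            {l: (p, 1 - p) for l in ("X2B", "X5A", "X3A")})
        scene = build_fixture(spec)
        render_map(scene)
        q = quantify_scene(scene)
        t = default_scattering_table()
        res = spec.resolution

        def analytic_density(points):
            dens = np.zeros(len(points))
            for s in scene.sites:
                B = b_eff(s.b_factor, res)
                r2 = np.sum((points - s.position) ** 2, axis=1)
                near = r2 < 25.0
                for el, occ in ((s.element, s.occupancy), ("S", s.s_occupancy)):
                    if occ <= 0:
                        continue
                    amp = occ * t.f2(el) * (4 * math.pi / B) ** 1.5
                    dens[near] += amp * np.exp(-4 * math.pi ** 2 * r2[near] / B)
            return dens

        hf = 0.05
        ax = np.arange(-1.0, 1.0 + hf / 2, hf)
        FX, FY, FZ = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = (FX ** 2 + FY ** 2 + FZ ** 2) <= 1.0
        offsets = np.stack([FX[mask], FY[mask], FZ[mask]], axis=1)

        def quad_total(site):
            """Quadrature sphere integral, normalized by analytic capture."""
            integral = analytic_density(site.position + offsets).sum() * hf ** 3
            sigma = math.sqrt(b_eff(site.b_factor, res) / (8 * math.pi ** 2))
            return integral / chi.cdf(1.0 / sigma, 3)

        fe_mean = np.mean([quad_total(s) for s in scene.fe_sites()])
        site = [s for s in scene.belt_sites() if s.copy_id == 1][0]
        d_norm = quad_total(site) / fe_mean
        r_se, r_s = t.ratio("Se", "Fe"), t.ratio("S", "Fe")
        oracle_p = (d_norm - r_s) / (r_se - r_s)
        got = q.per_copy[1][site.label].raw_estimate
        assert got == pytest.approx(oracle_p, abs=0.01)
        assert oracle_p == pytest.approx(p, abs=0.01)

    def test_scale_invariance(self, default_scene):
        """Multiplying the map by a constant leaves occupancies unchanged."""
        import copy
        q1 = quantify_scene(default_scene)
        scaled = copy.copy(default_scene)
        from femose.core import MapGrid
        scaled.map = MapGrid(default_scene.map.cell,
                             default_scene.map.values * np.float32(3.7))
        q2 = quantify_scene(scaled)
        for copy_id in (1, 2):
            for lbl, r in q1.per_copy[copy_id].items():
                assert q2.per_copy[copy_id][lbl].se_occupancy == \
                    pytest.approx(r.se_occupancy, abs=1e-4)

    def test_monotone_in_planted_fraction(self):
        """Estimated occupancy strictly increases with the planted fraction."""
        estimates = []
        for p in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            spec = FixtureSpec(seed=9, noise_rms=0.0).with_belt(
                {l: (p, 1 - p) for l in ("X2B", "X5A", "X3A")})
            scene = build_fixture(spec)
            render_map(scene)
            q = quantify_scene(scene)
            estimates.append(q.per_copy[1]["X2B"].raw_estimate)
        assert np.all(np.diff(estimates) > 0)

    def test_copy_deviation_within_anchor(self, make_scene):
        """Equal planted occupancies: copy deviation stays within ~5 points."""
        ok = 0
        n = 12
        for seed in range(n):
            scene = make_scene(seed=200 + seed,
                               belt={l: (0.5, 0.5) for l in
                                     ("X2B", "X5A", "X3A")})
            q = quantify_scene(scene)
            if max(q.copy_deviation.values()) <= 0.05:
                ok += 1
        assert ok >= 0.9 * n

    def test_free_mode_remote_site(self, make_scene):
        scene = make_scene(seed=33, noise_rms=0.0, remote_se_occupancy=0.2)
        q = quantify_scene(scene)
        assert q.averaged["RSE"].se_occupancy == pytest.approx(0.2, abs=0.02)


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = SeOccupancyEstimator(mode="free", radius=1.2)
        params = est.get_params()
        assert params["mode"] == "free"
        est2 = SeOccupancyEstimator().set_params(**params)
        assert est2.radius == 1.2

    def test_predict_requires_fit(self):
        with pytest.raises(RuntimeError):
            SeOccupancyEstimator().predict_results([_sd(1.0)])

    def test_fit_predict_plain_path(self):
        est = SeOccupancyEstimator(b_correction=False)
        est.fit([_sd(1.0, label=f"FE{i}", element="Fe") for i in range(30)])
        p = est.predict([_sd(1.36)])
        assert p[0] == pytest.approx(0.5)
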