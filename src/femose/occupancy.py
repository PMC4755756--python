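"""Se occupancy estimation by internal Fe calibration and f'' scaling.

The core statistic: with 30 full-occupancy Fe atoms as an internal anomalous
reference, a site's sphere-integrated anomalous density D is normalized as
D_norm = D / D_mean(Fe) and converted to a Se fraction using the f'' ratios
r_X = f''(X)/f''(Fe) at the data-collection energy.

For a belt chalcogen site modelled as a Se/S two-species mixture whose
fractions sum to one, the residual anomalous scattering of sulfur
(f''(S)/f''(Se) = 6.3% at 12,662 eV) enters as

    p_Se = (D_norm - r_S) / (r_Se - r_S)          ("mixed-chalcogen" mode)

while an isolated Se site with no complementary sulfur uses

    p_Se = D_norm / r_Se                           ("free" mode)

Uncertainty combines the Fe-calibration scatter (coefficient of variation,
quality bound 4%) in quadrature with the map-noise detection floor (the
occupancy whose expected peak height equals the map RMS; ~2% under the
default noise regime). The deviation between the two crystallographically
independent cofactor copies provides an independent empirical uncertainty
check (:func:`cross_copy_check`).

When sites are quantified through :func:`quantify_scene` (or the sklearn-style
:class:`SeOccupancyEstimator` with a grid spacing supplied), each integrated
density is first divided by the integration mode's measured response to a
Gaussian peak of that site's effective B (see
:func:`femose.integrate.gaussian_sphere_response`), converting densities to
total-peak-mass units. The mixing formulas above are then exact for the
Gaussian forward model regardless of B differences between Se and Fe sites or
of the sampling mode's systematic loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .core import ScatteringTable, default_scattering_table
from .integrate import (IntegrationConfig, SiteDensity, gaussian_sphere_response,
                        integrate_sphere, map_rms)
from .synthetic import BELT_LABELS, SyntheticScene, b_eff

__all__ = [
    "CalibrationError", "ScatteringRatioError", "InconsistentSiteError",
    "PairingError", "PeakModel", "Calibration", "OccupancyResult",
    "calibrate", "estimate_se_occupancy", "detection_floor",
    "cross_copy_check", "SeOccupancyEstimator", "SceneQuantification",
    "quantify_scene",
]

logger = logging.getLogger(__name__)

CV_WARN_PERCENT = 4.0     # reference-quality bound on Fe scatter
CV_ERROR_PERCENT = 15.0


class CalibrationError(ValueError):
    pass


class ScatteringRatioError(ValueError):
    """r_Se <= r_S: the two-species mixing formula is degenerate."""


class InconsistentSiteError(ValueError):
    """Site density negative beyond what map noise can explain."""


class PairingError(KeyError):
    """Cross-copy comparison with mismatched site labels."""


@dataclass(frozen=True)
class PeakModel:
    """Gaussian peak model linking atomic B, map resolution and peak shape."""

    resolution: float = 1.6

    @property
    def b_blur(self) -> float:
        return (self.resolution / 1.6) ** 2 * 9.0

    def b_eff(self, b_factor: float) -> float:
        return b_factor + self.b_blur

    def peak_height(self, total_mass: float, b_factor: float) -> float:
        """Peak maximum of a Gaussian of given total mass and atomic B."""
        B = self.b_eff(b_factor)
        return total_mass * (4.0 * math.pi / B) ** 1.5


@dataclass
class Calibration:
    """Internal Fe reference: mean full-occupancy density and its scatter."""

    densities: np.ndarray
    d_fe_mean: float
    cv_percent: float
    n_ref: int

    @property
    def cv(self) -> float:
        return self.cv_percent / 100.0


def calibrate(reference: list[SiteDensity] | np.ndarray) -> Calibration:
    """Mean and coefficient of variation of the Fe reference densities.

    A CV above 4% is logged as a warning (reference quality bound); above 15%
    the calibration is rejected.
    """
    if isinstance(reference, np.ndarray) or (
            len(reference) and isinstance(reference[0], (int, float, np.floating))):
        dens = np.asarray(reference, dtype=float)
    else:
        for sd in reference:
            if sd.element is not None and sd.element != "Fe":
                raise CalibrationError(
                    f"reference site {sd.label} is {sd.element}, not Fe")
        dens = np.array([sd.density for sd in reference], dtype=float)
    if dens.size == 0:
        raise CalibrationError("empty reference list")
    mean = float(dens.mean())
    if mean <= 0:
        raise CalibrationError("non-positive mean reference density")
    cv = float(dens.std(ddof=0) / mean * 100.0)
    if cv > CV_ERROR_PERCENT:
        raise CalibrationError(
            f"Fe reference CV {cv:.1f}% exceeds {CV_ERROR_PERCENT}%")
    if cv > CV_WARN_PERCENT:
        logger.warning("Fe reference CV %.1f%% exceeds the %.0f%% quality bound",
                       cv, CV_WARN_PERCENT)
    return Calibration(densities=dens, d_fe_mean=mean, cv_percent=cv,
                       n_ref=int(dens.size))


@dataclass
class OccupancyResult:
    label: str
    se_occupancy: float
    uncertainty: float
    below_detection: bool = False
    copy_id: int | None = None
    clamped: bool = False
    flags: list[str] = field(default_factory=list)
    raw_estimate: float = float("nan")
    d_norm: float = float("nan")


def estimate_se_occupancy(site: SiteDensity, cal: Calibration,
                          table: ScatteringTable | None = None,
                          mode: str = "mixed", *,
                          floor: float = 0.0,
                          noise_floor_density: float = 0.0) -> OccupancyResult:
    """Convert one integrated site density into a Se occupancy fraction.

    ``site.density`` and the calibration must be in the same units (both raw
    sphere integrals, or both response-corrected totals). ``floor`` is the
    detection floor in occupancy units; ``noise_floor_density`` (density
    units) guards against unphysically negative densities.
    """
    if mode not in ("mixed", "free"):
        raise ValueError("mode must be 'mixed' or 'free'")
    table = table or default_scattering_table()
    r_se = table.ratio("Se", "Fe")
    r_s = table.ratio("S", "Fe")
    if r_se <= r_s:
        raise ScatteringRatioError("f'' ratio of Se must exceed that of S")
    if noise_floor_density > 0 and site.density < -3.0 * noise_floor_density:
        raise InconsistentSiteError(
            f"site {site.label}: density {site.density:.3g} below -3x noise floor")
    d_norm = site.density / cal.d_fe_mean
    if mode == "mixed":
        p = (d_norm - r_s) / (r_se - r_s)
    else:
        p = d_norm / r_se
    unc = math.sqrt((p * cal.cv) ** 2 + floor ** 2)
    flags: list[str] = []
    clamped = False
    p_out = p
    if p < 0.0 or p > 1.0:
        bound = 0.0 if p < 0 else 1.0
        if abs(p - bound) <= 2.0 * unc:
            p_out = bound
            clamped = True
            flags.append("clamped")
        else:
            flags.append("inconsistent")
    return OccupancyResult(
        label=site.label, se_occupancy=p_out, uncertainty=unc,
        below_detection=bool(p_out < floor), copy_id=site.copy_id,
        clamped=clamped, flags=flags, raw_estimate=p, d_norm=d_norm)


def detection_floor(rms: float, cal: Calibration,
                    table: ScatteringTable | None = None, *,
                    peak_model: PeakModel | None = None,
                    se_b_factor: float = 9.9) -> float:
    """Occupancy whose expected Se peak height equals the map RMS.

    The expected full-occupancy Se peak is predicted from the calibration
    (which must be in total-peak-mass units) via the Gaussian peak model at
    the reference Se B-factor. A noiseless map gives 0; the default noise
    regime (RMS = 2% of the Se peak) gives 0.02, and the floor scales
    linearly with the map RMS.
    """
    if rms < 0:
        raise ValueError("map RMS must be >= 0")
    table = table or default_scattering_table()
    peak_model = peak_model or PeakModel()
    se_total = cal.d_fe_mean * table.ratio("Se", "Fe")
    peak = peak_model.peak_height(se_total, se_b_factor)
    return float(rms / peak)


def cross_copy_check(copy1: dict[str, OccupancyResult],
                     copy2: dict[str, OccupancyResult]
                     ) -> tuple[dict[str, float], float]:
    """Per-label |p1 - p2| and the maximum across labels.

    The largest copy-to-copy deviation is the empirical occupancy uncertainty
    anchor (~5 percentage points under reference conditions).
    """
    if set(copy1) != set(copy2):
        raise PairingError(
            f"label mismatch between copies: {sorted(copy1)} vs {sorted(copy2)}")
    if not copy1:
        raise PairingError("no site labels to compare")
    devs = {lbl: abs(copy1[lbl].se_occupancy - copy2[lbl].se_occupancy)
            for lbl in copy1}
    return devs, max(devs.values())


# ---------------------------------------------------------------------------
# sklearn-style estimator

class SeOccupancyEstimator(BaseEstimator):
    """Fe-calibrated Se occupancy estimator (fit on references, predict sites).

    Parameters
    ----------
    table : ScatteringTable, optional
        f'' table; defaults to the 12,662 eV values.
    mode : {"mixed", "free"}
        Mixed-chalcogen (Se+S sum to one) or free (isolated Se) conversion.
    resolution : float
        Map resolution (A) for the Gaussian peak model.
    grid_spacing : float or None
        Map grid spacing (A). When given together with ``b_correction=True``,
        measured densities are divided by the integration mode's Gaussian
        response at each site's effective B before the ratio algebra.
    radius, sampling, subdivision
        Sphere-integration settings the densities were produced with (used
        only for the response correction).
    b_correction : bool
        Enable the per-B response correction.

    Attributes
    ----------
    calibration_ : Calibration
        Fitted Fe reference (in total-mass units if correcting).
    """

    def __init__(self, table: ScatteringTable | None = None,
                 mode: str = "mixed", resolution: float = 1.6,
                 grid_spacing: float | None = None, radius: float = 1.0,
                 sampling: str = "subgrid-trilinear", subdivision: int = 4,
                 b_correction: bool = True):
        self.table = table
        self.mode = mode
        self.resolution = resolution
        self.grid_spacing = grid_spacing
        self.radius = radius
        self.sampling = sampling
        self.subdivision = subdivision
        self.b_correction = b_correction

    # -- helpers -----------------------------------------------------------
    def _cfg(self) -> IntegrationConfig:
        return IntegrationConfig(radius=self.radius, sampling=self.sampling,
                                 subdivision=self.subdivision)

    def _correct(self, sd: SiteDensity) -> float:
        if not (self.b_correction and self.grid_spacing and sd.b_factor):
            return sd.density
        B = b_eff(sd.b_factor, self.resolution)
        resp = gaussian_sphere_response(B, self.grid_spacing, self._cfg())
        return sd.density / resp

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X: list[SiteDensity], y=None) -> "SeOccupancyEstimator":
        """Calibrate on full-occupancy Fe reference site densities."""
        corrected = [self._correct(sd) for sd in X]
        self.calibration_ = calibrate(np.asarray(corrected))
        return self

    def predict(self, X: list[SiteDensity], *, floor: float = 0.0) -> np.ndarray:
        """Se occupancy fractions for a list of site densities."""
        return np.array([r.se_occupancy
                         for r in self.predict_results(X, floor=floor)])

    def predict_results(self, X: list[SiteDensity], *,
                        floor: float = 0.0) -> list[OccupancyResult]:
        if not hasattr(self, "calibration_"):
            raise RuntimeError("estimator is not fitted")
        table = self.table or default_scattering_table()
        out = []
        for sd in X:
            corrected = SiteDensity(label=sd.label, density=self._correct(sd),
                                    n_voxels=sd.n_voxels, peak=sd.peak,
                                    element=sd.element, b_factor=sd.b_factor,
                                    copy_id=sd.copy_id)
            out.append(estimate_se_occupancy(corrected, self.calibration_,
                                             table, self.mode, floor=floor))
        return out


# ---------------------------------------------------------------------------
# scene-level quantification

@dataclass
class SceneQuantification:
    calibration: Calibration
    map_rms: float
    floor: float
    per_copy: dict[int, dict[str, OccupancyResult]]
    averaged: dict[str, OccupancyResult]
    copy_deviation: dict[str, float]
    site_densities: list[SiteDensity]


def _average_copies(per_copy: dict[int, dict[str, OccupancyResult]]
                    ) -> tuple[dict[str, OccupancyResult], dict[str, float]]:
    copies = sorted(per_copy)
    if len(copies) == 1:
        return dict(per_copy[copies[0]]), {}
    c1, c2 = per_copy[copies[0]], per_copy[copies[1]]
    devs, _ = cross_copy_check(c1, c2)
    averaged = {}
    for lbl in c1:
        p = 0.5 * (c1[lbl].se_occupancy + c2[lbl].se_occupancy)
        # half the copy difference enters as an empirical uncertainty component
        u = math.sqrt(0.25 * (c1[lbl].uncertainty ** 2 + c2[lbl].uncertainty ** 2)
                      + (0.5 * devs[lbl]) ** 2)
        averaged[lbl] = OccupancyResult(
            label=lbl, se_occupancy=p, uncertainty=u,
            below_detection=c1[lbl].below_detection and c2[lbl].below_detection,
            copy_id=None, clamped=c1[lbl].clamped or c2[lbl].clamped,
            flags=sorted(set(c1[lbl].flags) | set(c2[lbl].flags)))
    return averaged, devs


def _offcenter_mass_fraction(b_eff_val: float, distance: float,
                             radius: float) -> float:
    """Mass fraction of a Gaussian peak inside a sphere centered ``distance``
    away (noncentral chi-square radial CDF, 3 degrees of freedom)."""
    from scipy.stats import ncx2

    sigma2 = b_eff_val / (8.0 * math.pi ** 2)
    return float(ncx2.cdf(radius ** 2 / sigma2, 3, distance ** 2 / sigma2))


def _estimated_masses(scene: SyntheticScene, table: ScatteringTable,
                      per_label: dict[tuple[int, str], float] | None) -> np.ndarray:
    """Anomalous peak mass (electrons) per site from current estimates.

    Fe references are full occupancy by assumption; belt sites use the
    mixed-chalcogen model (S fraction = 1 - p); other Se sites Se only.
    """
    masses = np.empty(len(scene.sites))
    for k, s in enumerate(scene.sites):
        if s.element == "Fe":
            masses[k] = table.f2("Fe")
        else:
            p = 0.0
            if per_label is not None:
                p = min(max(per_label.get((s.copy_id, s.label), 0.0), 0.0), 1.0)
            if s.label in BELT_LABELS:
                masses[k] = p * table.f2("Se") + (1.0 - p) * table.f2("S")
            else:
                masses[k] = p * table.f2("Se")
    return masses


def quantify_scene(scene: SyntheticScene,
                   table: ScatteringTable | None = None,
                   cfg: IntegrationConfig | None = None, *,
                   b_correction: bool = True,
                   crosstalk_correction: bool = True) -> SceneQuantification:
    """Full quantification of one scene: integrate, calibrate, estimate.

    When no integration config is given the low-variance subgrid-trilinear
    mode is used. Belt sites use mixed-chalcogen mode; any other non-Fe site
    (e.g. the remote low-occupancy Se site) uses free mode.

    With ``crosstalk_correction`` a second pass subtracts the predicted
    in-sphere mass of neighboring peaks (Fe-chalcogen contacts are ~2.2 A,
    so tails bleed ~0.3% between spheres) using first-pass occupancy
    estimates, then recalibrates.
    """
    if scene.map is None:
        raise ValueError("scene has no rendered map")
    table = table or default_scattering_table()
    if cfg is None:
        cfg = IntegrationConfig(sampling="subgrid-trilinear")
    spec = scene.spec
    spacing = float(np.cbrt(scene.map.voxel_volume))
    est = SeOccupancyEstimator(
        table=table, resolution=spec.resolution, grid_spacing=spacing,
        radius=cfg.radius, sampling=cfg.sampling, subdivision=cfg.subdivision,
        b_correction=b_correction)

    densities = [integrate_sphere(scene.map, s.position, cfg, label=s.label,
                                  element=s.element, b_factor=s.b_factor,
                                  copy_id=s.copy_id)
                 for s in scene.sites]
    rms = map_rms(scene.map)
    pm = PeakModel(resolution=spec.resolution)

    def run_pass(contam_raw: np.ndarray):
        work = [SiteDensity(label=d.label, density=d.density - c,
                            n_voxels=d.n_voxels, peak=d.peak,
                            element=d.element, b_factor=d.b_factor,
                            copy_id=d.copy_id)
                for d, c in zip(densities, contam_raw)]
        fe = [d for d in work if d.element == "Fe"]
        if cfg.b_factor_cutoff is not None:
            fe = [d for d in fe if d.b_factor is None
                  or d.b_factor <= cfg.b_factor_cutoff]
        est.fit(fe)
        cal = est.calibration_
        floor = detection_floor(rms, cal, table, peak_model=pm)
        per_copy: dict[int, dict[str, OccupancyResult]] = {}
        for d in work:
            if d.element == "Fe":
                continue
            est.mode = "mixed" if d.label in BELT_LABELS else "free"
            res = est.predict_results([d], floor=floor)[0]
            res.copy_id = d.copy_id
            per_copy.setdefault(d.copy_id or 0, {})[d.label] = res
        return cal, floor, per_copy

    cal, floor, per_copy = run_pass(np.zeros(len(densities)))

    if crosstalk_correction and b_correction:
        estimates = {(r.copy_id, r.label): r.raw_estimate
                     for copy in per_copy.values() for r in copy.values()}
        masses = _estimated_masses(scene, table, estimates)
        pos = np.array([s.position for s in scene.sites])
        beff = np.array([b_eff(s.b_factor, spec.resolution)
                         for s in scene.sites])
        # electron masses -> map units through the first-pass calibration,
        # keeping the correction (and hence all estimates) scale invariant
        unit_scale = cal.d_fe_mean / table.f2("Fe")
        contam = np.zeros(len(scene.sites))
        for i in range(len(scene.sites)):
            d_ij = np.linalg.norm(pos - pos[i], axis=1)
            for j in np.nonzero((d_ij > 1e-6) & (d_ij < 5.0))[0]:
                contam[i] += unit_scale * masses[j] * _offcenter_mass_fraction(
                    beff[j], d_ij[j], cfg.radius)
        cal, floor, per_copy = run_pass(contam)

    # only labels present in every copy are averaged (the remote site is
    # single-copy and passes through unchanged)
    common = set.intersection(*(set(v) for v in per_copy.values())) \
        if per_copy else set()
    shared = {c: {l: r for l, r in v.items() if l in common}
              for c, v in per_copy.items()}
    averaged, devs = _average_copies(shared) if common else ({}, {})
    for c, v in per_copy.items():
        for lbl, res in v.items():
            if lbl not in common:
                averaged[lbl] = res
    return SceneQuantification(
        calibration=cal, map_rms=rms, floor=floor, per_copy=per_copy,
        averaged=averaged, copy_deviation=devs, site_densities=densities)
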