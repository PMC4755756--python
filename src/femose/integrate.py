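"""Fixed-radius sphere integration of map density around atomic sites.

Two sampling modes:

``voxel-sum``
    Sum of map values at grid points whose centers lie within the radius,
    times the voxel volume (with periodic wrap across the P1 cell). This is
    the plain grid-map quantification rule; its sphere-discretization bias is
    systematic and cancels in Fe-calibrated ratios, but it carries a per-site
    scatter of order 1-2% at typical spacings.

``subgrid-trilinear``
    The map is resampled by trilinear interpolation on a subdivided grid
    (default 4x per axis) before the same sphere-sum rule is applied. The
    interpolation loses a mode-systematic fraction of sharply peaked density
    (again cancelling in ratios) but reduces the per-site scatter by nearly
    an order of magnitude, which is why the occupancy pipeline prefers it.

:func:`gaussian_sphere_response` measures, for either mode, the expected
integrated signal per unit total peak mass as a function of the peak's
effective B — the quantity used to convert integrated densities back to
total-mass units regardless of sampling mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .core import MapGrid, UnitCell, fractionalize

__all__ = [
    "IntegrationConfig", "SiteDensity", "OutOfBoundsError",
    "TooFewVoxelsError", "ZeroRmsError",
    "integrate_sphere", "map_rms", "peak_sigma_level",
    "gaussian_sphere_response",
]


class OutOfBoundsError(ValueError):
    """Sphere center outside the unit cell."""


class TooFewVoxelsError(ValueError):
    """Radius too small for the grid (fewer than 7 voxels in the sphere)."""


class ZeroRmsError(ZeroDivisionError):
    """Sigma level undefined on an all-zero map."""


@dataclass(frozen=True)
class IntegrationConfig:
    radius: float = 1.0
    sampling: str = "voxel-sum"     # or "subgrid-trilinear"
    subdivision: int = 4            # per-axis, subgrid-trilinear only
    b_factor_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.sampling not in ("voxel-sum", "subgrid-trilinear"):
            raise ValueError("sampling must be 'voxel-sum' or 'subgrid-trilinear'")
        if self.subdivision < 1:
            raise ValueError("subdivision must be >= 1")


@dataclass
class SiteDensity:
    """Integrated density around one site (map units x A^3)."""

    label: str
    density: float
    n_voxels: int
    peak: float
    element: str | None = None
    b_factor: float | None = None
    copy_id: int | None = None


def _interp_at(grid: MapGrid, frac_coords: np.ndarray) -> np.ndarray:
    """Trilinear map values at fractional coordinates (periodic)."""
    nd = np.array(grid.dims, dtype=float)
    coords = (np.atleast_2d(frac_coords) * nd).T
    return ndimage.map_coordinates(grid.values.astype(np.float64), coords,
                                   order=1, mode="grid-wrap")


def _sphere_window(grid: MapGrid, center, radius: float):
    """Index window, wrapped deltas and radial distances around a center."""
    cell = grid.cell
    frac = fractionalize(np.asarray(center, dtype=float), cell)
    if np.any(frac < -1e-9) or np.any(frac > 1 + 1e-9):
        raise OutOfBoundsError(f"center {center} lies outside the unit cell")
    nd = np.array(grid.dims)
    # conservative per-axis fractional half-width of the sphere
    fm = cell.frac_matrix
    half = radius * np.linalg.norm(fm, axis=1)
    lo = np.floor((frac - half) * nd).astype(int) - 1
    hi = np.ceil((frac + half) * nd).astype(int) + 1
    idx = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    I, J, K = np.meshgrid(*idx, indexing="ij")
    dfrac = np.stack([I / nd[0] - frac[0], J / nd[1] - frac[1],
                      K / nd[2] - frac[2]], axis=-1)
    cart = dfrac @ cell.orth_matrix.T
    r2 = np.einsum("...k,...k->...", cart, cart)
    return frac, (I, J, K), r2


def integrate_sphere(grid: MapGrid, center, cfg: IntegrationConfig | None = None,
                     *, label: str = "", element: str | None = None,
                     b_factor: float | None = None,
                     copy_id: int | None = None) -> SiteDensity:
    """Integrate density within ``cfg.radius`` of a Cartesian center."""
    cfg = cfg or IntegrationConfig()
    frac, (I, J, K), r2 = _sphere_window(grid, center, cfg.radius)
    mask = r2 <= cfg.radius ** 2
    n_coarse = int(mask.sum())
    if n_coarse < 7:
        raise TooFewVoxelsError(
            f"only {n_coarse} voxels inside radius {cfg.radius} A; "
            "grid too coarse for this radius")
    dims = grid.dims
    peak = float(_interp_at(grid, frac)[0])

    if cfg.sampling == "voxel-sum":
        wi = I[mask] % dims[0]
        wj = J[mask] % dims[1]
        wk = K[mask] % dims[2]
        total = float(grid.values[wi, wj, wk].astype(np.float64).sum()
                      * grid.voxel_volume)
        n_used = n_coarse
    else:
        s = cfg.subdivision
        nd = np.array(dims, dtype=float)
        lo = np.array([I.min(), J.min(), K.min()], dtype=float)
        hi = np.array([I.max(), J.max(), K.max()], dtype=float)
        axes = [np.arange(lo[k], hi[k] + 1e-9, 1.0 / s) for k in range(3)]
        FI, FJ, FK = np.meshgrid(*axes, indexing="ij")
        dfrac = np.stack([FI / nd[0] - frac[0], FJ / nd[1] - frac[1],
                          FK / nd[2] - frac[2]], axis=-1)
        cart = dfrac @ grid.cell.orth_matrix.T
        sr2 = np.einsum("...k,...k->...", cart, cart)
        smask = sr2 <= cfg.radius ** 2
        coords = np.stack([FI[smask], FJ[smask], FK[smask]])
        vals = ndimage.map_coordinates(grid.values.astype(np.float64), coords,
                                       order=1, mode="grid-wrap")
        total = float(vals.sum() * grid.voxel_volume / s ** 3)
        n_used = int(smask.sum())

    return SiteDensity(label=label, density=total, n_voxels=n_used, peak=peak,
                       element=element, b_factor=b_factor, copy_id=copy_id)


def map_rms(grid: MapGrid) -> float:
    """Root mean square of all voxel values (map units)."""
    if grid.n_points == 0:
        raise ValueError("empty map")
    v = grid.values.astype(np.float64)
    return float(np.sqrt(np.mean(v * v)))


def peak_sigma_level(grid: MapGrid, center) -> float:
    """Density at a Cartesian position in units of the map RMS."""
    rms = map_rms(grid)
    if rms == 0:
        raise ZeroRmsError("sigma level undefined: map RMS is zero")
    frac = fractionalize(np.asarray(center, dtype=float), grid.cell)
    if np.any(frac < -1e-9) or np.any(frac > 1 + 1e-9):
        raise OutOfBoundsError(f"center {center} lies outside the unit cell")
    return float(_interp_at(grid, frac)[0] / rms)


# ---------------------------------------------------------------------------
# mode response to a Gaussian peak

_RESPONSE_OFFSETS = (
    (0.0, 0.0, 0.0), (0.5, 0.5, 0.5), (0.25, 0.5, 0.75), (0.75, 0.25, 0.5),
    (0.5, 0.75, 0.25), (0.125, 0.625, 0.375), (0.875, 0.375, 0.625),
    (0.375, 0.125, 0.875),
)


@lru_cache(maxsize=256)
def _response_cached(b_eff: float, spacing: float, radius: float,
                     sampling: str, subdivision: int) -> float:
    r_cut = math.sqrt(b_eff * math.log(1e10) / (4.0 * math.pi ** 2))
    half = r_cut + radius + 2 * spacing
    n = int(math.ceil(2 * half / spacing))
    cell = UnitCell(n * spacing, n * spacing, n * spacing)
    ax = np.arange(n) * spacing
    cfg = IntegrationConfig(radius=radius, sampling=sampling,
                            subdivision=subdivision)
    amp = (4.0 * math.pi / b_eff) ** 1.5
    vals = np.empty(len(_RESPONSE_OFFSETS))
    for m, off in enumerate(_RESPONSE_OFFSETS):
        c = half + np.array(off) * spacing
        dx2 = (ax - c[0])[:, None, None] ** 2
        dy2 = (ax - c[1])[None, :, None] ** 2
        dz2 = (ax - c[2])[None, None, :] ** 2
        dens = amp * np.exp(-4.0 * math.pi ** 2 * (dx2 + dy2 + dz2) / b_eff)
        grid = MapGrid(cell=cell, values=dens.astype(np.float32))
        vals[m] = integrate_sphere(grid, c, cfg).density
    return float(vals.mean())


def gaussian_sphere_response(b_eff: float, spacing: float,
                             cfg: IntegrationConfig | None = None) -> float:
    """Expected sphere-integrated signal per unit total mass of a Gaussian peak.

    Measured numerically by rendering a unit-mass peak of the given effective
    B at the map's grid spacing and running the configured integrator, averaged
    over fixed sub-voxel offsets. Dividing a measured site density by this
    response converts it to total-peak-mass units, which removes both the
    B-dependent sphere-capture fraction and the sampling mode's systematic
    loss from downstream ratios.
    """
    cfg = cfg or IntegrationConfig()
    return _response_cached(round(float(b_eff), 3), round(float(spacing), 4),
                            cfg.radius, cfg.sampling, cfg.subdivision)
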