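"""Synthetic Av1-like scenes: planted-occupancy structures and noisy maps.

The generator emulates the asymmetric unit of the MoFe-protein as far as the
occupancy estimator cares: two copies of a 7-Fe cofactor whose three belt
chalcogen sites (labelled X2B, X5A, X3A; mutually 5.7 A apart) carry planted
Se/S occupancy mixtures, plus two copies of an 8-Fe cluster, giving the 30
full-occupancy Fe atoms used as the internal anomalous-scattering reference.
Cluster geometry is deliberately generic — only the site spacings that the
estimator is sensitive to (belt separation, ~2.2 A Fe-chalcogen contacts)
are controlled.

The rendered map is a sum of isotropic Gaussian peaks, one per scattering
species, in map units where the full-space integral of a full-occupancy peak
equals the element's f'' (electrons):

    rho(r) = occ * f'' * (4*pi/B_eff)^(3/2) * exp(-4*pi^2 r^2 / B_eff)

with B_eff = b_factor + B_blur(resolution) and B_blur = (res/1.6 A)^2 * 9 A^2,
so peak widths track both the atomic displacement parameter and the map
resolution. Noise is i.i.d. Gaussian per voxel, specified either absolutely
or as a fraction of the full-occupancy Se peak height (default 2%, the map
statistic reported for the experimental data this emulates).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (MapGrid, ScatteringTable, Site, UnitCell,
                   default_scattering_table, fractionalize)

__all__ = [
    "FixtureGeometryError", "FixtureSpec", "SyntheticScene",
    "BELT_LABELS", "BELT_SEPARATION", "RESTING_STATE", "CO_INHIBITED_STATE",
    "DEFAULT_TIMECOURSE", "b_blur", "b_eff",
    "build_fixture", "render_map", "simulate_timecourse_scenes",
]

logger = logging.getLogger(__name__)

BELT_LABELS = ("X2B", "X5A", "X3A")
#: Pairwise belt chalcogen separation in the resting state (angstrom).
BELT_SEPARATION = 5.7

#: Av1-Se2B resting state: Se fully at the 2B position, S at the other two.
RESTING_STATE: dict[str, tuple[float, float]] = {
    "X2B": (1.0, 0.0), "X5A": (0.0, 1.0), "X3A": (0.0, 1.0),
}

#: CO-inhibited endpoint: Se redistributed to 10/44/35% with the X2B deficit
#: unexplained by chalcogen density (the displacing ligand is not modelled).
CO_INHIBITED_STATE: dict[str, tuple[float, float]] = {
    "X2B": (0.10, 0.0), "X5A": (0.44, 0.56), "X3A": (0.35, 0.65),
}

#: Illustrative seven-point migration trajectory (turnovers per active site ->
#: belt Se fractions). Shapes follow the qualitative observations the series
#: is meant to exercise: monotone X2B decay, transient X5A > X3A, and a
#: non-increasing Se total that is nearly gone after several thousand
#: turnovers. The complementary S fraction fills each site to full occupancy.
DEFAULT_TIMECOURSE: list[tuple[int, dict[str, tuple[float, float]]]] = [
    (2,    {"X2B": (0.92, 0.08), "X5A": (0.06, 0.94), "X3A": (0.02, 0.98)}),
    (46,   {"X2B": (0.78, 0.22), "X5A": (0.14, 0.86), "X3A": (0.06, 0.94)}),
    (341,  {"X2B": (0.55, 0.45), "X5A": (0.25, 0.75), "X3A": (0.12, 0.88)}),
    (921,  {"X2B": (0.35, 0.65), "X5A": (0.28, 0.72), "X3A": (0.17, 0.83)}),
    (1785, {"X2B": (0.20, 0.80), "X5A": (0.22, 0.78), "X3A": (0.15, 0.85)}),
    (2141, {"X2B": (0.12, 0.88), "X5A": (0.15, 0.85), "X3A": (0.11, 0.89)}),
    (5361, {"X2B": (0.02, 0.98), "X5A": (0.04, 0.96), "X3A": (0.03, 0.97)}),
]


class FixtureGeometryError(ValueError):
    """Cell too small to satisfy the separation/edge-margin constraints."""


def b_blur(resolution: float) -> float:
    """Resolution-dependent blur term added to atomic B (A^2)."""
    return (resolution / 1.6) ** 2 * 9.0


def b_eff(b_factor: float, resolution: float) -> float:
    return b_factor + b_blur(resolution)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic scene."""

    cell: UnitCell = field(default_factory=lambda: UnitCell(50.0, 50.0, 50.0))
    resolution: float = 1.6
    grid_spacing: float | None = None        # default: resolution / 3
    noise_rms: float = 0.02
    noise_unit: str = "se_peak_fraction"      # or "absolute" (map units)
    belt_occupancies: dict[int, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {1: dict(RESTING_STATE), 2: dict(RESTING_STATE)})
    remote_se_occupancy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing is None:
            self.grid_spacing = self.resolution / 3.0
        if self.noise_unit not in ("se_peak_fraction", "absolute"):
            raise ValueError("noise_unit must be 'se_peak_fraction' or 'absolute'")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")
        for copy_id, table in self.belt_occupancies.items():
            for label, (se, s) in table.items():
                if label not in BELT_LABELS:
                    raise ValueError(f"unknown belt label {label!r}")
                if se < 0 or s < 0 or se + s > 1.0 + 1e-9:
                    raise ValueError(
                        f"belt site {label} copy {copy_id}: se+s must be in [0,1]")

    def with_belt(self, table: dict[str, tuple[float, float]]) -> "FixtureSpec":
        """Same spec with one occupancy table applied to both cofactor copies."""
        return replace(self, belt_occupancies={1: dict(table), 2: dict(table)})


@dataclass
class SyntheticScene:
    sites: list[Site]
    spec: FixtureSpec
    label: str = "scene"
    map: MapGrid | None = None

    @property
    def truth(self) -> dict[int, dict[str, tuple[float, float]]]:
        """Planted belt occupancies, per cofactor copy."""
        out: dict[int, dict[str, tuple[float, float]]] = {}
        for s in self.sites:
            if s.label in BELT_LABELS:
                out.setdefault(s.copy_id, {})[s.label] = (s.occupancy, s.s_occupancy)
        return out

    def fe_sites(self) -> list[Site]:
        return [s for s in self.sites if s.element == "Fe"]

    def belt_sites(self) -> list[Site]:
        return [s for s in self.sites if s.label in BELT_LABELS]


# ---------------------------------------------------------------------------
# geometry

def _cofactor_local() -> tuple[np.ndarray, np.ndarray]:
    """Local coordinates: (7 Fe positions, 3 belt positions), centered.

    Belt triangle of side 5.7 A in the z=0 plane; the six prism Fe form two
    eclipsed triangles at z = +-1.3 A with a 2.2 A Fe-chalcogen contact; a
    seventh apical Fe caps the prism.
    """
    r_belt = BELT_SEPARATION / math.sqrt(3.0)
    dz = 1.3
    r_fe = r_belt - math.sqrt(2.2 ** 2 - dz ** 2)
    angles = np.deg2rad([90.0, 210.0, 330.0])
    belt = np.stack([r_belt * np.cos(angles), r_belt * np.sin(angles),
                     np.zeros(3)], axis=1)
    fe = []
    for z in (dz, -dz):
        for a in angles:
            fe.append([r_fe * math.cos(a), r_fe * math.sin(a), z])
    fe.append([0.0, 0.0, 3.0])  # apex
    return np.array(fe), belt


def _p_cluster_local() -> np.ndarray:
    """8 Fe on a 2.6 A cube, centered (compact generic arrangement)."""
    e = 2.6 / 2.0
    pts = [[sx * e, sy * e, sz * e] for sx in (-1, 1) for sy in (-1, 1)
           for sz in (-1, 1)]
    return np.array(pts)


_CENTER_FRACS = {
    "cofactor": {1: (0.28, 0.28, 0.28), 2: (0.72, 0.72, 0.28)},
    "pcluster": {1: (0.72, 0.28, 0.72), 2: (0.28, 0.72, 0.72)},
}
_EDGE_MARGIN = 10.0
_COPY_SEPARATION = 25.0


def build_fixture(spec: FixtureSpec) -> SyntheticScene:
    """Place the 30-Fe / 6-belt-site scene in the cell (no map yet).

    B-factors are drawn once per scene from the reference distributions:
    Fe 9.0 +- 0.4 A^2, belt chalcogen (and remote Se) sites 9.9 +- 0.5 A^2.
    """
    cell = spec.cell
    diag = np.array([cell.a, cell.b, cell.c])
    centers: dict[tuple[str, int], np.ndarray] = {}
    for kind, table in _CENTER_FRACS.items():
        for copy_id, frac in table.items():
            centers[(kind, copy_id)] = np.array(frac) * diag

    pts = list(centers.values())
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.linalg.norm(pts[i] - pts[j]) < _COPY_SEPARATION:
                raise FixtureGeometryError(
                    "cell too small: cluster copies closer than "
                    f"{_COPY_SEPARATION} A")

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xFE]))
    fe_local, belt_local = _cofactor_local()
    p_local = _p_cluster_local()

    sites: list[Site] = []

    def _add(label: str, element: str, pos: np.ndarray, b_mu: float,
             b_sd: float, occ: float, copy_id: int, s_occ: float = 0.0) -> None:
        b = float(rng.normal(b_mu, b_sd))
        sites.append(Site(label=label, element=element, position=pos,
                          b_factor=max(b, 1.0), occupancy=occ,
                          copy_id=copy_id, s_occupancy=s_occ))

    for copy_id in (1, 2):
        c = centers[("cofactor", copy_id)]
        for k, p in enumerate(fe_local, start=1):
            _add(f"FE{k}", "Fe", c + p, 9.0, 0.4, 1.0, copy_id)
        occ_table = spec.belt_occupancies.get(copy_id, RESTING_STATE)
        for label, p in zip(BELT_LABELS, belt_local):
            se, s = occ_table.get(label, (0.0, 0.0))
            _add(label, "Se", c + p, 9.9, 0.5, se, copy_id, s_occ=s)
        cp = centers[("pcluster", copy_id)]
        for k, p in enumerate(p_local, start=1):
            _add(f"PF{k}", "Fe", cp + p, 9.0, 0.4, 1.0, copy_id)

    if spec.remote_se_occupancy > 0:
        # low-occupancy site ~22 A from cofactor copy 1, along the body diagonal
        pos = centers[("cofactor", 1)] + 22.0 / math.sqrt(3.0) * np.ones(3)
        _add("RSE", "Se", pos, 9.9, 0.5, float(spec.remote_se_occupancy), 1)

    for s in sites:
        frac = fractionalize(s.position, cell)
        cart_margin = np.minimum(frac, 1.0 - frac) * diag
        if np.any(cart_margin < _EDGE_MARGIN):
            raise FixtureGeometryError(
                f"site {s.label} (copy {s.copy_id}) closer than "
                f"{_EDGE_MARGIN} A to a cell edge")
    return SyntheticScene(sites=sites, spec=spec)


# ---------------------------------------------------------------------------
# rendering

def se_peak_height(spec: FixtureSpec, table: ScatteringTable,
                   b_se: float = 9.9) -> float:
    """Peak height (map units) of a full-occupancy Se site at the nominal B."""
    B = b_eff(b_se, spec.resolution)
    return table.f2("Se") * (4.0 * math.pi / B) ** 1.5


def _grid_dims(cell: UnitCell, spacing: float) -> tuple[int, int, int]:
    return tuple(max(int(math.ceil(L / spacing)), 2)
                 for L in (cell.a, cell.b, cell.c))


def render_map(scene: SyntheticScene, table: ScatteringTable | None = None,
               spec: FixtureSpec | None = None, *,
               noise_seed: int | None = None) -> MapGrid:
    """Render the scene's anomalous-difference-style map (and attach it).

    Peaks wrap periodically across the P1 cell; a peak whose tail crosses a
    cell edge is logged as a clipped-peak warning but rendered (wrapped)
    rather than rejected.
    """
    spec = spec or scene.spec
    table = table or default_scattering_table()
    if spec.grid_spacing > spec.resolution / 2.0 + 1e-12:
        raise ValueError("grid_spacing must be <= resolution/2")
    cell = spec.cell
    dims = _grid_dims(cell, spec.grid_spacing)
    values = np.zeros(dims, dtype=np.float64)
    diag = np.array([cell.a, cell.b, cell.c])
    nd = np.array(dims)

    for site in scene.sites:
        components = [(site.element, site.occupancy)]
        if site.s_occupancy > 0:
            components.append(("S", site.s_occupancy))
        B = b_eff(site.b_factor, spec.resolution)
        # cutoff where the Gaussian falls to 1e-8 of its peak
        r_cut = math.sqrt(B * math.log(1e8) / (4.0 * math.pi ** 2))
        frac = fractionalize(site.position, cell)
        if np.any(np.minimum(frac, 1 - frac) * diag < r_cut):
            logger.warning("peak at %s (copy %d) extends beyond the cell; "
                           "wrapped periodically", site.label, site.copy_id)
        lo = np.floor((frac - r_cut / diag) * nd).astype(int)
        hi = np.ceil((frac + r_cut / diag) * nd).astype(int)
        idx = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
        I, J, K = np.meshgrid(*idx, indexing="ij")
        dfrac = np.stack([I / nd[0] - frac[0], J / nd[1] - frac[1],
                          K / nd[2] - frac[2]], axis=-1)
        cart = dfrac @ cell.orth_matrix.T
        r2 = np.einsum("...k,...k->...", cart, cart)
        mask = r2 <= r_cut ** 2
        wi, wj, wk = I[mask] % dims[0], J[mask] % dims[1], K[mask] % dims[2]
        for element, occ in components:
            if occ <= 0:
                continue
            amp = occ * table.f2(element) * (4.0 * math.pi / B) ** 1.5
            np.add.at(values, (wi, wj, wk),
                      amp * np.exp(-4.0 * math.pi ** 2 * r2[mask] / B))

    if spec.noise_rms > 0:
        sigma = spec.noise_rms
        if spec.noise_unit == "se_peak_fraction":
            sigma = spec.noise_rms * se_peak_height(spec, table)
        seed = noise_seed if noise_seed is not None else spec.seed
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x01]))
        values += rng.normal(0.0, sigma, size=values.shape)

    grid = MapGrid(cell=cell, values=values.astype(np.float32))
    scene.map = grid
    return grid


def simulate_timecourse_scenes(
        series: list[tuple[int, dict[str, tuple[float, float]]]],
        spec: FixtureSpec | None = None,
        table: ScatteringTable | None = None) -> list[SyntheticScene]:
    """One rendered scene per (turnover count, belt occupancy table) point.

    All scenes share the fixture geometry and B-factors (same crystal form);
    noise is independent per time point.
    """
    spec = spec or FixtureSpec()
    table = table or default_scattering_table()
    scenes: list[SyntheticScene] = []
    for k, (count, occ_table) in enumerate(series):
        pt_spec = spec.with_belt(occ_table)
        scene = build_fixture(pt_spec)
        scene.label = f"fq-{count}"
        render_map(scene, table, pt_spec, noise_seed=int(spec.seed) * 1000 + k)
        scenes.append(scene)
    return scenes
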