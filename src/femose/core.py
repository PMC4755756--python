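"""Shared domain types and coordinate conventions.

Everything downstream works in Cartesian angstroms; fractional coordinates
appear only at file boundaries and inside the periodic-wrap arithmetic of the
sphere integrator.  Maps are scalar densities on a regular grid over a P1
unit cell, with grid point (0,0,0) at the fractional origin and axes stored
in x,y,z order (fastest-varying last in the numpy array, i.e. ``values[i,j,k]``
sits at fractional ``(i/nx, j/ny, k/nz)``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "InvalidCellError",
    "UnitCell",
    "MapGrid",
    "Site",
    "ScatteringTable",
    "default_scattering_table",
    "orthogonalize",
    "fractionalize",
    "f_ratio",
]


class InvalidCellError(ValueError):
    """Raised for degenerate unit-cell parameters (non-positive volume)."""


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {name} must be in (0, 180)")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise InvalidCellError("cell angles give non-positive volume")

    @property
    def volume(self) -> float:
        ca, cb, cg = (
            math.cos(math.radians(self.alpha)),
            math.cos(math.radians(self.beta)),
            math.cos(math.radians(self.gamma)),
        )
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            raise InvalidCellError("cell angles give non-positive volume")
        return self.a * self.b * self.c * math.sqrt(arg)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional to Cartesian coordinates (angstroms)."""
        m = self.to_gemmi().orth.mat
        return np.array(m.tolist(), dtype=float)

    @property
    def frac_matrix(self) -> np.ndarray:
        """3x3 matrix mapping Cartesian (angstroms) to fractional coordinates."""
        m = self.to_gemmi().frac.mat
        return np.array(m.tolist(), dtype=float)


def orthogonalize(frac, cell: UnitCell) -> np.ndarray:
    """Fractional -> Cartesian (angstrom).  Accepts a vector or (N,3) array."""
    frac = np.asarray(frac, dtype=float)
    if not np.all(np.isfinite(frac)):
        raise ValueError("fractional coordinates must be finite")
    return frac @ cell.orth_matrix.T


def fractionalize(cart, cell: UnitCell) -> np.ndarray:
    """Cartesian (angstrom) -> fractional.  Inverse of :func:`orthogonalize`."""
    cart = np.asarray(cart, dtype=float)
    if not np.all(np.isfinite(cart)):
        raise ValueError("Cartesian coordinates must be finite")
    return cart @ cell.frac_matrix.T


@dataclass
class MapGrid:
    """A scalar density lattice over a P1 unit cell.

    ``values`` has shape ``dims`` and dtype float32 (the CCP4 mode-2 storage
    type, so file round trips are bit exact).  ``values[i,j,k]`` is the density
    at fractional position ``(i/nx, j/ny, k/nz)``.
    """

    cell: UnitCell
    values: np.ndarray
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3-D array")
        if self.axis_order != "xyz":
            raise ValueError("only the xyz axis order is supported")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.n_points

    @property
    def spacing(self) -> np.ndarray:
        """Approximate grid spacing along each cell axis (angstrom)."""
        return np.array([self.cell.a, self.cell.b, self.cell.c]) / np.array(self.dims)


@dataclass
class Site:
    """An atomic (or chalcogen) position with element, B-factor and occupancy.

    ``occupancy`` is the planted fraction used in synthesis; on quantification
    inputs it is the unknown being estimated.  For mixed belt-chalcogen sites
    ``occupancy`` holds the Se fraction and ``s_occupancy`` the complementary
    S fraction (their sum may be < 1 when the site is partly vacant).
    """

    label: str
    element: str
    position: np.ndarray
    b_factor: float
    occupancy: float = 1.0
    copy_id: int = 0
    s_occupancy: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector (Cartesian angstrom)")
        if not self.b_factor > 0:
            raise ValueError("b_factor must be > 0")
        for occ in (self.occupancy, self.s_occupancy):
            if not 0.0 <= occ <= 1.0:
                raise ValueError("occupancies must lie in [0, 1]")
        if self.occupancy + self.s_occupancy > 1.0 + 1e-9:
            raise ValueError("Se + S occupancy may not exceed 1")

    def frac(self, cell: UnitCell) -> np.ndarray:
        return fractionalize(self.position, cell)


#: f'' values (electrons) at the Se K-edge data-collection energy.
_F2_AT_12662 = {"Se": 3.84, "Fe": 1.50, "S": 0.24}


@dataclass(frozen=True)
class ScatteringTable:
    """Imaginary anomalous scattering factors f'' (electrons) at one energy."""

    energy_eV: float
    f_doubleprime: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, f2 in self.f_doubleprime.items():
            if f2 < 0:
                raise ValueError(f"f'' for {el} must be >= 0")

    def f2(self, element: str) -> float:
        try:
            return self.f_doubleprime[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} not in scattering table at {self.energy_eV} eV"
            ) from None

    def ratio(self, num: str, den: str) -> float:
        """f''(num)/f''(den), unitless."""
        d = self.f2(den)
        if d <= 0:
            raise ZeroDivisionError(f"f'' for denominator {den!r} is not positive")
        return self.f2(num) / d


def default_scattering_table() -> ScatteringTable:
    """The f'' table at 12,662 eV (Se K-edge peak): Se 3.84 e, Fe 1.50 e, S 0.24 e."""
    return ScatteringTable(energy_eV=12662.0, f_doubleprime=dict(_F2_AT_12662))


def f_ratio(table: ScatteringTable, num: str, den: str) -> float:
    """Percentage ratio 100 * f''(num)/f''(den).

    Full precision is returned; format to one decimal for display
    (e.g. S/Se at 12,662 eV -> 6.3%).
    """
    return 100.0 * table.ratio(num, den)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding with halves away from zero (6.25 -> 6.3).

    Conventional for reporting percentages; Python's built-in round() uses
    banker's rounding and would print 6.2.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def asdict_site(site: Site) -> dict:
    d = dataclasses.asdict(site)
    d["position"] = [float(x) for x in site.position]
    return d
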