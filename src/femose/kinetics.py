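"""Assay computations: Dixon-plot K_i, activities, lag phase, dose optimum.

A Dixon plot graphs 1/v against inhibitor concentration at several substrate
levels; for competitive-type inhibition the per-level lines intersect at
I = -K_i. With more than two substrate levels the intersections are
overdetermined, so K_i is taken as the negated median of the pairwise
intersection abscissae (mean available as an option) with the median absolute
deviation as a dispersion estimate.

Concentrations are carried with explicit units and normalized to micromolar
internally; results report K_i in micromolar.

Assay tables are tidy pandas DataFrames. Column conventions:

==================  =====================================================
``substrate``       substrate level (any consistent unit, e.g. uL C2H2
                    per 9 mL headspace)
``inhibitor_conc``  inhibitor concentration, in ``inhibitor_unit``
``inhibitor_unit``  'uM' or 'mM' (optional; default uM)
``velocity``        reaction velocity, any consistent positive unit
``time_min``        time (minutes) for time-course tables
``product_nmol``    product amount for time-course tables
``condition``       label for relative-activity comparisons
``replicate``       replicate id (informational)
==================  =====================================================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "InvalidVelocityError", "NoIntersectionError", "to_micromolar",
    "DixonFit", "DixonKiEstimator", "dixon_ki", "specific_activity",
    "lag_phase", "relative_activity", "dose_optimum", "DoseOptimum",
]

_UNIT_TO_UM = {"uM": 1.0, "μM": 1.0, "um": 1.0, "mM": 1e3, "M": 1e6}


def to_micromolar(value: float, unit: str) -> float:
    try:
        return float(value) * _UNIT_TO_UM[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


class InvalidVelocityError(ValueError):
    pass


class NoIntersectionError(ValueError):
    pass


@dataclass
class DixonFit:
    lines: pd.DataFrame            # substrate, slope, intercept, n
    intersections_uM: np.ndarray   # pairwise intersection abscissae
    ki_uM: float
    ki_mad_uM: float
    excluded_pairs: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def ki_mM(self) -> float:
        return self.ki_uM / 1e3


def _normalize_inhibitor(table: pd.DataFrame) -> pd.Series:
    conc = table["inhibitor_conc"].astype(float)
    if "inhibitor_unit" in table:
        factors = table["inhibitor_unit"].map(_UNIT_TO_UM)
        if factors.isna().any():
            bad = table.loc[factors.isna(), "inhibitor_unit"].unique()
            raise ValueError(f"unknown concentration unit(s) {list(bad)}")
        conc = conc * factors
    return conc


class DixonKiEstimator(BaseEstimator):
    """Unrestrained per-substrate-level linear fits of 1/v vs [I].

    Fitted attributes: ``lines_`` (per-level OLS slope/intercept),
    ``intersections_`` (pairwise abscissae, uM), ``ki_`` (uM), ``ki_mad_``.
    """

    def __init__(self, aggregation: str = "median",
                 parallel_rtol: float = 1e-6):
        self.aggregation = aggregation
        self.parallel_rtol = parallel_rtol

    def fit(self, X: pd.DataFrame, y=None) -> "DixonKiEstimator":
        table = X
        if (table["velocity"] <= 0).any():
            raise InvalidVelocityError("all velocities must be > 0")
        conc_uM = _normalize_inhibitor(table)
        levels = sorted(table["substrate"].unique())
        if len(levels) < 2:
            raise ValueError("Dixon fit needs >= 2 substrate levels")
        rows = []
        for s in levels:
            sel = table["substrate"] == s
            x = conc_uM[sel].to_numpy()
            yv = 1.0 / table.loc[sel, "velocity"].to_numpy()
            if len(x) < 3:
                raise ValueError(f"substrate level {s}: need >= 3 points")
            slope, intercept = np.polyfit(x, yv, 1)
            rows.append({"substrate": s, "slope": slope,
                         "intercept": intercept, "n": int(len(x))})
        lines = pd.DataFrame(rows)

        xs, excluded, warns = [], 0, []
        slopes = lines["slope"].to_numpy()
        scale = np.max(np.abs(slopes))
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                m1, c1 = lines.loc[i, ["slope", "intercept"]]
                m2, c2 = lines.loc[j, ["slope", "intercept"]]
                if abs(m2 - m1) < self.parallel_rtol * scale:
                    excluded += 1
                    continue
                xs.append((c1 - c2) / (m2 - m1))
        if excluded:
            warns.append(f"excluded {excluded} near-parallel line pair(s)")
        if not xs:
            raise NoIntersectionError("all line pairs are near-parallel")
        xs = np.array(xs)
        agg = np.median if self.aggregation == "median" else np.mean
        self.lines_ = lines
        self.intersections_ = xs
        self.ki_ = float(-agg(xs))
        self.ki_mad_ = float(np.median(np.abs(xs - np.median(xs))))
        self.warnings_ = warns
        self.excluded_pairs_ = excluded
        return self

    def result(self) -> DixonFit:
        return DixonFit(lines=self.lines_, intersections_uM=self.intersections_,
                        ki_uM=self.ki_, ki_mad_uM=self.ki_mad_,
                        excluded_pairs=self.excluded_pairs_,
                        warnings=list(self.warnings_))


def dixon_ki(table: pd.DataFrame, aggregation: str = "median") -> DixonFit:
    """Dixon-plot inhibition constant from a tidy (substrate, [I], v) table."""
    return DixonKiEstimator(aggregation=aggregation).fit(table).result()


def specific_activity(table: pd.DataFrame, protein_mg: float) -> float:
    """Slope of product (nmol) vs time (min), per mg protein.

    Uses ordinary least squares over the supplied (assumed linear) region.
    """
    if protein_mg <= 0:
        raise ValueError("protein mass must be > 0")
    t = table["time_min"].to_numpy(dtype=float)
    p = table["product_nmol"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 time points")
    slope = np.polyfit(t, p, 1)[0]
    return float(slope / protein_mg)


def lag_phase(table: pd.DataFrame, min_points: int = 3) -> float:
    """Lag duration (min) from a product-vs-time trace.

    Fits every suffix of the trace (latest ``min_points`` or more points) by
    OLS, keeps the suffix with the best R^2 (ties favor the longer suffix),
    and returns the x-intercept of that steady-state line, floored at zero.
    """
    t = table["time_min"].to_numpy(dtype=float)
    p = table["product_nmol"].to_numpy(dtype=float)
    order = np.argsort(t)
    t, p = t[order], p[order]
    n = len(t)
    if n < 4:
        raise ValueError("need >= 4 time points spanning the lag and the "
                         "steady state")
    best = None  # (r2, suffix_len, slope, intercept)
    for start in range(0, n - min_points + 1):
        ts, ps = t[start:], p[start:]
        slope, intercept = np.polyfit(ts, ps, 1)
        resid = ps - (slope * ts + intercept)
        ss_tot = float(np.sum((ps - ps.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        cand = (round(r2, 12), len(ts), slope, intercept)
        if best is None or cand[:2] > best[:2]:
            best = cand
    _, _, slope, intercept = best
    if slope <= 0:
        return 0.0
    return max(0.0, float(-intercept / slope))


def relative_activity(table: pd.DataFrame, condition_a: str,
                      condition_b: str) -> tuple[float, float]:
    """100 * mean(activity_a) / mean(activity_b), with delta-method SD.

    Returns ``(percent, sd_percent)``; replicate scatter propagates through
    the ratio of means.
    """
    out = {}
    for cond in (condition_a, condition_b):
        sel = table.loc[table["condition"] == cond, "activity"]
        if sel.empty:
            raise ValueError(f"condition {cond!r} not present")
        vals = sel.to_numpy(dtype=float)
        out[cond] = (vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0,
                     len(vals))
    ma, sa, na = out[condition_a]
    mb, sb, nb = out[condition_b]
    if mb <= 0:
        raise ZeroDivisionError(f"mean activity of {condition_b!r} is not positive")
    pct = 100.0 * ma / mb
    if condition_a == condition_b:
        return pct, 0.0
    rel_var = (sa / ma) ** 2 / na if ma != 0 else 0.0
    rel_var += (sb / mb) ** 2 / nb
    return pct, abs(pct) * math.sqrt(rel_var)


@dataclass
class DoseOptimum:
    concentration_mM: float
    mean_product: float
    interior_maximum: bool
    warnings: list[str] = field(default_factory=list)


def dose_optimum(table: pd.DataFrame) -> DoseOptimum:
    """Concentration with the maximal mean product.

    Ties break toward the lower concentration (with a warning). If the
    optimum sits at the highest tested concentration the result is flagged
    as having no interior maximum.
    """
    if table.empty:
        raise ValueError("empty dose table")
    grouped = (table.groupby("concentration_mM")["product"]
               .mean().sort_index())
    best = grouped.max()
    winners = grouped[np.isclose(grouped, best)].index
    warns = []
    if len(winners) > 1:
        warns.append(f"tie among concentrations {list(winners)}; "
                     "reporting the lowest")
        warnings.warn(warns[-1])
    conc = float(winners.min())
    interior = conc < float(grouped.index.max())
    if not interior:
        warns.append("no interior maximum within the tested range")
    return DoseOptimum(concentration_mM=conc, mean_product=float(best),
                       interior_maximum=interior, warnings=warns)
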