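"""Micellization analysis: CMC break-point fits and micelle geometry.

Surface tension of a surfactant solution falls roughly linearly in
log10(concentration) until the critical micelle concentration (CMC), above
which added monomer goes into micelles and the tension plateaus.  The CMC
is located by a continuous two-segment piecewise-linear least-squares fit
of gamma against log10(c): the break abscissa is scanned on a fine grid,
refined by bounded scalar minimization, and accepted only if it improves on
a single straight line by an F test.  An optional seeded residual-resampling
bootstrap yields confidence bounds on the CMC.

Micelle geometry treats the aggregate as a sphere of hydrodynamic radius
R_H, so V_mic = (4/3) pi R_H^3, and estimates the aggregation number as
N_agg = V_mic / V_mon rounded to the nearest integer (half away from zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .errors import InvalidInputError, InvalidShapeError, NoBreakError

_MIN_POINTS = 6
_F_ALPHA = 0.05


class GeometrySource(str, Enum):
    DLS = "DLS"
    PM6 = "PM6"


@dataclass(frozen=True)
class TensiometryCurve:
    """Surface tension (mN/m) versus surfactant concentration (mM)."""

    label: str
    conc: tuple[float, ...]  # mM
    gamma: tuple[float, ...]  # mN/m
    counterion: Optional[str] = None
    counterion_conc: Optional[float] = None  # mM

    def __post_init__(self):
        c = np.asarray(self.conc, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "conc", tuple(c))
        object.__setattr__(self, "gamma", tuple(g))
        if c.size != g.size:
            raise InvalidInputError(
                f"{self.label}: {c.size} concentrations vs {g.size} tensions"
            )
        if c.size < _MIN_POINTS:
            raise InvalidInputError(
                f"{self.label}: need >= {_MIN_POINTS} points, got {c.size}"
            )
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise InvalidInputError(
                f"{self.label}: concentrations must be positive and strictly increasing"
            )
        if np.any(g <= 0):
            raise InvalidInputError(f"{self.label}: surface tensions must be positive")


@dataclass(frozen=True)
class CmcResult:
    cmc: float  # mM
    gamma_cmc: float  # mN/m at the break
    slope_pre: float  # mN/m per decade
    slope_post: float  # mN/m per decade
    sse: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass(frozen=True)
class MicelleGeometry:
    label: str
    r_h: float  # nm
    v_mic: float  # nm^3
    v_mon: Optional[float] = None  # nm^3
    n_agg: Optional[int] = None
    source: GeometrySource = GeometrySource.DLS

    def __post_init__(self):
        if abs(self.v_mic - sphere_volume(self.r_h)) > 1e-9:
            raise InvalidInputError(
                f"{self.label}: v_mic inconsistent with a sphere of radius {self.r_h}"
            )
        if self.n_agg is not None and self.n_agg < 1:
            raise InvalidInputError(f"{self.label}: n_agg must be >= 1")


def sphere_volume(r_h: float) -> float:
    """Volume (4/3) pi r^3 of a sphere of radius ``r_h`` (nm -> nm^3)."""
    if r_h < 0:
        raise InvalidInputError("radius must be non-negative")
    return 4.0 / 3.0 * math.pi * r_h**3


def aggregation_number(v_mic: float, v_mon: float) -> int:
    """Monomers per micelle: V_mic / V_mon, rounded half away from zero."""
    if v_mic <= 0 or v_mon <= 0:
        raise InvalidInputError("volumes must be positive")
    return max(1, int(math.floor(v_mic / v_mon + 0.5)))


def micelle_geometry(
    label: str,
    r_h: float,
    v_mon: Optional[float] = None,
    source: GeometrySource | str = GeometrySource.DLS,
) -> MicelleGeometry:
    """Assemble a :class:`MicelleGeometry` record from a hydrodynamic radius."""
    v_mic = sphere_volume(r_h)
    n_agg = aggregation_number(v_mic, v_mon) if v_mon is not None else None
    return MicelleGeometry(
        label=label,
        r_h=r_h,
        v_mic=v_mic,
        v_mon=v_mon,
        n_agg=n_agg,
        source=GeometrySource(source),
    )


def _piecewise_design(x: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Design matrices for gamma = a + s1*min(x-b,0) + s2*max(x-b,0)."""
    d = x[None, :] - breaks[:, None]
    return np.stack([np.ones_like(d), np.minimum(d, 0.0), np.maximum(d, 0.0)], axis=-1)


def _fit_at_breaks(
    x: np.ndarray, y: np.ndarray, breaks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched least squares at each candidate break; returns (coefs, sse)."""
    design = _piecewise_design(x, np.atleast_1d(breaks))
    gram = np.einsum("mni,mnj->mij", design, design)
    rhs = np.einsum("mni,n->mi", design, y)
    coefs = np.linalg.solve(gram, rhs[..., None])[..., 0]
    resid = y[None, :] - np.einsum("mni,mi->mn", design, coefs)
    return coefs, np.einsum("mn,mn->m", resid, resid)


def _fit_breakpoint_core(
    x: np.ndarray, y: np.ndarray, n_grid: int
) -> tuple[float, np.ndarray, float]:
    """Grid search + bounded refinement of the break abscissa."""
    lo, hi = x[1], x[-2]
    eps = (hi - lo) * 1e-6
    grid = np.linspace(lo + eps, hi - eps, n_grid)
    _, sses = _fit_at_breaks(x, y, grid)
    j = int(np.argmin(sses))
    b_lo = grid[max(j - 1, 0)]
    b_hi = grid[min(j + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda b: float(_fit_at_breaks(x, y, np.array([b]))[1][0]),
        bounds=(b_lo, b_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best_b = float(res.x) if res.fun <= sses[j] else float(grid[j])
    coefs, sse = _fit_at_breaks(x, y, np.array([best_b]))
    return best_b, coefs[0], float(sse[0])


def fit_cmc_breakpoint(
    curve: TensiometryCurve, n_boot: int = 0, seed: int = 0, n_grid: int = 256
) -> CmcResult:
    """Locate the CMC as the break of a two-segment fit in log-concentration.

    Parameters
    ----------
    curve
        Tensiometry series spanning the break.
    n_boot
        Number of residual-resampling bootstrap replicates for the CMC
        confidence interval; 0 disables the bootstrap.
    seed
        Seed for the bootstrap resampling.
    n_grid
        Number of candidate break abscissae scanned between the 2nd and
        second-to-last points before refinement.

    Raises
    ------
    InvalidShapeError
        If the curve ascends overall or the fitted segments do not flatten
        (pre-break slope not steeper-descending than the post-break slope).
    NoBreakError
        If the two-segment fit does not improve on a single straight line
        at the 5% level of the partial F test.
    """
    x = np.log10(np.asarray(curve.conc))
    y = np.asarray(curve.gamma)
    n = x.size
    slope1, icpt1 = np.polyfit(x, y, 1)
    sse1 = float(np.sum((y - (icpt1 + slope1 * x)) ** 2))
    # a genuinely rising trend, not float fuzz on a flat curve
    if slope1 * (x[-1] - x[0]) > 1e-9 * max(1.0, float(np.max(np.abs(y)))):
        raise InvalidShapeError(
            f"{curve.label}: surface tension rises with concentration; "
            "not a micellization curve"
        )
    best_b, coefs, sse2 = _fit_breakpoint_core(x, y, n_grid)
    gamma_break, slope_pre, slope_post = (float(v) for v in coefs)

    # Partial F test of the break (2 extra parameters) vs the single line.
    scale = float(np.sum((y - y.mean()) ** 2))
    dof = n - 4
    if sse2 <= max(scale, 1.0) * 1e-18 or dof <= 0:
        improved = sse1 - sse2 > max(scale, 1.0) * 1e-12
    else:
        f_stat = ((sse1 - sse2) / 2.0) / (sse2 / dof)
        improved = f_stat > stats.f.ppf(1.0 - _F_ALPHA, 2, dof)
    if not improved:
        raise NoBreakError(
            f"{curve.label}: no interior break improves on a single line"
        )
    if slope_pre >= slope_post:
        raise InvalidShapeError(
            f"{curve.label}: curve steepens past the break instead of "
            "plateauing; not a micellization curve"
        )

    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        design = _piecewise_design(x, np.array([best_b]))[0]
        y_hat = design @ coefs
        resid = y - y_hat
        cmcs = np.empty(n_boot)
        for i in range(n_boot):
            y_b = y_hat + rng.choice(resid, size=n, replace=True)
            b_i, _, _ = _fit_breakpoint_core(x, y_b, n_grid)
            cmcs[i] = 10.0**b_i
        ci_low, ci_high = (float(v) for v in np.percentile(cmcs, [2.5, 97.5]))

    return CmcResult(
        cmc=10.0**best_b,
        gamma_cmc=gamma_break,
        slope_pre=slope_pre,
        slope_post=slope_post,
        sse=sse2,
        ci_low=ci_low,
        ci_high=ci_high,
    )
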