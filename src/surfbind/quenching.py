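"""Fluorescence-quenching analysis of ligand-protein titrations.

A titration follows the intrinsic (tryptophan) emission of a protein such
as bovine serum albumin while a quenching ligand is added.  The stages
implemented here are

* inner-filter correction of the raw intensities,
  ``F_cor = F_obs * 10**((A_ex + A_em) / 2)``;
* the Stern-Volmer regression ``F0/F = 1 + K_SV [Q]``, from which the
  bimolecular quenching rate constant ``k_q = K_SV / tau0`` follows;
* the static-vs-dynamic mechanism call based on the magnitude of ``k_q``
  relative to the diffusion-controlled limit and on the temperature trend
  of ``K_SV``;
* the double-logarithmic binding isotherm
  ``log10[(F0 - F)/F] = log10 K_b + n log10 [Q]`` giving the binding
  constant ``K_b`` and the number of binding sites ``n``.

All regressions are ordinary least squares; residual standard deviations
use ``n - p`` degrees of freedom where ``p`` is the number of fitted
parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidInputError

#: Default unquenched fluorophore lifetime (s); serum albumin is ~5 ns.
DEFAULT_TAU0 = 5e-9

#: Diffusion-controlled ("maximum collision") quenching limit, 1/(M*s).
DIFFUSION_LIMIT_KQ = 2e10


class Mechanism(str, Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TitrationSeries:
    """One fluorescence titration at fixed temperature.

    ``quencher_conc`` is in mol/L, strictly increasing, and must start at 0
    (the zero-quencher row defines ``F0``).  Absorbance lists, when present,
    are the measured excitation/emission absorbances used for the
    inner-filter correction.
    """

    label: str
    temperature: float  # K
    quencher_conc: tuple[float, ...]
    intensity_obs: tuple[float, ...]
    abs_ex: Optional[tuple[float, ...]] = None
    abs_em: Optional[tuple[float, ...]] = None
    tau0: float = DEFAULT_TAU0
    intensity_sd: Optional[tuple[float, ...]] = None  # per-point replicate SD

    def __post_init__(self):
        q = np.asarray(self.quencher_conc, dtype=float)
        f = np.asarray(self.intensity_obs, dtype=float)
        object.__setattr__(self, "quencher_conc", tuple(q))
        object.__setattr__(self, "intensity_obs", tuple(f))
        if q.size != f.size:
            raise InvalidInputError(
                f"{self.label}: {q.size} concentrations vs {f.size} intensities"
            )
        if q.size == 0 or q[0] != 0.0:
            raise InvalidInputError(
                f"{self.label}: first quencher concentration must be 0 (defines F0)"
            )
        if np.any(np.diff(q) <= 0) or np.any(q < 0):
            raise InvalidInputError(
                f"{self.label}: quencher concentrations must be non-negative "
                "and strictly increasing"
            )
        bad = np.flatnonzero(f <= 0)
        if bad.size:
            raise InvalidInputError(
                f"{self.label}: non-positive intensity at index {bad[0]}"
            )
        if self.tau0 <= 0:
            raise InvalidInputError(f"{self.label}: tau0 must be positive")
        for name in ("abs_ex", "abs_em"):
            a = getattr(self, name)
            if a is None:
                continue
            a = np.asarray(a, dtype=float)
            object.__setattr__(self, name, tuple(a))
            if a.size != q.size:
                raise InvalidInputError(
                    f"{self.label}: {name} length {a.size} != {q.size}"
                )
            bad = np.flatnonzero(a < 0)
            if bad.size:
                raise InvalidInputError(
                    f"{self.label}: negative {name} at index {bad[0]}"
                )

    @property
    def f0(self) -> float:
        """Intensity of the zero-quencher row."""
        return self.intensity_obs[0]

    @property
    def n_points(self) -> int:
        return len(self.quencher_conc)

    def has_absorbances(self) -> bool:
        return self.abs_ex is not None and self.abs_em is not None


@dataclass(frozen=True)
class QuenchingFit:
    """Stern-Volmer regression result."""

    ksv: float  # 1/M
    kq: float  # 1/(M*s)
    intercept: float
    r_squared: float
    sd: float
    n_points: int
    mechanism: Mechanism
    note: str = ""


@dataclass(frozen=True)
class BindingFit:
    """Double-log binding isotherm regression result."""

    kb: float  # 1/M
    n_sites: float
    r_squared: float
    sd: float
    n_points_used: int
    excluded_indices: tuple[int, ...] = field(default_factory=tuple)


def correct_inner_filter(f_obs, a_ex, a_em):
    """Inner-filter corrected intensity ``F_obs * 10**((A_ex + A_em)/2)``.

    Accepts scalars or equal-length arrays; element ``i`` failing a
    precondition is named in the raised error.
    """
    f = np.asarray(f_obs, dtype=float)
    ax = np.asarray(a_ex, dtype=float)
    ae = np.asarray(a_em, dtype=float)
    for name, arr, pred in (
        ("intensity", f, f <= 0),
        ("excitation absorbance", ax, ax < 0),
        ("emission absorbance", ae, ae < 0),
    ):
        bad = np.flatnonzero(np.atleast_1d(pred))
        if bad.size:
            raise InvalidInputError(f"invalid {name} at index {bad[0]}")
    out = f * 10.0 ** ((ax + ae) / 2.0)
    return float(out) if np.isscalar(f_obs) or out.ndim == 0 else out


def correct_series(series: TitrationSeries) -> TitrationSeries:
    """Apply the inner-filter correction element-wise to a titration.

    Returns a new series with the absorbance columns consumed (set to
    ``None``); the input is never mutated.  A series without absorbances is
    returned unchanged.
    """
    if not series.has_absorbances():
        return series
    f_cor = correct_inner_filter(series.intensity_obs, series.abs_ex, series.abs_em)
    return replace(series, intensity_obs=tuple(f_cor), abs_ex=None, abs_em=None)


def _ols_stats(y: np.ndarray, y_hat: np.ndarray, n_params: int) -> tuple[float, float]:
    """R^2 and residual SD with n - n_params degrees of freedom."""
    resid = y - y_hat
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    dof = y.size - n_params
    sd = math.sqrt(sse / dof) if dof > 0 else 0.0
    return min(max(r2, 0.0), 1.0), sd


def fit_stern_volmer(
    series: TitrationSeries, fix_intercept: bool = False
) -> QuenchingFit:
    """Fit ``F0/F = intercept + K_SV [Q]`` by ordinary least squares.

    With ``fix_intercept`` the intercept is constrained to exactly 1, as the
    Stern-Volmer model implies; the default free intercept matches common
    plotting practice.  ``k_q`` is ``K_SV / tau0``.  A non-positive slope
    yields a warning and an indeterminate mechanism rather than an error.
    """
    if series.n_points < 3:
        raise InsufficientDataError(
            f"{series.label}: Stern-Volmer fit needs >= 3 points, got {series.n_points}"
        )
    q = np.asarray(series.quencher_conc)
    y = series.f0 / np.asarray(series.intensity_obs)
    if fix_intercept:
        slope = float(q @ (y - 1.0) / (q @ q))
        intercept = 1.0
        n_params = 1
    else:
        slope, intercept = (float(v) for v in np.polyfit(q, y, 1))
        n_params = 2
    r2, sd = _ols_stats(y, intercept + slope * q, n_params)
    if slope <= 0:
        warnings.warn(
            f"{series.label}: non-positive Stern-Volmer slope ({slope:.3g}); "
            "no quenching detected",
            stacklevel=2,
        )
        return QuenchingFit(
            ksv=slope,
            kq=slope / series.tau0,
            intercept=intercept,
            r_squared=r2,
            sd=sd,
            n_points=series.n_points,
            mechanism=Mechanism.INDETERMINATE,
            note="non-positive slope: no quenching",
        )
    kq = slope / series.tau0
    mech, note = _classify(kq, None)
    return QuenchingFit(
        ksv=slope,
        kq=kq,
        intercept=intercept,
        r_squared=r2,
        sd=sd,
        n_points=series.n_points,
        mechanism=mech,
        note=note,
    )


def _classify(
    kq: float,
    ksv_by_temperature: Optional[Mapping[float, float]],
    threshold: float = DIFFUSION_LIMIT_KQ,
) -> tuple[Mechanism, str]:
    above = kq > threshold
    trend = None  # None: absent or flat/mixed
    if ksv_by_temperature is not None and len(ksv_by_temperature) >= 2:
        temps = sorted(ksv_by_temperature)
        ks = [ksv_by_temperature[t] for t in temps]
        diffs = np.diff(ks)
        if np.all(diffs < 0):
            trend = "decreasing"
        elif np.all(diffs > 0):
            trend = "increasing"
    if above and trend in (None, "decreasing"):
        return Mechanism.STATIC, ""
    if not above and trend == "increasing":
        return Mechanism.DYNAMIC, ""
    if above:
        return (
            Mechanism.INDETERMINATE,
            "k_q above the diffusion-controlled limit suggests static quenching, "
            f"but K_SV is not decreasing with temperature (trend: {trend})",
        )
    return (
        Mechanism.INDETERMINATE,
        "k_q at or below the diffusion-controlled limit suggests dynamic "
        f"quenching, but K_SV is not increasing with temperature (trend: {trend})",
    )


def classify_mechanism(
    kq: float,
    ksv_by_temperature: Optional[Mapping[float, float]] = None,
    threshold: float = DIFFUSION_LIMIT_KQ,
) -> Mechanism:
    """Static/dynamic/indeterminate quenching call.

    Static quenching (ground-state complex formation) is called when k_q
    exceeds the diffusion-controlled collision limit of 2e10 1/(M*s) and,
    when a multi-temperature K_SV map is supplied, K_SV strictly decreases
    with temperature.  Dynamic (collisional) quenching requires k_q at or
    below the limit and K_SV strictly increasing.  Conflicting evidence
    returns ``indeterminate``.
    """
    if kq <= 0:
        raise InvalidInputError("k_q must be positive")
    return _classify(kq, ksv_by_temperature, threshold)[0]


def classify_mechanism_with_note(
    kq: float,
    ksv_by_temperature: Optional[Mapping[float, float]] = None,
    threshold: float = DIFFUSION_LIMIT_KQ,
) -> tuple[Mechanism, str]:
    """As :func:`classify_mechanism` but also returns the conflict note."""
    if kq <= 0:
        raise InvalidInputError("k_q must be positive")
    return _classify(kq, ksv_by_temperature, threshold)


def fit_binding_isotherm(series: TitrationSeries) -> BindingFit:
    """Fit ``log10[(F0-F)/F] = log10 K_b + n log10 [Q]`` by OLS.

    Only points with ``[Q] > 0`` and ``F0 - F > 0`` enter the regression;
    excluded indices (intensity at or above F0, typically noise at low
    quencher) are reported on the result.
    """
    if series.n_points < 4:
        raise InsufficientDataError(
            f"{series.label}: binding isotherm needs >= 4 points, got {series.n_points}"
        )
    q = np.asarray(series.quencher_conc)
    f = np.asarray(series.intensity_obs)
    f0 = series.f0
    usable = (q > 0) & (f0 - f > 0)
    excluded = tuple(int(i) for i in np.flatnonzero(~usable[1:]) + 1)
    if int(usable.sum()) < 3:
        raise InsufficientDataError(
            f"{series.label}: only {int(usable.sum())} usable points for the "
            f"binding isotherm (excluded indices: {list(excluded)})"
        )
    x = np.log10(q[usable])
    y = np.log10((f0 - f[usable]) / f[usable])
    slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    r2, sd = _ols_stats(y, intercept + slope * x, 2)
    return BindingFit(
        kb=10.0**intercept,
        n_sites=slope,
        r_squared=r2,
        sd=sd,
        n_points_used=int(usable.sum()),
        excluded_indices=excluded,
    )
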