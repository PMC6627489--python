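"""Van't Hoff thermodynamics of ligand binding.

The temperature dependence of an equilibrium constant,

    ln K = -dH/(R T) + dS/R,

is fitted by ordinary least squares of ln K on 1/T.  The enthalpy change is
``dH = -R * slope`` and the entropy change ``dS = R * intercept``; the Gibbs
energy follows from ``dG = dH - T dS`` at every input temperature.  The
signs of (dH, dS) classify the dominant binding forces by the
Ross-Subramanian rules: both negative points to hydrogen bonding plus
van der Waals contacts, both positive to hydrophobic interactions, and
dH < 0 with dS > 0 to electrostatic interactions.

Units follow the field's reporting convention: dH and dG in kJ/mol, dS in
J/(mol K); temperatures in kelvin; R = 8.314 J/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np

from .errors import InsufficientDataError, InvalidInputError

R_GAS = 8.314  # J/(mol K)


class ForceClass(str, Enum):
    HBOND_VDW = "hbond_vdw"
    HYDROPHOBIC = "hydrophobic"
    ELECTROSTATIC = "electrostatic"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TemperatureSeries:
    """Equilibrium constants of one system over several temperatures."""

    label: str
    temperatures: tuple[float, ...]  # K
    k_values: tuple[float, ...]  # 1/M

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        k = np.asarray(self.k_values, dtype=float)
        object.__setattr__(self, "temperatures", tuple(t))
        object.__setattr__(self, "k_values", tuple(k))
        if t.size != k.size:
            raise InvalidInputError(
                f"{self.label}: {t.size} temperatures vs {k.size} K values"
            )
        if np.unique(t).size < 2:
            raise InsufficientDataError(
                f"{self.label}: need >= 2 distinct temperatures"
            )
        if np.any(k <= 0):
            raise InvalidInputError(f"{self.label}: all K must be positive")
        if np.any(t <= 0):
            raise InvalidInputError(f"{self.label}: temperatures must be in kelvin")


@dataclass(frozen=True)
class ThermoResult:
    delta_h: float  # kJ/mol
    delta_s: float  # J/(mol K)
    delta_g_by_temperature: Mapping[float, float]  # K -> kJ/mol
    r_squared: float
    sd: float
    force_class: ForceClass
    note: str = ""

    @property
    def spontaneous(self) -> Mapping[float, bool]:
        return {t: g < 0 for t, g in self.delta_g_by_temperature.items()}


def gibbs_from_enthalpy_entropy(delta_h: float, delta_s: float, t: float) -> float:
    """dG = dH - T*dS, with dH in kJ/mol and dS in J/(mol K)."""
    if t <= 0:
        raise InvalidInputError("temperature must be positive kelvin")
    return delta_h - t * delta_s / 1000.0


def gibbs_from_k(k: float, t: float) -> float:
    """dG = -R T ln K, in kJ/mol."""
    if k <= 0 or t <= 0:
        raise InvalidInputError("K and T must be positive")
    return -R_GAS * t * math.log(k) / 1000.0


def classify_binding_forces(delta_h: float, delta_s: float) -> ForceClass:
    """Sign-based Ross-Subramanian classification of the binding forces."""
    return _classify_forces(delta_h, delta_s)[0]


def _classify_forces(delta_h: float, delta_s: float) -> tuple[ForceClass, str]:
    if delta_h == 0 or delta_s == 0:
        return (
            ForceClass.INDETERMINATE,
            "a vanishing dH or dS does not discriminate between force types",
        )
    if delta_h < 0 and delta_s < 0:
        return ForceClass.HBOND_VDW, ""
    if delta_h > 0 and delta_s > 0:
        return ForceClass.HYDROPHOBIC, ""
    if delta_h < 0 and delta_s > 0:
        return ForceClass.ELECTROSTATIC, ""
    # dH > 0, dS < 0: binding would be non-spontaneous at all T
    return (
        ForceClass.INDETERMINATE,
        "dH > 0 with dS < 0 lies outside the Ross-Subramanian rule set",
    )


def fit_vant_hoff(series: TemperatureSeries) -> ThermoResult:
    """OLS of ln K against 1/T; returns dH, dS, per-temperature dG.

    With exactly two points the line is exact: R^2 = 1 and sd = 0 by
    construction.  The residual SD uses n - 2 degrees of freedom.
    """
    t = np.asarray(series.temperatures)
    k = np.asarray(series.k_values)
    x = 1.0 / t
    y = np.log(k)
    slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    delta_h = -R_GAS * slope / 1000.0  # kJ/mol
    delta_s = R_GAS * intercept  # J/(mol K)
    resid = y - (intercept + slope * x)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if t.size == 2 or sst == 0 else 1.0 - sse / sst
    dof = t.size - 2
    sd = math.sqrt(sse / dof) if dof > 0 else 0.0
    dg = {float(ti): gibbs_from_enthalpy_entropy(delta_h, delta_s, float(ti)) for ti in t}
    force, note = _classify_forces(delta_h, delta_s)
    return ThermoResult(
        delta_h=delta_h,
        delta_s=delta_s,
        delta_g_by_temperature=dg,
        r_squared=min(max(r2, 0.0), 1.0),
        sd=sd,
        force_class=force,
        note=note,
    )
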