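"""Seeded generators emulating the study's instrument outputs.

Raw fluorescence spectra and tensiometry readings for surfactant-protein
work are rarely published, so every pipeline stage here is exercised
against synthetic data drawn from the forward models the analysis inverts:

* titrations obey ``F = F0 / (1 + K_SV [Q])`` (or the binding isotherm
  ``F = F0 / (1 + K_b [Q]^n)``), optionally attenuated by the inner-filter
  factor ``10**(-(A_ex + A_em)/2)`` with absorbances growing linearly in
  quencher concentration (Beer-Lambert), then perturbed by multiplicative
  Gaussian noise (fluorescence shot/gain noise is scale-proportional);
* equilibrium constants follow the Van't Hoff line
  ``K(T) = exp(-dH/(R T) + dS/R)``;
* surface tension is piecewise-linear in log10(concentration) with a
  continuous break at the CMC, plus additive Gaussian noise
  (instrument-limited).

Every generator is a pure function of its spec, seed included: the same
spec yields a byte-identical series.  Default grids mirror the study
conditions: quencher 0-120 uM, temperatures 298/303/310 K, surfactant
0.003-0.12 mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError
from .micelle import TensiometryCurve
from .quenching import DEFAULT_TAU0, TitrationSeries
from .thermo import R_GAS, TemperatureSeries

#: Quencher grid of the study's titrations (mol/L): 0-120 uM.
DEFAULT_CONC_GRID = (0.0, 10e-6, 20e-6, 50e-6, 70e-6, 100e-6, 120e-6)

#: The study's three working temperatures (K), 25/30/37 C with K = C + 273.
DEFAULT_TEMPERATURES = (298.0, 303.0, 310.0)

#: Surfactant grid (mM) spanning the tensiometric range 0.003-0.12 mM.
DEFAULT_TENSIO_GRID = tuple(np.geomspace(0.003, 0.12, 12))


@dataclass(frozen=True)
class TitrationSpec:
    """Forward model of one fluorescence titration.

    Exactly one quenching model must be specified: ``ksv_true`` alone for
    the Stern-Volmer model, or ``kb_true`` together with ``n_true`` for the
    binding isotherm.
    """

    f0: float = 1000.0
    ksv_true: Optional[float] = None  # 1/M
    kb_true: Optional[float] = None  # 1/M
    n_true: Optional[float] = None
    conc_grid: tuple[float, ...] = DEFAULT_CONC_GRID
    noise_rel: float = 0.0
    inner_filter_slope: float = 0.0  # absorbance per molar quencher
    temperature: float = 298.0
    tau0: float = DEFAULT_TAU0
    label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.f0 <= 0:
            raise ConfigError("f0 must be positive")
        if self.noise_rel < 0:
            raise ConfigError("noise_rel must be non-negative")
        if self.conc_grid[0] != 0.0:
            raise ConfigError("conc_grid must start at 0 (defines F0)")
        sv = self.ksv_true is not None
        kb, n = self.kb_true is not None, self.n_true is not None
        if kb != n:
            raise ConfigError(
                "binding-isotherm model needs both kb_true and n_true"
            )
        if sv and kb:
            raise ConfigError(
                "ambiguous model: give either ksv_true or (kb_true, n_true)"
            )
        if not sv and not kb:
            raise ConfigError("one of ksv_true or (kb_true, n_true) is required")
        if sv and self.ksv_true <= 0:
            raise ConfigError("ksv_true must be positive")
        if kb and (self.kb_true <= 0 or self.n_true <= 0):
            raise ConfigError("kb_true and n_true must be positive")


@dataclass(frozen=True)
class ThermoSpec:
    """Forward model of a multi-temperature equilibrium-constant table."""

    delta_h_true: float  # kJ/mol
    delta_s_true: float  # J/(mol K)
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    noise_rel: float = 0.0
    label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ConfigError("temperatures must be distinct")
        if self.noise_rel < 0:
            raise ConfigError("noise_rel must be non-negative")


@dataclass(frozen=True)
class TensiometrySpec:
    """Forward model of a descending-then-plateau surface-tension curve.

    The pre-CMC segment is fixed either by ``slope_pre`` (mN/m per decade)
    or, when that is None, by requiring the line through the plateau at the
    CMC to pass through ``gamma0`` at the lowest grid concentration.
    """

    gamma0: float = 69.4  # mN/m at the lowest concentration
    slope_pre: Optional[float] = None  # mN/m per decade, < 0
    cmc_true: float = 0.045  # mM
    gamma_plateau: float = 28.4  # mN/m
    conc_grid: tuple[float, ...] = field(default_factory=lambda: DEFAULT_TENSIO_GRID)
    noise_sd: float = 0.0  # mN/m
    label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if not (self.conc_grid[0] < self.cmc_true < self.conc_grid[-1]):
            raise ConfigError("cmc_true must lie strictly inside conc_grid")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.slope_pre is not None and self.slope_pre > 0:
            raise ConfigError("slope_pre must be <= 0")

    @property
    def effective_slope_pre(self) -> float:
        if self.slope_pre is not None:
            return self.slope_pre
        span = np.log10(self.cmc_true) - np.log10(self.conc_grid[0])
        return (self.gamma_plateau - self.gamma0) / span


def simulate_titration(spec: TitrationSpec) -> TitrationSeries:
    """Generate a :class:`TitrationSeries` from the forward quenching model."""
    q = np.asarray(spec.conc_grid, dtype=float)
    if spec.ksv_true is not None:
        f = spec.f0 / (1.0 + spec.ksv_true * q)
    else:
        f = spec.f0 / (1.0 + spec.kb_true * np.where(q > 0, q, 0.0) ** spec.n_true)
        f[q == 0] = spec.f0
    abs_ex = abs_em = None
    if spec.inner_filter_slope > 0:
        a = spec.inner_filter_slope * q
        f = f * 10.0 ** (-(a + a) / 2.0)
        abs_ex = abs_em = tuple(a)
    if spec.noise_rel > 0:
        rng = np.random.default_rng(spec.seed)
        f = f * (1.0 + spec.noise_rel * rng.standard_normal(q.size))
        f = np.maximum(f, 1e-12 * spec.f0)  # intensities stay positive
    return TitrationSeries(
        label=spec.label,
        temperature=spec.temperature,
        quencher_conc=tuple(q),
        intensity_obs=tuple(f),
        abs_ex=abs_ex,
        abs_em=abs_em,
        tau0=spec.tau0,
    )


def vant_hoff_k(delta_h: float, delta_s: float, t: float) -> float:
    """K(T) = exp(-dH/(R T) + dS/R); dH in kJ/mol, dS in J/(mol K)."""
    return float(np.exp(-delta_h * 1000.0 / (R_GAS * t) + delta_s / R_GAS))


def simulate_temperature_series(spec: ThermoSpec) -> TemperatureSeries:
    """Generate equilibrium constants on (or near) a Van't Hoff line."""
    t = np.asarray(spec.temperatures, dtype=float)
    k = np.array([vant_hoff_k(spec.delta_h_true, spec.delta_s_true, ti) for ti in t])
    if spec.noise_rel > 0:
        rng = np.random.default_rng(spec.seed)
        k = k * (1.0 + spec.noise_rel * rng.standard_normal(t.size))
        k = np.maximum(k, 1e-12)
    return TemperatureSeries(label=spec.label, temperatures=tuple(t), k_values=tuple(k))


def simulate_tensiometry(spec: TensiometrySpec) -> TensiometryCurve:
    """Generate a surface-tension curve with a continuous break at the CMC."""
    c = np.asarray(spec.conc_grid, dtype=float)
    x = np.log10(c)
    x_cmc = np.log10(spec.cmc_true)
    gamma = spec.gamma_plateau + spec.effective_slope_pre * np.minimum(x - x_cmc, 0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gamma = gamma + spec.noise_sd * rng.standard_normal(c.size)
        gamma = np.maximum(gamma, 1e-6)
    return TensiometryCurve(label=spec.label, conc=tuple(c), gamma=tuple(gamma))
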