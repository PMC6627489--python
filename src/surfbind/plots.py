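"""Optional diagnostic plots for each analysis stage (matplotlib, Agg)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .micelle import CmcResult, TensiometryCurve
from .quenching import BindingFit, QuenchingFit, TitrationSeries
from .thermo import TemperatureSeries, ThermoResult


def plot_stern_volmer(series: TitrationSeries, fit: QuenchingFit, path) -> None:
    q = np.asarray(series.quencher_conc)
    y = series.f0 / np.asarray(series.intensity_obs)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(q * 1e6, y, "o", label="data")
    ax.plot(q * 1e6, fit.intercept + fit.ksv * q, "-",
            label=f"$K_{{SV}}$ = {fit.ksv:.4g} M$^{{-1}}$")
    ax.set_xlabel("[Q] (µM)")
    ax.set_ylabel("$F_0/F$")
    ax.set_title(series.label)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_binding_isotherm(series: TitrationSeries, fit: BindingFit, path) -> None:
    q = np.asarray(series.quencher_conc)
    f = np.asarray(series.intensity_obs)
    ok = (q > 0) & (series.f0 - f > 0)
    x = np.log10(q[ok])
    y = np.log10((series.f0 - f[ok]) / f[ok])
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(x, y, "o", label="data")
    ax.plot(x, np.log10(fit.kb) + fit.n_sites * x, "-",
            label=f"$K_b$ = {fit.kb:.4g} M$^{{-1}}$, n = {fit.n_sites:.2f}")
    ax.set_xlabel("log$_{10}$ [Q]")
    ax.set_ylabel("log$_{10}$ [(F$_0$−F)/F]")
    ax.set_title(series.label)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_vant_hoff(series: TemperatureSeries, result: ThermoResult, path) -> None:
    t = np.asarray(series.temperatures)
    x = 1.0 / t
    y = np.log(np.asarray(series.k_values))
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(x * 1e3, y, "o", label="data")
    slope = -result.delta_h * 1000.0 / 8.314
    icpt = result.delta_s / 8.314
    ax.plot(x * 1e3, icpt + slope * x, "-",
            label=f"ΔH = {result.delta_h:.2f} kJ/mol")
    ax.set_xlabel("$10^3/T$ (K$^{-1}$)")
    ax.set_ylabel("ln K")
    ax.set_title(series.label)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tensiometry(curve: TensiometryCurve, result: CmcResult, path) -> None:
    x = np.log10(np.asarray(curve.conc))
    b = np.log10(result.cmc)
    xx = np.linspace(x.min(), x.max(), 200)
    yy = result.gamma_cmc + np.where(
        xx < b, result.slope_pre * (xx - b), result.slope_post * (xx - b)
    )
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(x, curve.gamma, "o", label="data")
    ax.plot(xx, yy, "-", label=f"CMC = {result.cmc:.3g} mM")
    ax.axvline(b, ls=":", c="grey")
    ax.set_xlabel("log$_{10}$ c (mM)")
    ax.set_ylabel("γ (mN/m)")
    ax.set_title(curve.label)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
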