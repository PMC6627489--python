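# surfbind

Biophysical analysis of surfactant–protein binding and micellization:
fluorescence-quenching titrations, Van't Hoff thermodynamics, and
tensiometric critical-micelle-concentration (CMC) determination, packaged
as a tested Python library, a set of analysis drivers, and a command-line
tool.

The package targets the standard characterization workflow for a ligand —
here the cyclic lipopeptide biosurfactant surfactin-C15 and its divalent
metal complexes (Cu²⁺, Zn²⁺, Mg²⁺, Ca²⁺) — interacting with bovine serum
albumin (BSA), whose intrinsic tryptophan fluorescence is quenched on
binding:

* **Quenching** (`surfbind.quenching`): inner-filter correction
  `F_cor = F_obs·10^((A_ex+A_em)/2)`; the Stern–Volmer fit
  `F₀/F = 1 + K_SV[Q]` with `k_q = K_SV/τ₀`; the static/dynamic mechanism
  call (`k_q` vs the 2×10¹⁰ M⁻¹s⁻¹ diffusion limit plus the temperature
  trend of `K_SV`); and the double-log binding isotherm
  `log[(F₀−F)/F] = log K_b + n·log[Q]`.
* **Thermodynamics** (`surfbind.thermo`): OLS of `ln K` on `1/T`
  (`ΔH = −R·slope`, `ΔS = R·intercept`), `ΔG = ΔH − TΔS = −RT ln K`, and
  the Ross–Subramanian sign rules for the dominant binding forces.
* **Micellization** (`surfbind.micelle`): continuous two-segment
  piecewise-linear break-point fit of γ vs log₁₀(c) for the CMC (with a
  seeded residual bootstrap for confidence bounds), spherical micelle
  volumes `V_mic = (4/3)πR_H³` and aggregation numbers
  `N_agg = V_mic/V_mon`.
* **Synthetic data** (`surfbind.synthetic`): seeded generators for all
  three instrument outputs, used by the drivers and the test suite.
* **I/O and CLI** (`surfbind.io`, `surfbind.cli`): delimited-text readers,
  a YAML-configurable full pipeline producing a JSON study report, and the
  `surfbind` command with `simulate-*`, `quench`, `binding`, `vanthoff`,
  `cmc`, `micelle` and `report` subcommands.

## Worked example

```python
from surfbind import (TemperatureSeries, TitrationSpec, fit_stern_volmer,
                      fit_vant_hoff, simulate_titration)

# a noiseless titration generated from K_SV = 7292 1/M, then refitted
series = simulate_titration(TitrationSpec(ksv_true=7.292e3, label="Cu-surfactin"))
fit = fit_stern_volmer(series)
print(f"K_SV = {fit.ksv:.4g} 1/M, k_q = {fit.kq:.4g} 1/(M s), "
      f"mechanism = {fit.mechanism.value}")

# Van't Hoff analysis of the measured Cu-complex constants at 25/30/37 C
res = fit_vant_hoff(TemperatureSeries(
    "Cu-surfactin", (298.0, 303.0, 310.0), (7.292e3, 5.102e3, 3.267e3)))
print(f"dH = {res.delta_h:.2f} kJ/mol, dS = {res.delta_s:.2f} J/(mol K), "
      f"dG(298 K) = {res.delta_g_by_temperature[298.0]:.2f} kJ/mol, "
      f"forces = {res.force_class.value}")
```

prints

```
K_SV = 7292 1/M, k_q = 1.458e+12 1/(M s), mechanism = static
dH = -51.30 kJ/mol, dS = -98.23 J/(mol K), dG(298 K) = -22.02 kJ/mol, forces = hbond_vdw
```

— the quenching rate is two orders of magnitude above the diffusion limit
(static, complex-forming quenching), and the negative ΔH and ΔS mark
hydrogen bonding plus van der Waals contacts as the dominant binding
forces, with binding spontaneous (ΔG < 0) at all three temperatures.

The same stages run from the shell:

```sh
surfbind simulate-titration --out titr.csv --ksv 7292 --label Cu-surfactin
surfbind quench titr.csv
surfbind report --titration titr.csv --out report.json
```

## Analysis drivers

The `analysis/` scripts narrate the full study end to end and write their
tables under `results/`:

1. `01_simulate_data.py` — seeded synthetic instrument tables for all five
   systems (titrations at three temperatures, tensiometry curves, the
   multi-temperature constant table, micelle geometry inputs);
2. `02_quenching_fits.py` — Stern–Volmer and binding fits with recovery
   errors against the generating truths;
3. `03_thermodynamics.py` — Van't Hoff ΔH/ΔS/ΔG and force classes for the
   five systems from their measured constants;
4. `04_micellization.py` — CMC break-point fits with bootstrap intervals,
   micelle volumes and aggregation numbers.

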