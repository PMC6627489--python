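# Methods

`surfbind` implements the quantitative workflow used to characterize how a
surfactant ligand (here surfactin-C15 and its divalent-metal complexes)
binds a fluorescent protein (bovine serum albumin, BSA) and how it
self-assembles into micelles. This note records the models, the defaults
and why, the numerical choices, and what the synthetic-data validation
does and does not establish.

## Fluorescence quenching

**Inner-filter correction.** Measured intensities are attenuated by the
absorbance of the sample at the excitation and emission wavelengths. The
standard first-order correction

    F_cor = F_obs · 10^((A_ex + A_em)/2)

is applied element-wise whenever a titration table carries absorbance
columns, and skipped with a logged notice when it does not (absorbance
readings are often not recorded alongside the intensities). The correction
is the identity at zero absorbance and strictly increasing in both
arguments.

**Stern–Volmer regression.** With `F0` the intensity at zero quencher and
`[Q]` the quencher concentration (mol/L),

    F0/F = 1 + K_SV [Q],

fitted by ordinary least squares of `F0/F` on `[Q]`. The model implies an
intercept of exactly 1; the default fit leaves the intercept free, which is
what plotted fits in practice report and what the quoted R²/SD columns of
published work correspond to, with a `fix_intercept` option to constrain it
(the two agree identically on noiseless data). `F0` is taken strictly from
the `[Q] = 0` row — a series without one is rejected. The bimolecular
quenching rate constant is `k_q = K_SV/τ0` with `τ0 = 5 ns` by default
(the BSA tryptophan lifetime); the division is carried out at full
precision so `k_q` is bit-identical to `K_SV/τ0`.

**Mechanism call.** Quenching is classified *static* (ground-state complex
formation) when `k_q` exceeds the diffusion-controlled collision limit of
`2×10¹⁰ M⁻¹s⁻¹` and, when constants at several temperatures are available,
`K_SV` strictly decreases with temperature; *dynamic* (collisional) when
`k_q` is at or below the limit and `K_SV` strictly increases; conflicting
evidence yields *indeterminate* with an explanatory note. The threshold is
configurable (`quench_threshold`).

**Binding isotherm.** For static quenchers the double-logarithmic isotherm

    log10[(F0 − F)/F] = log10 K_b + n · log10 [Q]

is fitted over the points with `[Q] > 0` and `F0 − F > 0`; points where
noise pushed `F` to or above `F0` are excluded and reported by index.
Base-10 logarithms are used throughout this stage (natural logs appear only
in the Van't Hoff fit). At least three usable points are required.

**Replicates.** Tables may carry replicate intensity columns
(`F_obs_2`, ...); they are averaged point-wise before fitting and the
per-point replicate SD is retained on the series.

**Regression dispersion.** R² is the ordinary coefficient of determination;
the reported SD is the residual standard deviation with `n − p` degrees of
freedom (`p` = number of fitted parameters, so `n − 2` for the default
free-intercept fits).

## Van't Hoff thermodynamics

Equilibrium constants at several temperatures are regressed as

    ln K = −ΔH/(R T) + ΔS/R,   R = 8.314 J/(mol·K),

by OLS of `ln K` on `1/T`; `ΔH = −R·slope` (reported in kJ/mol) and
`ΔS = R·intercept` (J/(mol·K)). Gibbs energies follow at every input
temperature from `ΔG = ΔH − TΔS`, and the sign pattern of (ΔH, ΔS)
classifies the dominant binding forces (Ross–Subramanian rules): both
negative → hydrogen bonds + van der Waals; both positive → hydrophobic;
ΔH < 0, ΔS > 0 → electrostatic; a vanishing component → indeterminate.

Two conventions matter for digit-level reproduction of the reference
system and are therefore the defaults:

* **Which K.** Binding constants are typically printed at one temperature
  only, while Stern–Volmer constants are printed at all three; for a static
  quencher `K_SV` reflects complex formation, and regressing `ln K_SV`
  reproduces the published ΔH/ΔS of the reference systems to the printed
  precision. The fit accepts any `TemperatureSeries`, so either constant
  can be supplied.
* **Kelvin offset.** Temperatures convert as `K = °C + 273` exactly (not
  273.15); this is the convention under which the published ΔG table
  reproduces digit-for-digit. It is configurable (`kelvin_offset`).

With exactly two temperatures the line is exact and `R² = 1`, `sd = 0` by
construction. Full precision is kept internally; rendering rounds to two
decimals for ΔH/ΔG (kJ/mol) and ΔS (J/(mol·K)). No curved (heat-capacity)
Van't Hoff model is offered, and K-uncertainty is not propagated beyond
the regression residuals.

## Micellization

**CMC break-point.** Surface tension γ is modeled as continuous and
piecewise-linear in `x = log10(c)`:

    γ(x) = a + s_pre·min(x − b, 0) + s_post·max(x − b, 0),

so `a` is the fitted tension at the break and `CMC = 10^b`. For each
candidate `b` the conditional fit is linear; the SSE profile over ≥ 200
candidates between the 2nd and (n−1)th points is minimized (batched normal
equations), then the best cell is refined by bounded scalar minimization
(tolerance 1e-10 in `b`). The break is accepted only if it beats a single
straight line in a partial F test (2 extra parameters, α = 0.05);
otherwise a *no-break* error is raised — a flat or perfectly straight
curve lands here. A curve whose overall trend rises, or whose fitted
segments steepen rather than flatten past the break, raises an
*invalid-shape* error. γ_cmc is the fitted value at the break rather than
the minimum observed tension, which is robust to plateau noise.

**Bootstrap CI.** Optional confidence bounds come from residual
resampling: residuals of the fitted model are resampled with replacement
(seeded), re-added to the fitted curve, and the break re-estimated;
`ci_low/ci_high` are the 2.5/97.5 percentiles of the recovered CMCs.
Percentile intervals from residual resampling on break-point estimates are
known to undercover slightly; at the validation noise level they cover the
truth in ≈ 86–97% of seeded replicates.

**Geometry.** Micelles are treated as spheres: `V_mic = (4/3)π R_H³` from
the hydrodynamic radius (DLS or quantum-chemical modeling), and
`N_agg = V_mic/V_mon` rounded half-away-from-zero with a floor of one
monomer. No Gibbs-adsorption surface-excess analysis and no non-spherical
shape models are included.

## Synthetic data

Raw spectra and tensiometry readings for this class of study are rarely
deposited, so the generators in `surfbind.synthetic` produce seeded
stand-ins from the exact forward models the analysis inverts:

* titrations from `F = F0/(1 + K_SV[Q])` or `F = F0/(1 + K_b[Q]^n)`, with
  optional inner-filter attenuation `10^(−(A_ex+A_em)/2)` where the
  absorbances grow linearly with quencher concentration (Beer–Lambert,
  slope shared between excitation and emission), and multiplicative
  Gaussian intensity noise — fluorescence shot/gain noise scales with the
  signal;
* equilibrium constants on the Van't Hoff line with multiplicative noise;
* tensiometry curves piecewise-linear in log-concentration with a
  continuous break at the CMC and additive Gaussian noise — tensiometer
  error is absolute, not proportional.

Default grids mirror the study conditions: quencher 0–120 µM (seven
points), temperatures 298/303/310 K, surfactant 0.003–0.12 mM (twelve
log-spaced points), buffer tension 69.4 mN/m, plateau 28.4 mN/m, CMC
0.045 mM, 1% intensity noise and 0.3 mN/m tension noise where noise is
used. Generators are pure functions of their spec (seed included).

Because the generators share their functional form with the fitted models,
round-trip recovery demonstrates correctness of the estimators and their
noise robustness at realistic levels — it does not probe model
misspecification (curved pre-CMC tensiometry, combined static+dynamic
quenching, wavelength-dependent inner-filter effects), which real data may
show and which is out of scope here.

## Problem sizes and determinism

The stochastic validation uses 200 seeded titrations (1% noise) for the
Stern–Volmer recovery, 100 seeded tensiometry curves (σ = 0.3 mN/m) for
CMC recovery, and 100 bootstrap-covered replicates at 199 resamples each;
all seeds are fixed in the test suite and analysis drivers. Every quantity
in the reproduction script `scripts/acceptance.py` is a deterministic
regression of published inputs.

## Known limitations

* One reference system (the Zn complex) has a published ΔH that differs
  from the value its own multi-temperature constants imply by ~0.4 kJ/mol
  (−51.95 recomputed vs −51.59 published, with ΔS agreeing); the pipeline
  reports the recomputed value, and `analysis/03_thermodynamics.py` flags
  the discrepancy.
* The per-temperature R²/SD columns that published thermodynamic tables
  sometimes attach to a single regression have no standard definition and
  are not reproduced; the regression's own R² and residual SD are reported
  once per system.
* The CMC estimator assumes exactly one break; multi-transition curves
  (e.g. premicellar aggregation) are not modeled.
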