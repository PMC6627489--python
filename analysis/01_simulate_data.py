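#!/usr/bin/env python
"""Generate synthetic instrument tables for all five surfactant systems.

The raw spectra and tensiometry readings of the study were never deposited,
so this driver writes stand-ins drawn from the forward models at the
published parameter values: one fluorescence titration per system and
temperature (K_SV from the measured Stern-Volmer constants, 1% intensity
noise), one surface-tension curve per system (break at the published CMC,
sigma = 0.3 mN/m), one multi-temperature constant table, and the micelle
geometry table.  Everything is seeded and lands under results/synthetic/.
"""

from pathlib import Path

from surfbind.datasets import (
    CMC_MM,
    GAMMA_BUFFER,
    GAMMA_CMC,
    MICELLE_RH_PM6,
    MICELLE_VMON_PM6,
    STERN_VOLMER_KSV,
    SYSTEMS,
    TEMPERATURES_K,
)
from surfbind.synthetic import TensiometrySpec, TitrationSpec, simulate_tensiometry, simulate_titration

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    n_files = 0

    for si, system in enumerate(SYSTEMS):
        for ti, (t_k, ksv) in enumerate(zip(TEMPERATURES_K, STERN_VOLMER_KSV[system])):
            series = simulate_titration(TitrationSpec(
                ksv_true=ksv, noise_rel=0.01, temperature=t_k,
                label=system, seed=100 * si + ti,
            ))
            stem = f"titration_{system}_{int(t_k)}K"
            rows = ["quencher_M,F_obs"] + [
                f"{q:.10g},{f:.10g}"
                for q, f in zip(series.quencher_conc, series.intensity_obs)
            ]
            (OUT / f"{stem}.csv").write_text("\n".join(rows) + "\n")
            (OUT / f"{stem}.yaml").write_text(
                f"label: {system}\ntemperature_C: {t_k - 273.0:g}\n"
            )
            n_files += 1

        curve = simulate_tensiometry(TensiometrySpec(
            gamma0=GAMMA_BUFFER, cmc_true=CMC_MM[system],
            gamma_plateau=GAMMA_CMC.get(system, 28.4),
            noise_sd=0.3, label=system, seed=1000 + si,
        ))
        rows = ["conc_mM,gamma_mN_m"] + [
            f"{c:.10g},{g:.10g}" for c, g in zip(curve.conc, curve.gamma)
        ]
        (OUT / f"tensiometry_{system}.csv").write_text("\n".join(rows) + "\n")
        (OUT / f"tensiometry_{system}.yaml").write_text(f"label: {system}\n")
        n_files += 1

    rows = ["label,temperature_C,K_per_M"]
    for system in SYSTEMS:
        rows += [
            f"{system},{t - 273.0:g},{k:.10g}"
            for t, k in zip(TEMPERATURES_K, STERN_VOLMER_KSV[system])
        ]
    (OUT / "stern_volmer_constants.csv").write_text("\n".join(rows) + "\n")

    rows = ["label,R_H_nm,V_mon_nm3,source"]
    rows += [f"{s},{MICELLE_RH_PM6[s]},{MICELLE_VMON_PM6[s]},PM6" for s in SYSTEMS]
    (OUT / "micelle_geometry.csv").write_text("\n".join(rows) + "\n")

    print(f"wrote {n_files + 2} tables to {OUT}")


if __name__ == "__main__":
    main()
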