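"""Reference measurements for the surfactin / metal-surfactin / BSA study.

These are the published working values for surfactin-C15 and its divalent
metal complexes (Cu2+, Zn2+, Mg2+, Ca2+) interacting with bovine serum
albumin: Stern-Volmer constants at three temperatures, binding constants,
thermodynamic parameters, micelle geometry from dynamic light scattering
(DLS) and PM6 semi-empirical modeling, and the tensiometric CMC anchors.

They are *inputs* to the analysis drivers, tests and the reproduction
script — for example, the Van't Hoff regressions recompute dH/dS from the
Stern-Volmer constants below rather than restating the published values.
"""

from __future__ import annotations

SYSTEMS = ("Cu-surfactin", "Zn-surfactin", "Mg-surfactin", "Ca-surfactin", "surfactin")

#: Working temperatures (K): 25/30/37 C with the study's K = C + 273 convention.
TEMPERATURES_K = (298.0, 303.0, 310.0)

#: Fluorophore lifetime of BSA (s).
TAU0_BSA = 5e-9

#: Stern-Volmer constants K_SV (1/M) per system at 298/303/310 K.
STERN_VOLMER_KSV: dict[str, tuple[float, float, float]] = {
    "Cu-surfactin": (7.292e3, 5.102e3, 3.267e3),
    "Zn-surfactin": (7.787e3, 5.186e3, 3.439e3),
    "Mg-surfactin": (6.917e3, 4.973e3, 3.148e3),
    "Ca-surfactin": (6.992e3, 4.993e3, 3.245e3),
    "surfactin": (6.696e3, 4.926e3, 3.147e3),
}

#: Reported bimolecular quenching rate constants k_q (1/(M s)), same order.
REPORTED_KQ: dict[str, tuple[float, float, float]] = {
    "Cu-surfactin": (1.458e12, 1.020e12, 6.534e11),
    "Zn-surfactin": (1.557e12, 1.037e12, 6.878e11),
    "Mg-surfactin": (1.383e12, 9.946e11, 6.296e11),
    "Ca-surfactin": (1.398e12, 9.986e11, 6.490e11),
    "surfactin": (1.339e12, 9.852e11, 6.294e11),
}

#: Binding constants K_b (1/M) and site numbers n at 298 K.
BINDING_PARAMS: dict[str, tuple[float, float]] = {
    "Cu-surfactin": (0.980e4, 1.03),
    "Zn-surfactin": (0.746e4, 0.99),
    "Mg-surfactin": (1.267e4, 1.07),
    "Ca-surfactin": (0.986e4, 1.03),
    "surfactin": (1.315e4, 1.07),
}

#: Reported thermodynamics: dH (kJ/mol), dS (J/(mol K)), dG (kJ/mol) at
#: 298/303/310 K.
REPORTED_THERMO: dict[str, dict[str, object]] = {
    "Cu-surfactin": {"dH": -51.30, "dS": -98.23, "dG": (-22.03, -21.54, -20.85)},
    "Zn-surfactin": {"dH": -51.59, "dS": -100.02, "dG": (-21.78, -21.28, -20.58)},
    "Mg-surfactin": {"dH": -50.42, "dS": -95.67, "dG": (-21.91, -21.43, -20.76)},
    "Ca-surfactin": {"dH": -49.07, "dS": -91.10, "dG": (-21.92, -21.47, -20.83)},
    "surfactin": {"dH": -48.42, "dS": -89.20, "dG": (-21.84, -21.39, -20.77)},
}

#: Micelle geometry: hydrodynamic radii R_H (nm) from DLS and PM6 modeling,
#: monomer volumes V_mon (nm^3) from PM6, reported micelle volumes (nm^3)
#: and aggregation numbers.
MICELLE_RH_DLS: dict[str, float] = {
    "surfactin": 2.46,
    "Cu-surfactin": 1.82,
    "Zn-surfactin": 2.05,
    "Mg-surfactin": 2.12,
    "Ca-surfactin": 2.38,
}
MICELLE_RH_PM6: dict[str, float] = {
    "surfactin": 2.4,
    "Cu-surfactin": 1.8,
    "Zn-surfactin": 2.0,
    "Mg-surfactin": 2.05,
    "Ca-surfactin": 2.29,
}
MICELLE_VMON_PM6: dict[str, float] = {
    "surfactin": 1.61,
    "Cu-surfactin": 1.35,
    "Zn-surfactin": 1.46,
    "Mg-surfactin": 1.54,
    "Ca-surfactin": 1.46,
}
REPORTED_VMIC_PM6: dict[str, float] = {
    "surfactin": 57.9,
    "Cu-surfactin": 24.43,
    "Zn-surfactin": 33.51,
    "Mg-surfactin": 36.09,
    "Ca-surfactin": 50.3,
}
REPORTED_NAGG_PM6: dict[str, int] = {
    "surfactin": 36,
    "Cu-surfactin": 18,
    "Zn-surfactin": 23,
    "Mg-surfactin": 23,
    "Ca-surfactin": 34,
}

#: Tensiometric anchors (mM / mN/m): CMC per system at 0.1 mM counterion,
#: surface tension of the bare buffer, and gamma at the CMC for surfactin
#: and the two most surface-active complexes.
CMC_MM: dict[str, float] = {
    "surfactin": 0.045,
    "Cu-surfactin": 0.033,
    "Zn-surfactin": 0.038,
    "Mg-surfactin": 0.036,
    "Ca-surfactin": 0.017,
}
GAMMA_BUFFER = 69.4
GAMMA_CMC: dict[str, float] = {
    "surfactin": 28.4,
    "Cu-surfactin": 24.5,
    "Ca-surfactin": 25.1,
}
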