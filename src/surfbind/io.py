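"""Table readers, configuration, and the end-to-end study pipeline.

Input tables are delimited text (comma by default).  Schemas:

* titrations: ``quencher_M``, ``F_obs`` (+ optional ``A_ex``, ``A_em``,
  replicate columns ``F_obs_2``, ``F_obs_3``, ..., and ``label`` /
  ``temperature_C`` columns); per-file metadata may instead come from a
  YAML sidecar (same path with a ``.yaml`` suffix) or keyword overrides;
* multi-temperature constants: ``label``, ``temperature_C``, ``K_per_M``;
* tensiometry: ``conc_mM``, ``gamma_mN_m`` (+ optional replicates and
  ``label``);
* micelle geometry: ``label``, ``R_H_nm``, optional ``V_mon_nm3``,
  optional ``source`` (DLS or PM6).

Concentrations cross the file boundary in molar for titrations and in
millimolar for tensiometry, matching how each experiment is reported;
temperatures cross in Celsius and are converted with the configurable
kelvin offset (default 273, the study's own rounding).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, InsufficientDataError, SchemaError
from .micelle import CmcResult, MicelleGeometry, TensiometryCurve, fit_cmc_breakpoint, micelle_geometry
from .quenching import (
    BindingFit,
    DEFAULT_TAU0,
    DIFFUSION_LIMIT_KQ,
    QuenchingFit,
    TitrationSeries,
    classify_mechanism_with_note,
    correct_series,
    fit_binding_isotherm,
    fit_stern_volmer,
)
from .thermo import TemperatureSeries, ThermoResult, fit_vant_hoff

log = logging.getLogger("surfbind")

_DEFAULT_PRECISION = {
    "ksv": 4,
    "kq": 4,
    "kb": 4,
    "n_sites": 2,
    "delta_h": 2,
    "delta_s": 2,
    "delta_g": 2,
    "cmc": 3,
    "gamma_cmc": 1,
    "v_mic": 2,
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared by every stage of the pipeline."""

    tau0: float = DEFAULT_TAU0  # s
    gas_constant: float = 8.314  # J/(mol K)
    kelvin_offset: float = 273.0
    quench_threshold: float = DIFFUSION_LIMIT_KQ  # 1/(M s)
    fix_intercept: bool = False
    bootstrap_n: int = 0
    seed: int = 0
    delimiter: str = ","
    output_precision: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_PRECISION)
    )

    def __post_init__(self):
        for name in ("tau0", "gas_constant", "kelvin_offset", "quench_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.bootstrap_n < 0:
            raise ConfigError("bootstrap_n must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a YAML key-value config file, with keyword overrides."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def to_kelvin(self, celsius: float) -> float:
        return celsius + self.kelvin_offset


def _read_table(path: str | Path, delimiter: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#", skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: unreadable table ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        coerced = pd.to_numeric(out[c], errors="coerce")
        bad = out.index[coerced.isna() & out[c].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column '{c}' at line {bad[0] + 2}"
            )
        if coerced.isna().any():
            raise SchemaError(
                f"{path}: empty cell in column '{c}' at line "
                f"{out.index[coerced.isna()][0] + 2}"
            )
        out[c] = coerced
    return out


def _sidecar(path: Path) -> dict:
    side = path.with_suffix(".yaml")
    if side.exists():
        meta = yaml.safe_load(side.read_text()) or {}
        if not isinstance(meta, dict):
            raise SchemaError(f"{side}: sidecar must be a key-value mapping")
        return meta
    return {}


def read_titration_table(
    path: str | Path,
    config: Optional[AnalysisConfig] = None,
    *,
    label: Optional[str] = None,
    temperature_c: Optional[float] = None,
    tau0: Optional[float] = None,
) -> list[TitrationSeries]:
    """Read one titration file into validated series.

    Replicate intensity columns (``F_obs``, ``F_obs_2``, ...) are averaged
    point-wise and the per-point replicate SD is retained.  Rows are split
    into separate series by ``label`` / ``temperature_C`` columns when
    present; otherwise metadata comes from the sidecar or the keyword
    arguments.
    """
    config = config or AnalysisConfig()
    path = Path(path)
    df = _read_table(path, config.delimiter, ["quencher_M", "F_obs"])
    meta = _sidecar(path)
    label = label or meta.get("label") or path.stem
    if temperature_c is None:
        temperature_c = meta.get("temperature_C", 25.0)
    tau0 = tau0 or meta.get("tau0", config.tau0)

    rep_cols = ["F_obs"] + sorted(
        (c for c in df.columns if c.startswith("F_obs_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    num_cols = ["quencher_M"] + rep_cols + [
        c for c in ("A_ex", "A_em", "temperature_C") if c in df.columns
    ]
    df = _numeric(df, num_cols, path)

    groups: list[tuple[str, float, pd.DataFrame]]
    keys = [c for c in ("label", "temperature_C") if c in df.columns]
    if keys:
        groups = []
        for key, sub in df.groupby(keys, sort=False):
            key = key if isinstance(key, tuple) else (key,)
            info = dict(zip(keys, key))
            groups.append(
                (str(info.get("label", label)), float(info.get("temperature_C", temperature_c)), sub)
            )
    else:
        groups = [(label, float(temperature_c), df)]

    series = []
    for lab, t_c, sub in groups:
        sub = sub.sort_values("quencher_M")
        if not (sub["quencher_M"] == 0).any():
            raise SchemaError(f"{path} [{lab}]: no quencher_M = 0 row (F0 undefined)")
        reps = sub[rep_cols].to_numpy(dtype=float)
        f_mean = reps.mean(axis=1)
        f_sd = reps.std(axis=1, ddof=1) if reps.shape[1] > 1 else None
        series.append(
            TitrationSeries(
                label=lab,
                temperature=config.to_kelvin(t_c),
                quencher_conc=tuple(sub["quencher_M"]),
                intensity_obs=tuple(f_mean),
                abs_ex=tuple(sub["A_ex"]) if "A_ex" in sub.columns else None,
                abs_em=tuple(sub["A_em"]) if "A_em" in sub.columns else None,
                tau0=float(tau0),
                intensity_sd=tuple(f_sd) if f_sd is not None else None,
            )
        )
    return series


def read_temperature_table(
    path: str | Path, config: Optional[AnalysisConfig] = None
) -> list[TemperatureSeries]:
    """Read a ``label, temperature_C, K_per_M`` table, one series per label."""
    config = config or AnalysisConfig()
    df = _read_table(path, config.delimiter, ["label", "temperature_C", "K_per_M"])
    df = _numeric(df, ["temperature_C", "K_per_M"], path)
    out = []
    for lab, sub in df.groupby("label", sort=False):
        sub = sub.sort_values("temperature_C")
        out.append(
            TemperatureSeries(
                label=str(lab),
                temperatures=tuple(config.to_kelvin(t) for t in sub["temperature_C"]),
                k_values=tuple(sub["K_per_M"]),
            )
        )
    return out


def read_tensiometry_table(
    path: str | Path, config: Optional[AnalysisConfig] = None
) -> list[TensiometryCurve]:
    """Read ``conc_mM, gamma_mN_m`` curves; replicate columns are averaged."""
    config = config or AnalysisConfig()
    path = Path(path)
    df = _read_table(path, config.delimiter, ["conc_mM", "gamma_mN_m"])
    rep_cols = ["gamma_mN_m"] + sorted(
        (c for c in df.columns if c.startswith("gamma_mN_m_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    df = _numeric(df, ["conc_mM"] + rep_cols, path)
    meta = _sidecar(path)
    groups = (
        [(str(lab), sub) for lab, sub in df.groupby("label", sort=False)]
        if "label" in df.columns
        else [(meta.get("label", path.stem), df)]
    )
    curves = []
    for lab, sub in groups:
        sub = sub.sort_values("conc_mM")
        curves.append(
            TensiometryCurve(
                label=lab,
                conc=tuple(sub["conc_mM"]),
                gamma=tuple(sub[rep_cols].mean(axis=1)),
                counterion=meta.get("counterion"),
                counterion_conc=meta.get("counterion_conc_mM"),
            )
        )
    return curves


def read_geometry_table(
    path: str | Path, config: Optional[AnalysisConfig] = None
) -> list[MicelleGeometry]:
    """Read ``label, R_H_nm[, V_mon_nm3][, source]`` micelle-geometry rows."""
    config = config or AnalysisConfig()
    df = _read_table(path, config.delimiter, ["label", "R_H_nm"])
    num = ["R_H_nm"] + (["V_mon_nm3"] if "V_mon_nm3" in df.columns else [])
    df = _numeric(df, num, path)
    out = []
    for _, row in df.iterrows():
        v_mon = row["V_mon_nm3"] if "V_mon_nm3" in df.columns and pd.notna(row["V_mon_nm3"]) else None
        out.append(
            micelle_geometry(
                label=str(row["label"]),
                r_h=float(row["R_H_nm"]),
                v_mon=None if v_mon is None else float(v_mon),
                source=str(row.get("source", "DLS")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Study report and full pipeline


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class StudyReport:
    """Everything the pipeline computed, plus provenance."""

    quenching: dict[str, dict[str, Any]] = field(default_factory=dict)
    binding: dict[str, dict[str, Any]] = field(default_factory=dict)
    thermodynamics: dict[str, ThermoResult] = field(default_factory=dict)
    cmc: dict[str, CmcResult] = field(default_factory=dict)
    geometry: dict[str, MicelleGeometry] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _as_jsonable(dataclasses.asdict(self))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def write_report(report: StudyReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json() + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(
    paths: dict[str, Any], config: Optional[AnalysisConfig] = None
) -> StudyReport:
    """Run every applicable stage over the supplied input files.

    ``paths`` maps stage names to files: ``titrations`` (list),
    ``thermo`` (one file), ``tensiometry`` (list), ``geometry`` (one
    file).  Missing stages are skipped with a logged notice; an empty
    input set is a configuration error.  The pipeline is deterministic
    given fixed inputs and config (timestamps aside).
    """
    config = config or AnalysisConfig()
    titr_paths = [Path(p) for p in paths.get("titrations", [])]
    tensio_paths = [Path(p) for p in paths.get("tensiometry", [])]
    thermo_path = paths.get("thermo")
    geom_path = paths.get("geometry")
    all_inputs = titr_paths + tensio_paths
    all_inputs += [Path(p) for p in (thermo_path, geom_path) if p]
    if not all_inputs:
        raise ConfigError("no input tables supplied")

    report = StudyReport()

    def notice(msg: str) -> None:
        log.info(msg)
        report.notices.append(msg)

    # --- fluorescence titrations: correction -> Stern-Volmer -> binding
    all_series: list[TitrationSeries] = []
    for p in titr_paths:
        all_series.extend(read_titration_table(p, config))
    sv_fits: dict[tuple[str, float], QuenchingFit] = {}
    for s in all_series:
        if s.has_absorbances():
            s = correct_series(s)
        else:
            notice(f"{s.label} @ {s.temperature:g} K: no absorbance columns; "
                   "inner-filter correction skipped")
        fit = fit_stern_volmer(s, fix_intercept=config.fix_intercept)
        sv_fits[(s.label, s.temperature)] = fit
        try:
            bind = fit_binding_isotherm(s)
            report.binding[f"{s.label}@{s.temperature:g}K"] = _as_jsonable(bind)
        except InsufficientDataError as exc:
            notice(f"binding isotherm skipped: {exc}")

    # refine mechanism calls with the cross-temperature K_SV trend
    labels = {lab for lab, _ in sv_fits}
    for lab in sorted(labels):
        temps = sorted(t for l, t in sv_fits if l == lab)
        ksv_by_t = {t: sv_fits[(lab, t)].ksv for t in temps}
        for t in temps:
            fit = sv_fits[(lab, t)]
            mech, mnote = classify_mechanism_with_note(
                fit.kq, ksv_by_t if len(ksv_by_t) >= 2 else None,
                threshold=config.quench_threshold,
            )
            fit = dataclasses.replace(fit, mechanism=mech, note=mnote)
            report.quenching[f"{lab}@{t:g}K"] = _as_jsonable(fit)
        if len(ksv_by_t) >= 2:
            series = TemperatureSeries(
                label=lab,
                temperatures=tuple(temps),
                k_values=tuple(ksv_by_t[t] for t in temps),
            )
            report.thermodynamics[lab] = fit_vant_hoff(series)

    # --- explicit multi-temperature K tables
    if thermo_path:
        for series in read_temperature_table(thermo_path, config):
            report.thermodynamics[series.label] = fit_vant_hoff(series)
    elif not titr_paths:
        notice("no equilibrium-constant table; Van't Hoff stage skipped")

    # --- micellization
    for p in tensio_paths:
        for curve in read_tensiometry_table(p, config):
            report.cmc[curve.label] = fit_cmc_breakpoint(
                curve, n_boot=config.bootstrap_n, seed=config.seed
            )
    if not tensio_paths:
        notice("no tensiometry tables; CMC stage skipped")
    if geom_path:
        for geom in read_geometry_table(geom_path, config):
            report.geometry[geom.label] = geom
    else:
        notice("no geometry table; micelle-geometry stage skipped")

    report.provenance = {
        "tool": "surfbind",
        "version": __version__,
        "config": _as_jsonable(dataclasses.asdict(config)),
        "inputs": {str(p): _digest(p) for p in all_inputs},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return report
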