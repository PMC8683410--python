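"""File I/O, run configuration, fixture generation and stage orchestration.

All input files are plain CSV with named headers (no binary instrument
formats).  ``run_pipeline`` wires the stages in dependency order -- the DLS
critical concentration and the ITC molar enthalpy feed the thermodynamic
chain; the build-up curve feeds the diameter; each isotherm feeds a Hill
fit -- and emits a consolidated :class:`Report` whose JSON body is
deterministic for a fixed configuration and seed, with every numeric leaf
carrying its units.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import binding, dls, kinetics, nmr, synthgen, thermo
from .errors import SchemaError

logger = logging.getLogger("fibrilkit")

# column name -> units string, per input class
SCHEMAS: dict[str, dict[str, str]] = {
    "correlogram": {"lag_s": "s", "g2m1": ""},
    "detection": {"conc_M": "M", "detected": ""},
    "thermogram": {"time_s": "s", "heatflow_ucal_per_s": "ucal/s"},
    "dh_table": {"T_K": "K", "dH_kJ_mol": "kJ/mol"},
    "buildup": {"mixing_ms": "ms", "intensity": ""},
    "isotherm": {"conc_M": "M", "response_RU": "RU"},
    "tht": {"time_h": "h", "fluorescence_AU": "AU"},
    "cd": {"wavelength_nm": "nm", "ellipticity_mdeg": "mdeg"},
    "shifts": {"residue": "", "atom": "", "ppm": "ppm"},
}

_NUMERIC_COLUMNS_EXEMPT = {"residue", "atom"}


def read_table(path: str | Path, schema: str | dict[str, str]) -> pd.DataFrame:
    """Read and validate a CSV input against a named (or explicit) schema.

    The header must contain every schema column; numeric columns are parsed
    strictly, and rows with non-numeric cells (including locale decimal
    commas) are rejected with their line numbers.
    """
    path = Path(path)
    if isinstance(schema, str):
        if schema not in SCHEMAS:
            raise SchemaError(f"unknown schema {schema!r}")
        schema = SCHEMAS[schema]
    if not path.exists():
        raise SchemaError(f"input file {path} does not exist")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty and df.columns.size == 0:
        raise SchemaError(f"{path} is empty")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing column(s): {', '.join(missing)}")
    bad_lines: list[tuple[int, str, str]] = []
    for col in schema:
        if col in _NUMERIC_COLUMNS_EXEMPT:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        for i in np.flatnonzero(parsed.isna().to_numpy()):
            cell = df[col].iloc[i]
            hint = " (decimal comma?)" if isinstance(cell, str) and "," in cell else ""
            bad_lines.append((i + 2, col, f"{cell!r}{hint}"))  # +2: header + 1-based
        df[col] = parsed
    if bad_lines:
        detail = "; ".join(f"line {ln}, column {c}: {v}" for ln, c, v in bad_lines[:10])
        raise SchemaError(f"{path} has non-numeric cells: {detail}")
    if df.empty:
        raise SchemaError(f"{path} contains no data rows")
    return df[list(schema)]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

ALL_STAGES = ("dls", "itc", "thermo", "hydration", "binding", "kinetics")


@dataclass
class RunConfig:
    """Pipeline run configuration: stage selection, inputs, parameter
    overrides, output directory and seed."""

    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    inputs: dict[str, Any] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise SchemaError(f"unknown stage(s): {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: raw[k] for k in ("stages", "inputs", "params", "outdir", "seed")
                     if k in raw})
        base = Path(path).parent
        missing = []
        for key, value in cfg.inputs.items():
            paths = value if isinstance(value, list) else [value]
            resolved = []
            for p in paths:
                rp = (base / p) if not Path(p).is_absolute() else Path(p)
                if not rp.exists():
                    missing.append(str(rp))
                resolved.append(str(rp))
            cfg.inputs[key] = resolved if isinstance(value, list) else resolved[0]
        if missing:
            raise SchemaError(f"missing input file(s): {', '.join(missing)}")
        return cfg

    def canonical_hash(self) -> str:
        body = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(body.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

def _q(value: float | None, units: str) -> dict[str, Any] | None:
    """A units-tagged numeric leaf for the report JSON."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return {"value": None, "units": units}
    return {"value": float(value), "units": units}


@dataclass
class Report:
    """Consolidated pipeline report (thermodynamic summary, sizes, hydration,
    binding fits, kinetics fits, provenance)."""

    thermo: thermo.ThermoParams | None = None
    dls_sizes: list[dls.SizeDistribution] = field(default_factory=list)
    critical_conc: dls.CriticalConcentration | None = None
    hydration: nmr.HydrationResult | None = None
    binding_fits: dict[str, binding.HillFit] = field(default_factory=dict)
    kinetics_fits: list[kinetics.ThTFit] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"provenance": self.provenance,
                             "failures": dict(sorted(self.failures.items()))}
        tp = self.thermo
        d["thermo"] = None if tp is None else {
            "T": _q(tp.T, "K"),
            "critical_conc": _q(tp.critical_conc, "M"),
            "K_F": _q(tp.K_F, "1/M"),
            "dG_app": _q(tp.dG_app, "kJ/mol"),
            "dH": _q(tp.dH, "kJ/mol"),
            "dS": _q(tp.dS, "kJ/mol/K"),
            "dCp_low": _q(tp.dCp_low, "kJ/mol/K"),
            "dCp_high": _q(tp.dCp_high, "kJ/mol/K"),
        }
        d["dls"] = [
            {"species": [{"radius": _q(s.radius, "nm"),
                          "fraction": _q(s.fraction, ""),
                          "mass": _q(s.mass, "kDa") if s.mass is not None else None}
                         for s in dist.species],
             "residual": _q(dist.residual, "")}
            for dist in self.dls_sizes
        ]
        d["critical_conc"] = None if self.critical_conc is None else {
            "value": _q(self.critical_conc.value, "M"),
            "bound": self.critical_conc.bound,
        }
        h = self.hydration
        d["hydration"] = None if h is None else {
            "t_m_s": _q(h.t_m_s, "ms"), "D_eff": _q(h.d_eff, "nm^2/ms"),
            "v_over_s": _q(h.v_over_s, "nm"), "diameter": _q(h.diameter, "nm"),
            "shape": h.shape,
        }
        d["binding"] = {
            label: {"K_D": _q(fit.K_D, "M"), "n": _q(fit.n, ""),
                    "R_max": _q(fit.R_max, "RU"), "verdict": fit.verdict}
            for label, fit in sorted(self.binding_fits.items())
        }
        d["kinetics"] = [
            {"F0": _q(f.F0, "AU"), "A": _q(f.A, "AU"), "k": _q(f.k, "1/h"),
             "t50": _q(f.t50, "h"), "lag": _q(f.lag, "h"),
             "plateau_time": _q(f.plateau_time, "h"),
             "no_transition": f.no_transition}
            for f in self.kinetics_fits
        ]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def summary_markdown(self) -> str:
        """Human-readable summary mirroring the thermodynamic/binding tables."""
        lines = ["# fibrilkit report", ""]
        tp = self.thermo
        if tp is not None:
            lines += ["## Thermodynamics of fibrillization",
                      "| quantity | value | units |", "|---|---|---|"]
            rows = [("[C]", tp.critical_conc, "M"), ("K_F", tp.K_F, "1/M"),
                    ("dG_app", tp.dG_app, "kJ/mol"), ("dH", tp.dH, "kJ/mol"),
                    ("dS", tp.dS, "kJ/mol/K"), ("dCp (low T)", tp.dCp_low, "kJ/mol/K"),
                    ("dCp (high T)", tp.dCp_high, "kJ/mol/K"), ("T", tp.T, "K")]
            for name, val, unit in rows:
                if val is not None:
                    lines.append(f"| {name} | {val:.6g} | {unit} |")
            lines.append("")
        if self.hydration is not None:
            h = self.hydration
            lines += ["## Hydration / fibril diameter",
                      f"t_m^s = {h.t_m_s:.3g} ms, V/S = {h.v_over_s:.3g} nm, "
                      f"core diameter = {h.diameter:.3g} nm ({h.shape})", ""]
        if self.binding_fits:
            lines += ["## Binding constants", "| pair | K_D | n | verdict |",
                      "|---|---|---|---|"]
            for label, fit in sorted(self.binding_fits.items()):
                kd = fit.K_D
                kd_str = f"{kd * 1e9:.3g} nM" if kd < 1e-6 else f"{kd * 1e6:.3g} uM"
                lines.append(f"| {label} | {kd_str} | {fit.n:.2g} | {fit.verdict} |")
            lines.append("")
        if self.failures:
            lines += ["## Failures"] + [f"- {k}: {v}" for k, v in self.failures.items()]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Fixture generation
# --------------------------------------------------------------------------

def make_fixtures(outdir: str | Path, seed: int = 0,
                  noise: bool = False) -> dict[str, str]:
    """Write one synthetic CSV per input class plus a ground-truth sidecar.

    Ground-truth parameters are the package's embedded reference values
    (critical concentration 750 nM, molar enthalpy -297.74 kJ/mol, heat
    capacities 113.84 / -373.51 kJ/mol/K, build-up time 45 ms, and the nine
    reference (K_D, n) binding pairs).  ``noise=False`` writes the noiseless
    forward-model columns; the sidecar JSON records every parameter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sd = {"corr": 0.002, "tg": 0.05, "bu": 0.01, "iso": 2.0, "tht": 2.0,
          "dh": 1.0, "cd": 0.1} if noise else dict.fromkeys(
              ("corr", "tg", "bu", "iso", "tht", "dh", "cd"), 0.0)
    truth: dict[str, Any] = {"seed": seed, "noise": noise}
    files: dict[str, str] = {}

    instrument = dls.InstrumentConfig(temperature=310.15)
    species = [(4.1, 0.5), (17.2, 0.5)]
    trace = synthgen.gen_correlogram(
        synthgen.SimSpec("correlogram", {"species": species},
                         np.geomspace(1e-7, 1.0, 160), sd["corr"], seed),
        instrument)
    pd.DataFrame({"lag_s": trace.lags, "g2m1": trace.g2m1}).to_csv(
        outdir / "correlogram.csv", index=False)
    files["correlogram"] = str(outdir / "correlogram.csv")
    truth["correlogram"] = {"species_nm": species,
                            "temperature_K": instrument.temperature,
                            "beta": instrument.beta}

    concs = [2.5e-7, 5.0e-7, 7.5e-7, 1.0e-6, 2.5e-6, 5.0e-6, 1.0e-5]
    detected = [0, 0, 1, 1, 1, 1, 1]
    pd.DataFrame({"conc_M": concs, "detected": detected}).to_csv(
        outdir / "detection_series.csv", index=False)
    files["detection"] = str(outdir / "detection_series.csv")
    truth["detection"] = {"critical_conc_M": 7.5e-7}

    # thermogram: four pulses totalling -59.548 mJ for 0.2 umol of protein
    total_ucal = -59.548e-3 / thermo.JOULE_PER_CALORIE * 1e6
    amp = total_ucal / 4 / 120.0
    pulses = [(200.0 + i * 300.0, 120.0, amp) for i in range(4)]
    syn = synthgen.gen_thermogram(
        synthgen.SimSpec("thermogram",
                         {"baseline": 0.5, "pulses": pulses, "n_mol": 2e-7},
                         np.arange(0.0, 1500.0, 0.1), sd["tg"], seed))
    pd.DataFrame({"time_s": syn.thermogram.times,
                  "heatflow_ucal_per_s": syn.thermogram.heat_flow}).to_csv(
        outdir / "thermogram.csv", index=False, float_format="%.6g")
    files["thermogram"] = str(outdir / "thermogram.csv")
    truth["thermogram"] = {
        "total_heat_J": syn.total_heat_J, "n_mol": 2e-7,
        "injections": syn.thermogram.injections,
        "dH_kJ_mol": thermo.enthalpy_from_heats(syn.total_heat_J, 2e-7)}

    dh_spec = synthgen.SimSpec(
        "dH_table",
        {"breakpoint": 310.15, "slope_low": 113.84, "slope_high": -373.51,
         "intercept": -297.74},
        np.array([293.15, 298.15, 303.15, 308.15, 313.15, 318.15, 323.15, 333.15]),
        sd["dh"], seed)
    synthgen.gen_dH_table(dh_spec).to_csv(outdir / "dh_table.csv", index=False)
    files["dh_table"] = str(outdir / "dh_table.csv")
    truth["dh_table"] = {"breakpoint_K": 310.15, "slope_low": 113.84,
                         "slope_high": -373.51}

    bu = synthgen.gen_buildup(
        synthgen.SimSpec("buildup", {"t_m_s": 45.0, "model": "linear_capped"},
                         np.array([2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0,
                                   75.0, 100.0, 200.0, 350.0, 500.0]),
                         sd["bu"], seed))
    pd.DataFrame({"mixing_ms": bu.mixing_times, "intensity": bu.intensities}).to_csv(
        outdir / "buildup.csv", index=False)
    files["buildup"] = str(outdir / "buildup.csv")
    truth["buildup"] = {"t_m_s_ms": 45.0, "model": "linear_capped"}

    iso_files = {}
    iso_truth = {}
    for (ligand, prep), (kd, n) in binding.REFERENCE_BINDING_PARAMS.items():
        grid = np.geomspace(0.1 * kd, 10.0 * kd, 12)
        iso = synthgen.gen_isotherm(
            synthgen.SimSpec("isotherm", {"k_d": kd, "n": n, "r_max": 100.0,
                                          "ligand": ligand, "analyte": prep},
                             grid, sd["iso"], seed))
        name = f"isotherm_{ligand}_{prep}.csv"
        pd.DataFrame({"conc_M": iso.concentrations,
                      "response_RU": iso.responses}).to_csv(
            outdir / name, index=False)
        iso_files[f"{ligand}/{prep}"] = str(outdir / name)
        iso_truth[f"{ligand}/{prep}"] = {"K_D_M": kd, "n": n, "R_max_RU": 100.0}
    files["isotherms"] = iso_files
    truth["isotherms"] = iso_truth

    tht = synthgen.gen_tht(
        synthgen.SimSpec("tht", {"f0": 50.0, "a": 400.0, "k": 1.5, "t50": 4.0},
                         np.linspace(0.0, 12.0, 97), sd["tht"], seed))
    pd.DataFrame({"time_h": tht.times, "fluorescence_AU": tht.fluorescence}).to_csv(
        outdir / "tht.csv", index=False)
    files["tht"] = str(outdir / "tht.csv")
    truth["tht"] = {"f0": 50.0, "a": 400.0, "k_per_h": 1.5, "t50_h": 4.0}

    cd = synthgen.gen_cd_spectrum(
        synthgen.SimSpec("cd_spectrum", {}, np.arange(190.0, 260.5, 0.5),
                         sd["cd"], seed))
    pd.DataFrame({"wavelength_nm": cd.wavelengths,
                  "ellipticity_mdeg": cd.ellipticity}).to_csv(
        outdir / "cd_spectrum.csv", index=False)
    files["cd"] = str(outdir / "cd_spectrum.csv")

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    files["ground_truth"] = str(outdir / "ground_truth.json")
    return files


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def _package_version() -> str:
    try:
        return metadata.version("fibrilkit")
    except metadata.PackageNotFoundError:
        return "unknown"


def run_pipeline(config: RunConfig) -> Report:
    """Execute the selected stages in dependency order and collect a Report.

    A failing stage is recorded in ``report.failures`` and its dependents
    (the thermodynamic chain depends on both the DLS and ITC stages) are
    skipped; everything else still runs.
    """
    report = Report()
    report.provenance = {
        "config_hash": config.canonical_hash(),
        "package_version": _package_version(),
        "seed": config.seed,
        "stages": list(config.stages),
    }
    p = config.params
    temperature = float(p.get("temperature_K", 293.15))

    critical = None
    if "dls" in config.stages:
        try:
            if "correlogram" in config.inputs:
                df = read_table(config.inputs["correlogram"], "correlogram")
                cfg = dls.InstrumentConfig(
                    temperature=float(p.get("dls_temperature_K", 310.15)),
                    beta=float(p.get("beta", 0.9)))
                trace = dls.CorrelogramTrace(df["lag_s"].to_numpy(),
                                             df["g2m1"].to_numpy(), cfg)
                dist = dls.fit_correlogram(trace,
                                           n_components=int(p.get("n_components", 2)))
                if p.get("mass_pairs"):
                    cal = dls.calibrate_mass([tuple(x) for x in p["mass_pairs"]])
                    dist = dls.annotate_masses(dist, cal)
                report.dls_sizes.append(dist)
            if "detection" in config.inputs:
                df = read_table(config.inputs["detection"], "detection")
                critical = dls.estimate_critical_concentration(
                    list(zip(df["conc_M"], df["detected"] > 0)))
                report.critical_conc = critical
            logger.info("dls stage complete")
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            report.failures["dls"] = str(exc)
            logger.error("dls stage failed: %s", exc)

    dh_molar = None
    if "itc" in config.stages:
        try:
            if "thermogram" in config.inputs:
                df = read_table(config.inputs["thermogram"], "thermogram")
                injections = [tuple(x) for x in p.get("injections", [])]
                tg = thermo.Thermogram(
                    df["time_s"].to_numpy(), df["heatflow_ucal_per_s"].to_numpy(),
                    injections=injections,
                    baseline_model=p.get("baseline_model", "constant"))
                heats = thermo.integrate_thermogram(tg)
                n_total = sum(n for _, n in injections)
                dh_molar = thermo.enthalpy_from_heats(sum(heats), n_total)
            logger.info("itc stage complete: dH = %s kJ/mol", dh_molar)
        except Exception as exc:  # noqa: BLE001
            report.failures["itc"] = str(exc)
            logger.error("itc stage failed: %s", exc)

    if "thermo" in config.stages:
        try:
            dcp = None
            if "dh_table" in config.inputs:
                df = read_table(config.inputs["dh_table"], "dh_table")
                fit = thermo.heat_capacity_fit(
                    list(zip(df["T_K"], df["dH_kJ_mol"])),
                    breakpoint=p.get("breakpoint_K", 310.15))
                dcp = (fit.dcp_low, fit.dcp_high)
            if critical is None or dh_molar is None:
                raise RuntimeError(
                    "thermo chain needs the DLS critical concentration and "
                    "the ITC molar enthalpy")
            report.thermo = thermo.ThermoParams.from_measurements(
                critical_conc=critical.value, dH=dh_molar,
                temperature=temperature, dCp=dcp)
            logger.info("thermo stage complete")
        except Exception as exc:  # noqa: BLE001
            report.failures["thermo"] = str(exc)
            logger.error("thermo stage failed: %s", exc)

    if "hydration" in config.stages:
        try:
            if "buildup" in config.inputs:
                df = read_table(config.inputs["buildup"], "buildup")
                curve = nmr.BuildUpCurve(df["mixing_ms"].to_numpy(),
                                         df["intensity"].to_numpy())
                if curve.intensities.max() > 1.0 + 1e-9:
                    curve = nmr.normalize_buildup(
                        curve, reference_time=float(p.get("reference_ms", 100.0)))
                else:
                    curve.normalized = True
                report.hydration = nmr.analyze_buildup(
                    curve, d_eff=float(p.get("D_eff", 0.2)),
                    window=float(p.get("slope_window", 0.5)))
            logger.info("hydration stage complete")
        except Exception as exc:  # noqa: BLE001
            report.failures["hydration"] = str(exc)
            logger.error("hydration stage failed: %s", exc)

    if "binding" in config.stages:
        for label, path in sorted(dict(config.inputs.get("isotherms", {})).items()):
            try:
                df = read_table(path, "isotherm")
                iso = binding.BindingIsotherm(df["conc_M"].to_numpy(),
                                              df["response_RU"].to_numpy(),
                                              ligand_label=label)
                report.binding_fits[label] = binding.compare_cooperativity(
                    iso, alpha=float(p.get("alpha", 0.05)))
            except Exception as exc:  # noqa: BLE001
                report.failures[f"binding:{label}"] = str(exc)
                logger.error("binding fit %s failed: %s", label, exc)
        logger.info("binding stage complete (%d fits)", len(report.binding_fits))

    if "kinetics" in config.stages:
        try:
            if "tht" in config.inputs:
                df = read_table(config.inputs["tht"], "tht")
                trace = kinetics.ThTTrace(df["time_h"].to_numpy(),
                                          df["fluorescence_AU"].to_numpy(),
                                          background_corrected=True)
                report.kinetics_fits.append(kinetics.fit_tht_sigmoid(trace))
            logger.info("kinetics stage complete")
        except Exception as exc:  # noqa: BLE001
            report.failures["kinetics"] = str(exc)
            logger.error("kinetics stage failed: %s", exc)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.md").write_text(report.summary_markdown())
    return report
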