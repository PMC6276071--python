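"""Configuration schema, model serialization and result export.

Run configurations are YAML mappings validated field-by-field (unknown
keys are rejected so typos fail loudly); results are written as CSV for
curves and time series and JSON for fits, audits and cycle reports,
with floating-point formatting pinned so identical runs produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import (
    CarrierParams,
    MultisiteParams,
    build_asymmetric_carrier,
    build_branched_multisite,
    build_multisite_chain,
    build_symmetric_carrier,
)
from .network import (
    Compartment,
    CycleReport,
    LigandSpecies,
    CarrierState,
    NetworkModel,
    Transition,
    check_detailed_balance,
)
from .protocols import (
    CounterflowResult,
    FluxCurve,
    SaturationFit,
    KineticSummary,
    fit_michaelis_menten,
    run_counterflow,
    run_equilibrium_exchange,
    run_zero_trans,
)
from .thermo import equilibrium_audit

__all__ = [
    "ConfigError",
    "model_to_dict",
    "model_from_dict",
    "build_from_config",
    "load_config",
    "run_config",
    "flux_curve_frame",
    "write_flux_curve",
    "fit_to_dict",
    "cycle_report_to_dict",
    "write_json",
]

MODEL_BUILDERS = {
    "symmetric": (build_symmetric_carrier, CarrierParams),
    "asymmetric": (build_asymmetric_carrier, CarrierParams),
    "multisite": (build_multisite_chain, MultisiteParams),
    "branched": (build_branched_multisite, MultisiteParams),
}

_PROTOCOL_KEYS = {"type", "grid", "fit", "labelled_fraction",
                  "inside_load", "tracer_outside", "t_max", "inside_capacity"}
_TOP_KEYS = {"model", "protocols", "audit", "seed"}
_MODEL_KEYS = {"type", "params", "block_right_branch"}


class ConfigError(ValueError):
    """A configuration failed schema validation."""


# ---------------------------------------------------------------------------
# model (de)serialization
# ---------------------------------------------------------------------------


def model_to_dict(model: NetworkModel) -> dict:
    return {
        "species": [dataclasses.asdict(s) for s in model.species.values()],
        "compartments": [dataclasses.asdict(c) for c in model.compartments.values()],
        "states": [{**dataclasses.asdict(s), "occupants": list(s.occupants)}
                   for s in model.states.values()],
        "transitions": [dataclasses.asdict(t) for t in model.transitions.values()],
        "groups": dict(model.groups),
    }


def model_from_dict(data: dict) -> NetworkModel:
    m = NetworkModel()
    for s in data["species"]:
        m.species[s["name"]] = LigandSpecies(**s)
    for c in data["compartments"]:
        m.compartments[c["name"]] = Compartment(
            c["name"], c["kind"], c["capacity"], dict(c["conc"]))
    for s in data["states"]:
        m.states[s["id"]] = CarrierState(s["id"], s["location"],
                                         tuple(s["occupants"]), s["group"])
    for t in data["transitions"]:
        m.transitions[t["name"]] = Transition(**t)
    m.groups = {k: float(v) for k, v in data["groups"].items()}
    m.validate()
    return m


def build_from_config(spec: dict) -> NetworkModel:
    unknown = set(spec) - _MODEL_KEYS
    if unknown:
        raise ConfigError(f"unknown model keys: {sorted(unknown)}")
    mtype = spec.get("type")
    if mtype not in MODEL_BUILDERS:
        raise ConfigError(f"model type must be one of {sorted(MODEL_BUILDERS)}, "
                          f"got {mtype!r}")
    builder, params_cls = MODEL_BUILDERS[mtype]
    params = None
    if "params" in spec:
        fields = {f.name for f in dataclasses.fields(params_cls)}
        bad = set(spec["params"]) - fields
        if bad:
            raise ConfigError(f"unknown {params_cls.__name__} fields: {sorted(bad)}")
        kwargs = dict(spec["params"])
        if "site_kds" in kwargs:
            kwargs["site_kds"] = tuple(kwargs["site_kds"])
        params = params_cls(**kwargs)
    if mtype == "branched":
        return builder(bool(spec.get("block_right_branch", False)), params)
    if "block_right_branch" in spec:
        raise ConfigError("block_right_branch applies only to the branched model")
    return builder(params)


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------


def flux_curve_frame(curve: FluxCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "concentration_mmol_per_L": curve.concentrations,
        "flux_per_carrier_per_s": curve.fluxes,
    })


def write_flux_curve(curve: FluxCurve, path) -> Path:
    path = Path(path)
    flux_curve_frame(curve).to_csv(path, index=False, float_format="%.12g")
    return path


def fit_to_dict(fit: SaturationFit) -> dict:
    return {
        "km_mmol_per_L": fit.km,
        "vmax_per_carrier_per_s": fit.vmax,
        "rss": fit.rss,
        "km_stderr": fit.km_stderr,
        "vmax_stderr": fit.vmax_stderr,
        "converged": fit.converged,
        "n_points": fit.n_points,
    }


def summary_to_dict(summary: KineticSummary) -> dict:
    out = {
        "zero_trans_influx": fit_to_dict(summary.influx),
        "zero_trans_efflux": fit_to_dict(summary.efflux),
        "equilibrium_exchange_influx": fit_to_dict(summary.exchange_influx),
        "observables": summary.observables(),
    }
    if summary.exchange_efflux is not None:
        out["equilibrium_exchange_efflux"] = fit_to_dict(summary.exchange_efflux)
    return out


def cycle_report_to_dict(report: CycleReport) -> dict:
    return {
        "tolerance": report.tolerance,
        "passed": report.passed,
        "cycles": [
            {"transitions": c.transitions,
             "forward_product": c.forward_product,
             "reverse_product": c.reverse_product,
             "ratio": c.ratio}
            for c in report.cycles
        ],
    }


def _round_floats(obj, digits=12):
    if isinstance(obj, float):
        return float(f"{obj:.{digits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(data: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_round_floats(data), indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# config-driven runs
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "model" not in cfg:
        raise ConfigError("config requires a 'model' section")
    for proto in cfg.get("protocols", []):
        bad = set(proto) - _PROTOCOL_KEYS
        if bad:
            raise ConfigError(f"unknown protocol keys: {sorted(bad)}")
        if "type" not in proto:
            raise ConfigError("each protocol needs a 'type'")
    return cfg


def _grid_from(spec) -> np.ndarray | None:
    if spec is None:
        return None
    if isinstance(spec, dict):
        bad = set(spec) - {"start", "stop", "num"}
        if bad:
            raise ConfigError(f"unknown grid keys: {sorted(bad)}")
        return np.geomspace(spec.get("start", 0.03), spec.get("stop", 300.0),
                            int(spec.get("num", 24)))
    return np.asarray(spec, dtype=float)


def run_config(path, out_dir) -> list[Path]:
    """Execute a config: build the model, run each requested protocol
    (with optional Michaelis-Menten fits), run the audit, and write CSV
    and JSON artifacts plus a provenance record (config hash, package
    version, seed) into ``out_dir``."""
    cfg = load_config(path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = build_from_config(cfg["model"])
    artifacts: list[Path] = []
    fits: dict[str, dict] = {}
    for proto in cfg.get("protocols", []):
        ptype = proto["type"]
        grid = _grid_from(proto.get("grid"))
        if ptype == "counterflow":
            res = run_counterflow(
                model,
                inside_load=float(proto.get("inside_load", 100.0)),
                tracer_outside=float(proto.get("tracer_outside", 1.0)),
                t_grid=np.linspace(0.0, float(proto.get("t_max", 200.0)), 400),
                inside_capacity=float(proto.get("inside_capacity", 1.0)))
            frame = pd.DataFrame({"time_s": res.t,
                                  "label_ratio_in_over_out": res.label_ratio})
            p = out / "counterflow.csv"
            frame.to_csv(p, index=False, float_format="%.12g")
            artifacts.append(p)
            continue
        if ptype.startswith("zero_trans"):
            curve = run_zero_trans(model, ptype.rsplit("_", 1)[-1], grid)
        elif ptype.startswith("equilibrium_exchange"):
            curve = run_equilibrium_exchange(
                model, ptype.rsplit("_", 1)[-1], grid,
                float(proto.get("labelled_fraction", 1e-6)))
        else:
            raise ConfigError(f"unknown protocol type {ptype!r}")
        artifacts.append(write_flux_curve(curve, out / f"{ptype}.csv"))
        if proto.get("fit", True):
            fits[ptype] = fit_to_dict(fit_michaelis_menten(curve))
    if fits:
        artifacts.append(write_json(fits, out / "fits.json"))
    if "audit" in cfg:
        audit_cfg = cfg["audit"] or {}
        bad = set(audit_cfg) - {"bath_conc", "tolerance"}
        if bad:
            raise ConfigError(f"unknown audit keys: {sorted(bad)}")
        audit = equilibrium_audit(model, float(audit_cfg.get("bath_conc", 10.0)),
                                  float(audit_cfg.get("tolerance", 1e-8)))
        report = check_detailed_balance(model)
        artifacts.append(write_json({
            "detailed_balance": cycle_report_to_dict(report),
            "equilibrium": {
                "bath_conc": audit.bath_conc,
                "pool_concentrations": audit.pool_conc,
                "max_conc_deviation": audit.max_conc_deviation,
                "max_flux_imbalance": audit.max_flux_imbalance,
                "uniform": audit.uniform,
            },
        }, out / "audit.json"))
    config_text = Path(path).read_text()
    artifacts.append(write_json({
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "portersim_version": __version__,
        "seed": int(cfg.get("seed", 0)),
    }, out / "run.json"))
    return artifacts
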