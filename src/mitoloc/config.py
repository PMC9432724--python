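"""Structured configuration, experiment runner and result serialization.

Configs are YAML mappings mirroring :class:`mitoloc.simulate.SimulationConfig`.
Lengths are micrometres unless the geometry section sets
``length_unit: nm`` (diffusivity stays in um^2/s either way).  Every run
writes a manifest recording the seed, the config hash and the package
version, so any output table can be regenerated byte-identically.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .closed_forms import (
    beta,
    beta_mature,
    mature_exposure_time,
    mean_search_time,
)
from .four_state import (
    FourStateRates,
    limit_rapid_transport,
    limit_slow_transport,
    steady_state,
)
from .propagator import CylinderGeometry, geometry_from_mvf
from .rates import build_gene_table
from .simulate import (
    SimulationConfig,
    ensemble_chx_localization,
    ensemble_localization,
    simulate_ensemble,
    sweep,
)
from .synthetic import SyntheticCohortSpec, generate_synthetic_cohort
from .translation import CompetenceModel, GeneKinetics

__all__ = [
    "ConfigError",
    "load_config",
    "build_simulation_config",
    "run_experiment",
]

COMMANDS = ("simulate", "sweep", "rates", "closedform", "fourstate", "synth")


class ConfigError(ValueError):
    """Configuration problem, reported with the offending key path."""


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ConfigError(f"missing required key: {path}.{key}" if path else
                          f"missing required key: {key}")
    return mapping[key]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _build_gene(section: dict) -> GeneKinetics:
    return GeneKinetics(
        name=str(section.get("name", "gene")),
        k_init=float(_require(section, "k_init", "gene")),
        k_elong=float(_require(section, "k_elong", "gene")),
        L=int(_require(section, "L", "gene")),
        l_MTS=int(section.get("l_MTS", 100)),
    )


def _build_competence(section: dict) -> CompetenceModel:
    mode = section.get("mode", "instantaneous")
    if mode == "instantaneous":
        return CompetenceModel.instantaneous()
    if mode == "maturation":
        if "tau_MTS" in section:
            return CompetenceModel.maturation(float(section["tau_MTS"]))
        if "k_MTS" in section:
            return CompetenceModel("maturation", float(section["k_MTS"]))
        raise ConfigError("competence.tau_MTS (or k_MTS) required in maturation mode")
    raise ConfigError(f"competence.mode must be instantaneous|maturation, got {mode}")


def _build_geometry(section: dict) -> CylinderGeometry:
    section = dict(section)
    unit = section.pop("length_unit", "um")
    if unit not in ("um", "nm"):
        raise ConfigError("geometry.length_unit must be 'um' or 'nm'")
    scale = 1e-3 if unit == "nm" else 1.0
    f_m = float(_require(section, "f_m", "geometry"))
    overrides = {}
    for key in ("r_m", "r_a", "r_b", "eps"):
        if key in section:
            overrides[key] = float(section.pop(key)) * scale
    for key in ("D", "accessible_fraction", "V_cell"):
        if key in section:
            overrides[key] = float(section.pop(key))
    section.pop("f_m", None)
    if section:
        raise ConfigError(f"unknown geometry keys: {sorted(section)}")
    return geometry_from_mvf(f_m, **overrides)


def build_simulation_config(cfg: dict) -> SimulationConfig:
    """Assemble a :class:`SimulationConfig` from a parsed config mapping."""
    nuclear = cfg.get("nuclear", {})
    return SimulationConfig(
        gene=_build_gene(_require(cfg, "gene", "")),
        competence=_build_competence(cfg.get("competence", {})),
        geometry=_build_geometry(_require(cfg, "geometry", "")),
        k_decay=float(cfg.get("k_decay", 0.0017)),
        nuclear_mean=float(nuclear.get("mean", 60.0)),
        nuclear_sd=float(nuclear.get("sd", 30.0)),
        n_trajectories=int(cfg.get("n_trajectories", 50)),
        seed=int(cfg.get("seed", 0)),
        max_time=float(cfg.get("max_time", 6000.0)),
    )


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trajectory": np.arange(len(records)),
            "T_lifetime": [r.T_lifetime for r in records],
            "t_nuclear": [r.t_nuclear for r in records],
            "t_region1": [r.t_region1 for r in records],
            "t_region2": [r.t_region2 for r in records],
            "t_region3": [r.t_region3 for r in records],
            "t_bound": [r.t_bound for r in records],
            "t_translated_mts": [r.t_translated_mts for r in records],
            "t_competent_mts": [r.t_competent_mts for r in records],
            "f_loc_binding": [r.f_loc_binding for r in records],
            "f_loc_imaging": [r.f_loc_imaging for r in records],
            "decayed": [int(r.decayed) for r in records],
            "n_bindings": [r.n_bindings for r in records],
        }
    )


def fourstate_frame(rates: FourStateRates) -> pd.DataFrame:
    dist = steady_state(rates)
    return pd.DataFrame(
        [
            {
                "k_S": rates.k_S, "k_U": rates.k_U,
                "k_R": rates.k_R, "k_L": rates.k_L,
                "f_s": rates.f_s, "f_d": rates.f_d,
                "p_SN": dist.p_SN, "p_SF": dist.p_SF,
                "p_UN": dist.p_UN, "p_UF": dist.p_UF,
                "localized": dist.localized,
                "rapid_transport_limit": limit_rapid_transport(rates.f_s, rates.f_d),
                "slow_transport_limit": limit_slow_transport(rates.f_s, rates.f_d),
            }
        ]
    )


def closedform_frame(gene: GeneKinetics, tau_MTS: float,
                     geometry: CylinderGeometry) -> pd.DataFrame:
    k_MTS = 1.0 / tau_MTS
    return pd.DataFrame(
        [
            {
                "name": gene.name,
                "beta": beta(gene),
                "beta_mature": beta_mature(gene, k_MTS),
                "t_expo": gene.t_expo,
                "t_expo_mature": mature_exposure_time(gene, k_MTS),
                "t_search": mean_search_time(geometry.r_a, geometry.R_out,
                                             geometry.D),
            }
        ]
    )


def run_experiment(config_path, outdir) -> Path:
    """Execute the command named in a config file; write tables + manifest."""
    config_path = Path(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    command = _require(cfg, "command", "")
    if command not in COMMANDS:
        raise ConfigError(f"command must be one of {COMMANDS}, got {command!r}")
    seed = int(cfg.get("seed", 0))

    if command == "fourstate":
        sec = _require(cfg, "fourstate", "")
        rates = FourStateRates(*(float(_require(sec, k, "fourstate"))
                                 for k in ("k_S", "k_U", "k_R", "k_L")))
        _write_tsv(fourstate_frame(rates), outdir / "summary.tsv")
    elif command == "closedform":
        gene = _build_gene(_require(cfg, "gene", ""))
        tau = float(cfg.get("tau_MTS", 40.0))
        geom = _build_geometry(cfg.get("geometry", {"f_m": 0.04}))
        _write_tsv(closedform_frame(gene, tau, geom), outdir / "summary.tsv")
    elif command == "rates":
        sec = _require(cfg, "rates", "")
        table = pd.read_csv(_require(sec, "input", "rates"), sep="\t")
        out = build_gene_table(table, tau_MTS=float(sec.get("tau_MTS", 40.0)))
        _write_tsv(out, outdir / "genes.tsv")
    elif command == "synth":
        sec = cfg.get("synth", {})
        spec = SyntheticCohortSpec(
            n_conditional=int(sec.get("n_conditional", 52)),
            n_constitutive=int(sec.get("n_constitutive", 70)),
            sigma_log=float(sec.get("sigma_log", 0.4)),
            seed=seed,
        )
        _write_tsv(generate_synthetic_cohort(spec), outdir / "genes.tsv")
    elif command == "simulate":
        sim = build_simulation_config(cfg)
        records = simulate_ensemble(sim)
        _write_tsv(records_frame(records), outdir / "trajectories.tsv")
        summary = pd.DataFrame(
            [
                {
                    "gene": sim.gene.name,
                    "n_trajectories": sim.n_trajectories,
                    "f_binding": ensemble_localization(records, "binding"),
                    "f_imaging": ensemble_localization(records, "imaging"),
                    "f_chx": ensemble_chx_localization(records),
                }
            ]
        )
        _write_tsv(summary, outdir / "summary.tsv")
    elif command == "sweep":
        sim = build_simulation_config(cfg)
        sec = _require(cfg, "sweep", "")
        axis = _require(sec, "axis", "sweep")
        values = [float(v) for v in _require(sec, "values", "sweep")]
        _write_tsv(sweep(sim, axis, values), outdir / "sweep.tsv")

    digest = hashlib.sha256(config_path.read_bytes()).hexdigest()
    (outdir / "manifest.txt").write_text(
        f"command\t{command}\nseed\t{seed}\nconfig_sha256\t{digest}\n"
        f"mitoloc_version\t{__version__}\n"
    )
    return outdir
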