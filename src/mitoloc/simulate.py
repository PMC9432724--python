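"""Whole-lifetime mRNA trajectories: translation coupled to spatial transport.

One trajectory runs from mRNA synthesis to decay: a nuclear residence
(no translation, no decay), placement at the outer reflecting wall, then
alternating diffusive region transitions and translation-driven competence
changes until the decay clock fires.  A binding-competent mRNA entering
region 1 binds the mitochondrial surface instantly and irreversibly; it is
released only when its last competent MTS terminates, at which point it is
re-placed uniformly over the binding-shell cross-section.

Because translation kinetics are independent of the mRNA's position (and
binding affects transport only, not elongation), each trajectory first
simulates the full translation/competence/decay time course with the exact
Gillespie kernel and then drives the spatial event loop against the
resulting piecewise-constant competence indicator.  By memorylessness of
all translation clocks this is statistically identical to interleaving the
two processes event by event and resampling translation times at every
region change, but draws each spatial first-passage time exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .propagator import CylinderGeometry, RegionPropagators, geometry_from_mvf, get_propagators
from .translation import (
    DEFAULT_K_DECAY,
    NUCLEAR_MEAN_S,
    NUCLEAR_SD_S,
    CompetenceModel,
    GeneKinetics,
    sample_nuclear_residence,
    simulate_translation,
)

__all__ = [
    "SimulationConfig",
    "TrajectoryRecord",
    "simulate_mrna",
    "simulate_ensemble",
    "ensemble_localization",
    "ensemble_chx_localization",
    "sweep",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce an ensemble of mRNA trajectories."""

    gene: GeneKinetics
    competence: CompetenceModel
    geometry: CylinderGeometry
    k_decay: float = DEFAULT_K_DECAY
    nuclear_mean: float = NUCLEAR_MEAN_S
    nuclear_sd: float = NUCLEAR_SD_S
    n_trajectories: int = 50
    seed: int = 0
    max_time: float = 6000.0  # horizon (s) when k_decay = 0: 10x the 600 s mean life

    def __post_init__(self):
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.k_decay < 0:
            raise ValueError("k_decay must be >= 0")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")


@dataclass
class TrajectoryRecord:
    """Lifetime and time-in-state accounting for one mRNA trajectory.

    The component times satisfy
    ``t_nuclear + t_region1 + t_region2 + t_region3 + t_bound == T_lifetime``
    to float round-off.  Bound time counts as region-1 (and hence imaging)
    localized time; region times are unbound residence only.
    """

    T_lifetime: float
    t_nuclear: float
    t_region1: float
    t_region2: float
    t_region3: float
    t_bound: float
    t_translated_mts: float   # cytosolic time with >=1 translated MTS
    t_competent_mts: float    # cytosolic time with >=1 mature MTS
    decayed: bool
    n_bindings: int

    @property
    def f_loc_binding(self) -> float:
        """Fraction of lifetime within binding range (region 1, incl. bound)."""
        return (self.t_region1 + self.t_bound) / self.T_lifetime

    @property
    def f_loc_imaging(self) -> float:
        """Fraction of lifetime within imaging range (regions 1+2, incl. bound)."""
        return (self.t_region1 + self.t_region2 + self.t_bound) / self.T_lifetime


def _switch_state(switches: np.ndarray, t: float) -> tuple[bool, float]:
    """State of an on/off indicator with given toggle times, and next toggle.

    ``switches`` alternates on/off starting with an 'on'.  Returns
    (state at time t, time of next toggle after t; inf if none).
    """
    idx = int(np.searchsorted(switches, t, side="right"))
    state = idx % 2 == 1
    nxt = switches[idx] if idx < len(switches) else math.inf
    return state, float(nxt)


def _simulate_spatial(
    props: RegionPropagators,
    comp_switches: np.ndarray,
    t_cyt: float,
    rng: np.random.Generator,
):
    """Drive the region event loop against a fixed competence indicator.

    Returns (t_region1, t_region2, t_region3, t_bound, n_bindings).
    Start: outer reflecting wall (nuclear export), region 3, unbound.
    """
    geom = props.geom
    t = 0.0
    t_r = [0.0, 0.0, 0.0]  # unbound residence per region
    t_bound = 0.0
    n_bindings = 0

    region = 3
    r3_start = "outer_wall"
    r1_r0 = None  # None -> canonical entry at r_a - eps
    bound = False

    while t < t_cyt:
        if bound:
            # bound until the last competent MTS disappears
            _, t_off = _switch_state(comp_switches, t)
            t_next = min(t_off, t_cyt)
            t_bound += t_next - t
            t = t_next
            if t >= t_cyt:
                break
            # unbind: re-place uniformly over the binding shell
            bound = False
            region = 1
            r1_r0 = props.sample_unbinding_position(rng)
            continue

        if region == 1:
            competent, t_on = _switch_state(comp_switches, t)
            if competent:
                bound = True
                n_bindings += 1
                r1_r0 = None
                continue
            dt_exit = props.sample_region1_exit(rng, r1_r0)
            t_exit = t + dt_exit
            t_next = min(t_exit, t_on, t_cyt)
            t_r[0] += t_next - t
            t = t_next
            if t >= t_cyt:
                break
            if t == t_on:
                # gained competence while inside region 1: binds, exit cancelled
                bound = True
                n_bindings += 1
                r1_r0 = None
            else:
                region = 2
                r2_entry = "inner"
                r1_r0 = None
        elif region == 2:
            side, dt_tr = props.sample_region2_transit(r2_entry, rng)
            t_next = min(t + dt_tr, t_cyt)
            t_r[1] += t_next - t
            t = t_next
            if t >= t_cyt:
                break
            if side == "inner":
                region = 1
                r1_r0 = None
            else:
                region = 3
                r3_start = "inner_edge"
        else:  # region 3
            dt_ret = props.sample_region3_return(rng, r3_start)
            t_next = min(t + dt_ret, t_cyt)
            t_r[2] += t_next - t
            t = t_next
            if t >= t_cyt:
                break
            region = 2
            r2_entry = "outer"

    return t_r[0], t_r[1], t_r[2], t_bound, n_bindings


def _trajectory_seeds(seed: int, index: int):
    """Independent, order-free streams for one trajectory.

    Returns (kernel SeedSequence for the translation Gillespie RNG,
    Generator for nuclear residence + spatial sampling).
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    kernel_ss, spatial_ss = ss.spawn(2)
    return kernel_ss, np.random.default_rng(spatial_ss)


def simulate_mrna(config: SimulationConfig, trajectory_index: int) -> TrajectoryRecord:
    """Simulate one mRNA from synthesis to decay; bit-reproducible.

    The RNG streams are derived from ``(config.seed, trajectory_index)``
    only, so ensembles are reproducible independently of execution order.
    """
    kernel_ss, rng = _trajectory_seeds(config.seed, trajectory_index)
    t_nuc = sample_nuclear_residence(rng, mean=config.nuclear_mean,
                                     sd=config.nuclear_sd)
    traj = simulate_translation(
        config.gene, config.competence,
        k_decay=config.k_decay, seed=kernel_ss, max_time=config.max_time,
    )
    props = get_propagators(config.geometry)
    t1, t2, t3, tb, nb = _simulate_spatial(
        props, traj.competence_switches, traj.lifetime, rng
    )
    return TrajectoryRecord(
        T_lifetime=t_nuc + traj.lifetime,
        t_nuclear=t_nuc,
        t_region1=t1,
        t_region2=t2,
        t_region3=t3,
        t_bound=tb,
        t_translated_mts=traj.translated_time,
        t_competent_mts=traj.competent_time,
        decayed=traj.decayed,
        n_bindings=nb,
    )


def simulate_ensemble(config: SimulationConfig) -> list[TrajectoryRecord]:
    """Simulate ``config.n_trajectories`` independent mRNA lifetimes."""
    return [simulate_mrna(config, i) for i in range(config.n_trajectories)]


def ensemble_localization(records, measure: str = "binding") -> float:
    """Lifetime-weighted ensemble localization fraction.

    ``sum_i f_loc,i T_lifetime,i / sum_i T_lifetime,i`` with f_loc the
    fraction of lifetime within binding range (``measure='binding'``,
    region 1) or within imaging range (``measure='imaging'``, regions 1+2);
    bound time counts in both.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record set")
    if measure not in ("binding", "imaging"):
        raise ValueError("measure must be 'binding' or 'imaging'")
    T = np.array([r.T_lifetime for r in records])
    f = np.array(
        [r.f_loc_binding if measure == "binding" else r.f_loc_imaging
         for r in records]
    )
    return float((f * T).sum() / T.sum())


def ensemble_chx_localization(records) -> float:
    """Localization fraction under cycloheximide (CHX) arrest.

    CHX freezes elongation, so any mRNA holding at least one fully
    translated (not necessarily mature) MTS can localize; the statistic is
    the lifetime-weighted fraction of lifetime with >=1 translated MTS.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record set")
    T = np.array([r.T_lifetime for r in records])
    num = np.array([r.t_translated_mts for r in records])
    return float(num.sum() / T.sum())


_SWEEP_AXES = ("mvf", "k_init", "k_elong", "tau_MTS", "D", "k_decay")


def _config_for(config: SimulationConfig, axis: str, value: float) -> SimulationConfig:
    if axis == "mvf":
        geom = geometry_from_mvf(
            value, r_m=config.geometry.r_m, r_a=config.geometry.r_a,
            r_b=config.geometry.r_b, eps=config.geometry.eps,
            D=config.geometry.D,
            accessible_fraction=config.geometry.accessible_fraction,
        )
        return replace(config, geometry=geom)
    if axis == "k_init":
        return replace(config, gene=replace(config.gene, k_init=value))
    if axis == "k_elong":
        return replace(config, gene=replace(config.gene, k_elong=value))
    if axis == "tau_MTS":
        return replace(config, competence=CompetenceModel.maturation(value))
    if axis == "D":
        return replace(config, geometry=replace(config.geometry, D=value))
    if axis == "k_decay":
        return replace(config, k_decay=value)
    raise ValueError(f"axis must be one of {_SWEEP_AXES}")


def sweep(config: SimulationConfig, axis: str, values) -> pd.DataFrame:
    """Ensemble localization along one parameter axis.

    All rows share the base seed (matched random numbers across values for
    variance reduction).  Inadmissible values are reported per row in the
    ``error`` column rather than aborting the sweep.
    """
    if axis not in _SWEEP_AXES:
        raise ValueError(f"axis must be one of {_SWEEP_AXES}")
    rows = []
    for v in values:
        row = {"axis": axis, "value": float(v), "f_binding": np.nan,
               "f_imaging": np.nan, "f_chx": np.nan, "error": ""}
        try:
            cfg = _config_for(config, axis, float(v))
            recs = simulate_ensemble(cfg)
            row["f_binding"] = ensemble_localization(recs, "binding")
            row["f_imaging"] = ensemble_localization(recs, "imaging")
            row["f_chx"] = ensemble_chx_localization(recs)
        except (ValueError, ArithmeticError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
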