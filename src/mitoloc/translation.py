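"""Gillespie simulation of translation on a single mRNA.

Ribosomes initiate at rate ``k_init`` when the first codon is free, hop to
the next codon at rate ``k_elong`` when it is free (1-codon footprint
exclusion), and terminate at rate ``k_elong`` from the final codon.  A
ribosome whose position reaches ``l_MTS`` has a fully translated MTS; in
the maturation competence model that MTS becomes binding-competent after
an independent Exp(k_MTS) delay drawn inside the Gillespie loop, in the
instantaneous model it is competent immediately.  An exponential decay
clock at ``k_decay`` (active only during cytosolic life) terminates the
trajectory and discards all ribosomes.

The exact-stochastic event loop is compiled with numba; a trajectory is a
few thousand events for typical yeast parameters and sub-millisecond to
simulate, which makes the large parameter-scan ensembles used elsewhere in
the package practical on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "GeneKinetics",
    "CompetenceModel",
    "TranslationTrajectory",
    "simulate_translation",
    "competent_fraction",
    "chx_localizable_fraction",
    "sample_nuclear_residence",
    "NUCLEAR_MEAN_S",
    "NUCLEAR_SD_S",
    "DEFAULT_K_DECAY",
]

#: default mRNA decay rate (1/s); typical decay time 600 s
DEFAULT_K_DECAY = 0.0017
#: nuclear residence: positive-truncated normal, mean 60 s, sd 30 s
NUCLEAR_MEAN_S = 60.0
NUCLEAR_SD_S = 30.0

# event codes in the trajectory log
EV_INIT, EV_HOP, EV_TERMINATE, EV_MATURE, EV_DECAY = 0, 1, 2, 3, 4
EVENT_NAMES = {
    EV_INIT: "init",
    EV_HOP: "hop",
    EV_TERMINATE: "terminate",
    EV_MATURE: "mature",
    EV_DECAY: "decay",
}


@dataclass(frozen=True)
class GeneKinetics:
    """Per-gene translation parameters.

    Parameters
    ----------
    name : gene identifier.
    k_init : translation initiation rate (1/s).
    k_elong : ribosome elongation rate (codons/s).
    L : transcript length (codons).
    l_MTS : codon index at which the MTS is fully translated and has
        cleared the ribosome exit tunnel (default 100: up to ~70 aa of MTS
        plus ~30 aa of exit tunnel).
    """

    name: str
    k_init: float
    k_elong: float
    L: int
    l_MTS: int = 100

    def __post_init__(self):
        if self.k_init <= 0 or not np.isfinite(self.k_init):
            raise ValueError("k_init must be positive")
        if self.k_elong <= 0 or not np.isfinite(self.k_elong):
            raise ValueError("k_elong must be positive")
        if int(self.L) != self.L or self.L < 1:
            raise ValueError("L must be an integer >= 1")
        if int(self.l_MTS) != self.l_MTS or self.l_MTS < 1:
            raise ValueError("l_MTS must be an integer >= 1")

    @property
    def rho_ribo(self) -> float:
        """Low-occupancy ribosome line density k_init/k_elong (per codon)."""
        return self.k_init / self.k_elong

    @property
    def t_max(self) -> float:
        """Post-MTS elongation horizon (L - l_MTS)/k_elong (s); 0 if L < l_MTS."""
        return max(self.L - self.l_MTS, 0) / self.k_elong

    @property
    def T_total(self) -> float:
        """Total translation time L/k_elong (s)."""
        return self.L / self.k_elong

    @property
    def t_expo(self) -> float:
        """Instantaneous-model MTS exposure time (L - l_MTS)/k_elong (s)."""
        return self.t_max


@dataclass(frozen=True)
class CompetenceModel:
    """How a translated MTS becomes binding-competent.

    mode="instantaneous": competent the moment the ribosome passes l_MTS
    (the k_MTS -> infinity limit).  mode="maturation": each translated MTS
    carries an independent exponential maturation clock at rate ``k_MTS``.
    """

    mode: str = "instantaneous"
    k_MTS: float = math.inf

    def __post_init__(self):
        if self.mode not in ("instantaneous", "maturation"):
            raise ValueError("mode must be 'instantaneous' or 'maturation'")
        if self.mode == "maturation" and not (
            np.isfinite(self.k_MTS) and self.k_MTS > 0
        ):
            raise ValueError("maturation mode requires finite k_MTS > 0")

    @classmethod
    def instantaneous(cls) -> "CompetenceModel":
        return cls("instantaneous", math.inf)

    @classmethod
    def maturation(cls, tau_MTS: float) -> "CompetenceModel":
        """Build from the mean maturation time tau_MTS = 1/k_MTS (s)."""
        if tau_MTS <= 0:
            raise ValueError("tau_MTS must be positive")
        return cls("maturation", 1.0 / tau_MTS)

    @property
    def tau_MTS(self) -> float:
        """Mean maturation time 1/k_MTS (s); 0 in instantaneous mode."""
        return 0.0 if math.isinf(self.k_MTS) else 1.0 / self.k_MTS


@njit(cache=True)
def _translation_kernel(
    k_init, k_elong, L, l_mts, k_mts, instantaneous,
    k_decay, max_time, seed, record_events,
):
    """Exact Gillespie loop; see module docstring for the event rules.

    Returns compact per-trajectory summaries plus on/off switch times of
    the >=1-mature and >=1-translated indicators, and (optionally) the
    full event log.
    """
    np.random.seed(seed)

    cap = L + 1  # max concurrent ribosomes with 1-codon footprint
    pos = np.zeros(cap, np.int64)        # circular buffer, head = lead ribosome
    translated = np.zeros(cap, np.uint8)
    mature = np.zeros(cap, np.uint8)
    head = 0
    n_ribo = 0
    n_trans = 0
    n_mature = 0

    nev = 0
    ev_cap = 256 if record_events else 1
    ev_t = np.empty(ev_cap, np.float64)
    ev_kind = np.empty(ev_cap, np.int8)
    ev_ribo = np.empty(ev_cap, np.int64)

    n_comp = 0
    comp_cap = 64
    comp_sw = np.empty(comp_cap, np.float64)
    n_transw = 0
    trans_cap = 64
    trans_sw = np.empty(trans_cap, np.float64)

    # time integrals of counts, and time with >=1 translated / mature MTS
    int_ribo = 0.0
    int_trans = 0.0
    int_mature = 0.0
    t_ge1_trans = 0.0
    t_ge1_mature = 0.0

    n_completed = 0
    next_rid = 0  # ribosome ids in initiation order

    t = 0.0
    decayed = 0
    while True:
        # --- propensities ---
        a_init = 0.0
        if n_ribo == 0 or pos[(head + n_ribo - 1) % cap] > 1:
            a_init = k_init
        n_mov = 0
        for i in range(n_ribo):
            j = (head + i) % cap
            if i == 0:
                n_mov += 1  # lead ribosome always hops or terminates
            elif pos[(head + i - 1) % cap] - pos[j] > 1:
                n_mov += 1
        a_move = k_elong * n_mov
        a_mat = 0.0
        if not instantaneous:
            a_mat = k_mts * (n_trans - n_mature)
        a_tot = a_init + a_move + a_mat + k_decay

        if a_tot <= 0.0:
            dt = max_time - t
        else:
            dt = np.random.exponential(1.0 / a_tot)

        t_new = t + dt
        if t_new >= max_time:
            dt_eff = max_time - t
            int_ribo += n_ribo * dt_eff
            int_trans += n_trans * dt_eff
            int_mature += n_mature * dt_eff
            if n_trans > 0:
                t_ge1_trans += dt_eff
            if n_mature > 0:
                t_ge1_mature += dt_eff
            t = max_time
            break

        int_ribo += n_ribo * dt
        int_trans += n_trans * dt
        int_mature += n_mature * dt
        if n_trans > 0:
            t_ge1_trans += dt
        if n_mature > 0:
            t_ge1_mature += dt
        t = t_new

        prev_trans = n_trans
        prev_mature = n_mature

        # --- choose event ---
        u = np.random.rand() * a_tot
        kind = -1
        rid = -1
        if u < k_decay:
            decayed = 1
            kind = EV_DECAY
        elif u < k_decay + a_init:
            j = (head + n_ribo) % cap
            pos[j] = 1
            translated[j] = 0
            mature[j] = 0
            rid = next_rid
            next_rid += 1
            n_ribo += 1
            if 1 >= l_mts:
                translated[j] = 1
                n_trans += 1
                if instantaneous:
                    mature[j] = 1
                    n_mature += 1
            kind = EV_INIT
        elif u < k_decay + a_init + a_move:
            m = int((u - k_decay - a_init) / k_elong)
            if m >= n_mov:
                m = n_mov - 1
            # find the m-th movable ribosome
            cnt = -1
            sel = -1
            for i in range(n_ribo):
                j = (head + i) % cap
                movable = False
                if i == 0:
                    movable = True
                elif pos[(head + i - 1) % cap] - pos[j] > 1:
                    movable = True
                if movable:
                    cnt += 1
                    if cnt == m:
                        sel = i
                        break
            j = (head + sel) % cap
            rid = next_rid - n_ribo + sel  # id consistent with init order
            if sel == 0 and pos[j] == L:
                # termination
                if translated[j] == 1:
                    n_trans -= 1
                if mature[j] == 1:
                    n_mature -= 1
                head = (head + 1) % cap
                n_ribo -= 1
                n_completed += 1
                kind = EV_TERMINATE
            else:
                pos[j] += 1
                if pos[j] == l_mts and translated[j] == 0:
                    translated[j] = 1
                    n_trans += 1
                    if instantaneous:
                        mature[j] = 1
                        n_mature += 1
                kind = EV_HOP
        else:
            # maturation: pick uniformly among translated-but-immature
            k = int((u - k_decay - a_init - a_move) / k_mts)
            n_imm = n_trans - n_mature
            if k >= n_imm:
                k = n_imm - 1
            cnt = -1
            for i in range(n_ribo):
                j = (head + i) % cap
                if translated[j] == 1 and mature[j] == 0:
                    cnt += 1
                    if cnt == k:
                        mature[j] = 1
                        n_mature += 1
                        rid = next_rid - n_ribo + i
                        break
            kind = EV_MATURE

        if record_events:
            if nev >= ev_cap:
                ev_cap *= 2
                tmp_t = np.empty(ev_cap, np.float64)
                tmp_k = np.empty(ev_cap, np.int8)
                tmp_r = np.empty(ev_cap, np.int64)
                tmp_t[:nev] = ev_t[:nev]
                tmp_k[:nev] = ev_kind[:nev]
                tmp_r[:nev] = ev_ribo[:nev]
                ev_t, ev_kind, ev_ribo = tmp_t, tmp_k, tmp_r
            ev_t[nev] = t
            ev_kind[nev] = kind
            ev_ribo[nev] = rid
            nev += 1

        # competence / translated indicator switches
        if (prev_mature == 0) != (n_mature == 0):
            if n_comp >= comp_cap:
                comp_cap *= 2
                tmp = np.empty(comp_cap, np.float64)
                tmp[:n_comp] = comp_sw[:n_comp]
                comp_sw = tmp
            comp_sw[n_comp] = t
            n_comp += 1
        if (prev_trans == 0) != (n_trans == 0):
            if n_transw >= trans_cap:
                trans_cap *= 2
                tmp = np.empty(trans_cap, np.float64)
                tmp[:n_transw] = trans_sw[:n_transw]
                trans_sw = tmp
            trans_sw[n_transw] = t
            n_transw += 1

        if decayed:
            break

    return (
        t, decayed,
        comp_sw[:n_comp].copy(), trans_sw[:n_transw].copy(),
        int_ribo, int_trans, int_mature, t_ge1_trans, t_ge1_mature,
        n_completed,
        ev_t[:nev].copy(), ev_kind[:nev].copy(), ev_ribo[:nev].copy(),
    )



@dataclass
class TranslationTrajectory:
    """Outcome of one cytosolic translation trajectory.

    Times are measured from nuclear export (cytosol entry).  The
    binding-competence indicator is "at least one mature MTS"; in the
    instantaneous competence model mature and translated coincide.
    ``competence_switches`` / ``translated_switches`` hold the times at
    which the respective >=1 indicator toggled, alternating on/off and
    starting with an 'on'; an unpaired final entry means the trajectory
    ended in the on state.
    """

    gene: GeneKinetics
    model: CompetenceModel
    lifetime: float                 # cytosolic lifetime (s)
    decayed: bool                   # False = max_time horizon reached
    competence_switches: np.ndarray
    translated_switches: np.ndarray
    time_avg_ribosomes: float
    time_avg_translated_mts: float
    time_avg_mature_mts: float
    competent_time: float           # time with >=1 mature MTS (s)
    translated_time: float          # time with >=1 translated MTS (s)
    n_completed: int                # full protein completions
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_kinds: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    event_ribosomes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def event_log(self) -> str:
        """Tab-separated event log (time, event, ribosome id) for debugging."""
        lines = ["time_s\tevent\tribosome"]
        for t, k, r in zip(self.event_times, self.event_kinds, self.event_ribosomes):
            lines.append(f"{t:.9g}\t{EVENT_NAMES[int(k)]}\t{int(r)}")
        return "\n".join(lines) + "\n"


def _kernel_seed(seed_or_seq) -> int:
    if isinstance(seed_or_seq, np.random.SeedSequence):
        return int(seed_or_seq.generate_state(1, np.uint32)[0])
    return int(np.random.SeedSequence(seed_or_seq).generate_state(1, np.uint32)[0])


def simulate_translation(
    gene: GeneKinetics,
    model: CompetenceModel,
    k_decay: float = DEFAULT_K_DECAY,
    seed=0,
    max_time: float = 36000.0,
    record_events: bool = False,
) -> TranslationTrajectory:
    """Simulate one mRNA's translation from cytosol entry to decay.

    ``seed`` may be an integer or a ``numpy.random.SeedSequence``.  If
    ``k_decay == 0`` the trajectory runs to the ``max_time`` horizon.
    ``L < l_MTS`` is permitted: the MTS is never completed and the
    competence indicator is identically zero.
    """
    if k_decay < 0:
        raise ValueError("k_decay must be >= 0")
    if k_decay == 0 and not (max_time > 0 and np.isfinite(max_time)):
        raise ValueError("with k_decay = 0 a finite positive max_time is required")
    instantaneous = model.mode == "instantaneous"
    k_mts = 0.0 if instantaneous else model.k_MTS
    (
        t_end, decayed, comp_sw, trans_sw,
        int_ribo, int_trans, int_mature, t_ge1_trans, t_ge1_mature,
        n_completed, ev_t, ev_k, ev_r,
    ) = _translation_kernel(
        gene.k_init, gene.k_elong, int(gene.L), int(gene.l_MTS),
        k_mts, instantaneous, k_decay, max_time,
        _kernel_seed(seed), record_events,
    )
    return TranslationTrajectory(
        gene=gene,
        model=model,
        lifetime=t_end,
        decayed=bool(decayed),
        competence_switches=comp_sw,
        translated_switches=trans_sw,
        time_avg_ribosomes=int_ribo / t_end if t_end > 0 else 0.0,
        time_avg_translated_mts=int_trans / t_end if t_end > 0 else 0.0,
        time_avg_mature_mts=int_mature / t_end if t_end > 0 else 0.0,
        competent_time=t_ge1_mature,
        translated_time=t_ge1_trans,
        n_completed=int(n_completed),
        event_times=ev_t,
        event_kinds=ev_k,
        event_ribosomes=ev_r,
    )


def _weighted_fraction(numerators, lifetimes) -> float:
    num = np.asarray(numerators, dtype=float)
    life = np.asarray(lifetimes, dtype=float)
    if num.size == 0:
        raise ValueError("empty trajectory ensemble")
    if np.any(life <= 0):
        raise ValueError("lifetimes must be positive")
    if num.shape != life.shape:
        raise ValueError("trajectories and lifetimes must align")
    return float(num.sum() / life.sum())


def competent_fraction(trajectories, lifetimes) -> float:
    """Lifetime-weighted fraction of total lifetime that is binding-competent.

    ``sum_i t_competent,i / sum_i T_lifetime,i`` — each trajectory's
    contribution is weighted by its lifetime, so the statistic equals the
    probability that an mRNA sampled proportionally to its lifetime is
    competent.  ``lifetimes`` may include nuclear residence (in which case
    the nuclear period counts as incompetent time) or equal the cytosolic
    lifetimes to exclude it.
    """
    return _weighted_fraction([tr.competent_time for tr in trajectories], lifetimes)


def chx_localizable_fraction(trajectories, lifetimes) -> float:
    """Lifetime-weighted fraction of lifetime with >=1 *translated* MTS.

    Cycloheximide arrests elongation, leaving every fully translated MTS
    exposed indefinitely, so any mRNA carrying a translated (not
    necessarily mature) MTS can localize.  Equals
    :func:`competent_fraction` in the instantaneous model and bounds it
    from above in the maturation model.
    """
    return _weighted_fraction([tr.translated_time for tr in trajectories], lifetimes)


def competency_screen(
    n_sets: int,
    seed: int,
    beta_window: tuple[float, float] | None = None,
    n_trajectories: int = 50,
    model: CompetenceModel | None = None,
    k_decay: float = DEFAULT_K_DECAY,
    k_init_range: tuple[float, float] = (1e-3, 0.5),
    L_range: tuple[int, int] = (150, 600),
    k_elong_range: tuple[float, float] = (1.0, 10.0),
    include_nuclear: bool = True,
    max_attempts_factor: int = 2000,
):
    """Lifetime-competent fraction across random translation parameters.

    Draws translation-parameter triplets — ``k_init`` log-uniform (it
    spans ~2.7 decades physiologically), ``L`` and ``k_elong`` uniform —
    from the stated ranges, optionally rejecting triplets whose mean
    translated-MTS count ``beta`` falls outside ``beta_window``.  For each
    accepted triplet an ensemble of translation-only trajectories is
    simulated (nuclear residence and cytosolic decay active) and the
    lifetime-weighted competent fraction recorded.  Lifetimes include
    nuclear residence unless ``include_nuclear`` is false.

    Returns a DataFrame with columns k_init, k_elong, L, beta,
    competent_fraction.
    """
    import pandas as pd  # local import: keeps module import light

    if model is None:
        model = CompetenceModel.instantaneous()
    root = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    rows = []
    attempts = 0
    max_attempts = max_attempts_factor * n_sets
    while len(rows) < n_sets:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"accepted only {len(rows)}/{n_sets} parameter sets after "
                f"{attempts} draws; beta_window={beta_window} too narrow"
            )
        lo, hi = k_init_range
        k_init = math.exp(param_rng.uniform(math.log(lo), math.log(hi)))
        L = int(param_rng.integers(L_range[0], L_range[1] + 1))
        k_elong = param_rng.uniform(*k_elong_range)
        gene = GeneKinetics(f"set{len(rows)}", k_init, k_elong, L)
        b = gene.k_init * max(L - gene.l_MTS, 0) / gene.k_elong
        if beta_window is not None and not (beta_window[0] <= b <= beta_window[1]):
            continue
        set_ss = np.random.SeedSequence(
            entropy=seed, spawn_key=(1, len(rows))
        )
        comp_time = 0.0
        total_life = 0.0
        nuc_rng = np.random.default_rng(set_ss.spawn(1)[0])
        for j in range(n_trajectories):
            traj = simulate_translation(
                gene, model, k_decay=k_decay,
                seed=np.random.SeedSequence(entropy=seed, spawn_key=(2, len(rows), j)),
            )
            t_nuc = sample_nuclear_residence(nuc_rng) if include_nuclear else 0.0
            comp_time += traj.competent_time
            total_life += traj.lifetime + t_nuc
        rows.append(
            {
                "k_init": k_init,
                "k_elong": k_elong,
                "L": L,
                "beta": b,
                "competent_fraction": comp_time / total_life,
            }
        )
    return pd.DataFrame(rows)


def sample_nuclear_residence(
    rng: np.random.Generator,
    size=None,
    mean: float = NUCLEAR_MEAN_S,
    sd: float = NUCLEAR_SD_S,
):
    """Nuclear residence time(s): Normal(mean, sd), resampled until positive."""
    if size is None:
        while True:
            x = rng.normal(mean, sd)
            if x > 0:
                return x
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out
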