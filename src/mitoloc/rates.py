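"""Gene-specific translation-rate estimation from steady-state measurements.

Initiation rate: at steady state each mRNA makes protein at rate k_init and
proteins are effectively removed by cell division (lifetime T_div), so
``k_init = (N_prot / N_mRNA) / T_div``.  Protein-per-mRNA datasets are
relative, hence ``k_init = alpha * P / T_div`` with the proportionality
constant ``alpha`` calibrated on the reference gene TIM50 (absolute counts
N_prot = 4095 and N_mRNA = 6 are available for it).

Elongation rate: ribosome occupancy ``occ`` is proportional to the ribosome
line density N_ribo/L, and steady state requires
``k_elong = k_init L / N_ribo``; taking the ratio to the reference gene
cancels the unknown proportionality:
``k_elong/k_elong_ref = (k_init/k_init_ref) * (occ_ref/occ)``, anchored at
``k_elong,TIM50 = 4`` aa/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from . import closed_forms
from .translation import GeneKinetics

__all__ = [
    "GeneMeasurements",
    "Calibration",
    "calibrate",
    "default_calibration",
    "estimate_kinit",
    "estimate_kelong",
    "build_gene_table",
    "DEFAULT_T_DIV",
    "TIM50_N_PROT",
    "TIM50_N_MRNA",
    "TIM50_P",
    "TIM50_K_ELONG",
]

#: effective protein lifetime = typical yeast division time (s)
DEFAULT_T_DIV = 5400.0
#: reference-gene (TIM50) absolute measurements
TIM50_N_PROT = 4095.0
TIM50_N_MRNA = 6.0
TIM50_P = 15.12
TIM50_K_ELONG = 4.0  # aa/s


@dataclass(frozen=True)
class GeneMeasurements:
    """One gene's measurement row.

    P: relative protein-per-mRNA; occ: relative ribosome occupancy
    (arbitrary units, only ratios to the reference gene matter);
    L: transcript length in codons; group: conditional/constitutive/other.
    """

    name: str
    group: str
    P: float
    occ: float
    L: int

    def __post_init__(self):
        if not (self.P > 0):
            raise ValueError(f"{self.name}: P must be positive")
        if not (self.occ > 0):
            raise ValueError(f"{self.name}: occ must be positive")
        if self.L < 1:
            raise ValueError(f"{self.name}: L must be >= 1")


@dataclass(frozen=True)
class Calibration:
    """Reference-gene anchoring of the rate estimates."""

    alpha: float                       # protein-per-mRNA proportionality
    T_div: float = DEFAULT_T_DIV       # effective protein lifetime (s)
    k_init_ref: float = TIM50_N_PROT / TIM50_N_MRNA / DEFAULT_T_DIV
    k_elong_ref: float = TIM50_K_ELONG
    occ_ref: float = 1.0
    P_ref: float = TIM50_P

    def __post_init__(self):
        for name in ("alpha", "T_div", "k_init_ref", "k_elong_ref", "occ_ref",
                     "P_ref"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


def calibrate(
    N_prot: float,
    N_mRNA: float,
    P_ref: float,
    T_div: float = DEFAULT_T_DIV,
    k_elong_ref: float = TIM50_K_ELONG,
    occ_ref: float = 1.0,
) -> Calibration:
    """Anchor the estimators on a gene with absolute protein/mRNA counts.

    ``k_init_ref = (N_prot/N_mRNA)/T_div`` and
    ``alpha = k_init_ref * T_div / P_ref``.  With the TIM50 values
    (4095, 6, 15.12, 5400 s) this gives k_init_ref = 0.1264 1/s and
    alpha = 45.14.
    """
    for name, v in [("N_prot", N_prot), ("N_mRNA", N_mRNA), ("P_ref", P_ref),
                    ("T_div", T_div)]:
        if not (v > 0):
            raise ValueError(f"{name} must be positive")
    k_init_ref = (N_prot / N_mRNA) / T_div
    alpha = k_init_ref * T_div / P_ref
    return Calibration(alpha=alpha, T_div=T_div, k_init_ref=k_init_ref,
                       k_elong_ref=k_elong_ref, occ_ref=occ_ref, P_ref=P_ref)


def default_calibration() -> Calibration:
    """The TIM50 calibration used throughout."""
    return calibrate(TIM50_N_PROT, TIM50_N_MRNA, TIM50_P)


def estimate_kinit(P: float, cal: Calibration) -> float:
    """k_init = alpha * P / T_div (1/s)."""
    if not (P > 0):
        raise ValueError("P must be positive")
    return cal.alpha * P / cal.T_div


def estimate_kelong(k_init: float, occ: float, cal: Calibration) -> float:
    """k_elong = k_elong_ref * (k_init/k_init_ref) * (occ_ref/occ) (aa/s)."""
    if not (k_init > 0):
        raise ValueError("k_init must be positive")
    if not (occ > 0):
        raise ValueError("occ must be positive")
    return cal.k_elong_ref * (k_init / cal.k_init_ref) * (cal.occ_ref / occ)


def measurements_to_kinetics(m: GeneMeasurements, cal: Calibration,
                             l_MTS: int = 100) -> GeneKinetics:
    """Estimate one gene's :class:`GeneKinetics` from its measurements."""
    k_init = estimate_kinit(m.P, cal)
    k_elong = estimate_kelong(k_init, m.occ, cal)
    return GeneKinetics(name=m.name, k_init=k_init, k_elong=k_elong,
                        L=int(m.L), l_MTS=l_MTS)


def build_gene_table(
    measurements: pd.DataFrame,
    cal: Calibration | None = None,
    tau_MTS: float = 40.0,
    l_MTS: int = 100,
    reference: str = "TIM50",
) -> pd.DataFrame:
    """Per-gene kinetics and closed-form predictors from a measurement table.

    ``measurements`` needs columns name, group, P, occ, L.  If the
    reference gene is present in the table its occupancy becomes
    ``occ_ref`` (occupancy units are arbitrary; only the ratio matters).
    Rows failing validation are dropped with a warning naming the error
    rather than aborting the table.  Output columns: name, group, L,
    k_init, k_elong, beta, beta_mature, t_expo, t_expo_mature.
    """
    if cal is None:
        cal = default_calibration()
    required = {"name", "group", "P", "occ", "L"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
    if len(measurements) == 0:
        warnings.warn("empty measurement table", stacklevel=2)
    ref_rows = measurements[measurements["name"] == reference]
    if len(ref_rows):
        cal = replace(cal, occ_ref=float(ref_rows.iloc[0]["occ"]))
    k_MTS = 1.0 / tau_MTS
    rows = []
    for _, r in measurements.iterrows():
        try:
            m = GeneMeasurements(str(r["name"]), str(r["group"]),
                                 float(r["P"]), float(r["occ"]), int(r["L"]))
            gk = measurements_to_kinetics(m, cal, l_MTS=l_MTS)
        except (ValueError, TypeError) as exc:
            warnings.warn(f"dropping row {r['name']!r}: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "name": gk.name,
                "group": m.group,
                "L": gk.L,
                "k_init": gk.k_init,
                "k_elong": gk.k_elong,
                "beta": closed_forms.beta(gk),
                "beta_mature": closed_forms.beta_mature(gk, k_MTS),
                "t_expo": gk.t_expo,
                "t_expo_mature": closed_forms.mature_exposure_time(gk, k_MTS),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "group", "L", "k_init", "k_elong", "beta",
                 "beta_mature", "t_expo", "t_expo_mature"],
    )
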