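"""Synthetic gene cohorts emulating the conditional/constitutive groups.

The generator draws per-gene translation kinetics log-normally around
group medians and *inverts* the rate-estimation relations to produce the
(P, occ) measurement columns, so a cohort pushed through
:func:`mitoloc.rates.build_gene_table` recovers the drawn kinetics exactly.

Group medians default to the typical conditional gene
(L = 393 aa, k_init = 0.3253 1/s, k_elong = 14.5086 aa/s) and typical
constitutive gene (L = 483 aa, k_init = 0.1259 1/s, k_elong = 7.7468 aa/s):
conditional transcripts are shorter and elongate faster, which is the
feature that makes their MTS exposure brief.  Only medians are anchored in
measurements; the log-scale spread (default sigma = 0.4 for all three
parameters) is a fixture choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rates import Calibration, default_calibration

__all__ = [
    "GroupMedians",
    "SyntheticCohortSpec",
    "CONDITIONAL_MEDIANS",
    "CONSTITUTIVE_MEDIANS",
    "generate_synthetic_cohort",
]


@dataclass(frozen=True)
class GroupMedians:
    """Median translation parameters of one gene group."""

    L: float
    k_init: float
    k_elong: float

    def __post_init__(self):
        if min(self.L, self.k_init, self.k_elong) <= 0:
            raise ValueError("medians must be positive")


CONDITIONAL_MEDIANS = GroupMedians(L=393, k_init=0.3253, k_elong=14.5086)
CONSTITUTIVE_MEDIANS = GroupMedians(L=483, k_init=0.1259, k_elong=7.7468)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic two-group cohort."""

    n_conditional: int = 52
    n_constitutive: int = 70
    conditional: GroupMedians = CONDITIONAL_MEDIANS
    constitutive: GroupMedians = CONSTITUTIVE_MEDIANS
    sigma_log: float = 0.4     # log-scale sd for L, k_init, k_elong
    l_MTS: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_conditional < 1 or self.n_constitutive < 1:
            raise ValueError("group sizes must be >= 1")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


def _invert_measurements(k_init, k_elong, cal: Calibration):
    """(P, occ) that the rate estimators map back onto (k_init, k_elong)."""
    P = k_init * cal.T_div / cal.alpha
    occ = cal.occ_ref * (k_init / cal.k_init_ref) * (cal.k_elong_ref / k_elong)
    return P, occ


def generate_synthetic_cohort(
    spec: SyntheticCohortSpec,
    cal: Calibration | None = None,
) -> pd.DataFrame:
    """Synthetic measurement table with columns name, group, P, occ, L.

    Kinetics are log-normal about the group medians (the log-normal median
    equals its scale parameter, so sample medians concentrate on the group
    medians); lengths are rounded to whole codons and floored at
    ``l_MTS + 10`` so every gene completes an MTS.  The drawn ground-truth
    kinetics are attached as ``k_init_true``/``k_elong_true`` columns for
    round-trip validation; downstream consumers ignore them.
    """
    if cal is None:
        cal = default_calibration()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, med, n in [
        ("conditional", spec.conditional, spec.n_conditional),
        ("constitutive", spec.constitutive, spec.n_constitutive),
    ]:
        L = np.maximum(
            np.rint(med.L * np.exp(rng.normal(0.0, spec.sigma_log, n))),
            spec.l_MTS + 10,
        ).astype(int)
        k_init = med.k_init * np.exp(rng.normal(0.0, spec.sigma_log, n))
        k_elong = med.k_elong * np.exp(rng.normal(0.0, spec.sigma_log, n))
        P, occ = _invert_measurements(k_init, k_elong, cal)
        frames.append(
            pd.DataFrame(
                {
                    "name": [f"{group[:4]}_{i:03d}" for i in range(n)],
                    "group": group,
                    "P": P,
                    "occ": occ,
                    "L": L,
                    "k_init_true": k_init,
                    "k_elong_true": k_elong,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
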