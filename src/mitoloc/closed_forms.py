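"""Analytic predictors for MTS-mediated localization.

All expressions neglect ribosome exclusion (valid at low ribosome
occupancy) and assume a deterministic elongation clock for the purposes of
averaging: a ribosome that has completed the MTS at codon ``l_MTS`` keeps
translating for ``t_max = (L - l_MTS)/k_elong`` before terminating.
Maturation of a translated MTS is a Poisson process at rate
``k_MTS = 1/tau_MTS``.
"""

from __future__ import annotations

import math

from .translation import GeneKinetics

__all__ = [
    "beta",
    "beta_mature",
    "mean_wait_time",
    "mature_exposure_time",
    "mature_exposure_time_all_mts",
    "mean_search_time",
]


def beta(gene: GeneKinetics) -> float:
    """Mean steady-state number of fully translated MTSs per mRNA.

    ``beta = k_init (L - l_MTS) / k_elong``: initiation flux times the time
    each nascent chain spends downstream of the MTS-completing codon.
    Returns 0 when the transcript is shorter than the MTS region.
    """
    if gene.L < gene.l_MTS:
        return 0.0
    return gene.k_init * (gene.L - gene.l_MTS) / gene.k_elong


def beta_mature(gene: GeneKinetics, k_MTS: float) -> float:
    """Mean steady-state number of *mature* (binding-competent) MTSs.

    Integrating the maturation probability ``1 - exp(-k_MTS x / k_elong)``
    over codon positions x beyond the MTS region at ribosome line density
    ``k_init/k_elong`` gives

        (k_init/k_elong) * {L - l_MTS
            - (k_elong/k_MTS) [1 - exp(-(k_MTS/k_elong)(L - l_MTS))]}.

    Recovers :func:`beta` as ``k_MTS -> infinity``.
    """
    if k_MTS <= 0:
        raise ValueError("k_MTS must be positive")
    if gene.L < gene.l_MTS:
        return 0.0
    span = gene.L - gene.l_MTS
    x = k_MTS / gene.k_elong * span
    return gene.k_init / gene.k_elong * (
        span - (gene.k_elong / k_MTS) * -math.expm1(-x)
    )


def mean_wait_time(k_MTS: float, t_max: float) -> float:
    """Mean MTS-translation-to-maturity delay, conditioned on maturing.

    Mean of an Exponential(k_MTS) truncated to [0, t_max] (an MTS whose
    ribosome terminates first never matures):

        (1/k_MTS) [1 - e^{-k t_max}(k t_max + 1)] / (1 - e^{-k t_max}).

    Tends to ``t_max/2`` as ``k_MTS -> 0`` and to ``1/k_MTS`` as
    ``k_MTS -> infinity``.
    """
    if k_MTS <= 0 or t_max <= 0:
        raise ValueError("k_MTS and t_max must be positive")
    x = k_MTS * t_max
    if x < 1e-4:
        # series form: the closed expression loses all precision to
        # cancellation when k_MTS*t_max is tiny
        return 0.5 * t_max * (1.0 - x / 6.0)
    num = 1.0 - math.exp(-x) * (x + 1.0)
    den = -math.expm1(-x)
    return num / (k_MTS * den)


def mature_exposure_time(gene: GeneKinetics, k_MTS: float) -> float:
    """Mean binding-competent exposure time of an MTS with maturation.

    The maturing fraction ``1 - e^{-k t_max}`` of translated MTSs times the
    conditional maturation delay :func:`mean_wait_time`:

        (1/k_MTS) [1 - e^{-k_MTS t_max}(k_MTS t_max + 1)],

    with ``t_max = (L - l_MTS)/k_elong``.  This is the primary (default)
    bookkeeping.  Its ``k_MTS -> infinity`` limit is ``1/k_MTS -> 0``,
    i.e. it does *not* recover the instantaneous-model exposure ``t_max``;
    :func:`mature_exposure_time_all_mts` is the alternative bookkeeping
    that does.  The two agree to leading order when ``k_MTS t_max << 1``
    (both ``~ k_MTS t_max^2 / 2``), which is the regime where maturation
    actually limits localization.
    """
    if k_MTS <= 0:
        raise ValueError("k_MTS must be positive")
    if gene.L < gene.l_MTS:
        return 0.0
    t_max = (gene.L - gene.l_MTS) / gene.k_elong
    x = k_MTS * t_max
    if x < 1e-5:  # cancellation guard; leading behaviour k_MTS*t_max^2/2
        return k_MTS * t_max * t_max * (0.5 - x / 3.0)
    return (1.0 - math.exp(-x) * (x + 1.0)) / k_MTS


def mature_exposure_time_all_mts(gene: GeneKinetics, k_MTS: float) -> float:
    """Mean mature-exposure time averaged over all translated MTSs.

    ``t_max - (1/k_MTS)(1 - e^{-k_MTS t_max})``, i.e.
    ``E[max(t_max - T, 0)]`` for maturation delay ``T ~ Exp(k_MTS)``
    (non-maturing MTSs contribute zero exposure).  Its
    ``k_MTS -> infinity`` limit recovers the instantaneous-model exposure
    time ``t_max``.  Secondary, clearly-named alternative to the default
    :func:`mature_exposure_time` bookkeeping.
    """
    if k_MTS <= 0:
        raise ValueError("k_MTS must be positive")
    if gene.L < gene.l_MTS:
        return 0.0
    t_max = (gene.L - gene.l_MTS) / gene.k_elong
    return t_max + math.expm1(-k_MTS * t_max) / k_MTS


def mean_search_time(r1: float, r2: float, D: float) -> float:
    """Mean diffusive search time to an absorbing inner cylinder.

    Area-averaged mean first-passage time of a particle with diffusivity
    ``D`` diffusing in the annulus between an absorbing cylinder of radius
    ``r1`` and a reflecting outer cylinder of radius ``r2``:

        (1/2D) [ r2^4/(r2^2 - r1^2) ln(r2/r1) - (3 r2^2 - r1^2)/4 ].
    """
    if not (0 < r1 < r2):
        raise ValueError("require 0 < r1 < r2")
    if D <= 0:
        raise ValueError("D must be positive")
    r1sq, r2sq = r1 * r1, r2 * r2
    return (
        r2sq * r2sq / (r2sq - r1sq) * math.log(r2 / r1)
        - (3.0 * r2sq - r1sq) / 4.0
    ) / (2.0 * D)
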