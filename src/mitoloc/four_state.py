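"""Four-state model of mRNA localization: exact steady state and limits.

An mRNA is either binding-competent ("sticky", S) or not (U), and either
within binding range of a mitochondrion ("near", N) or not ("far", F).
Switching into/out of competence occurs at rates ``k_S``/``k_U``; spatial
exchange between near and far occurs at rates ``k_R`` (arrive) and ``k_L``
(leave).  A competent mRNA that is near is bound, so the only exit from
S_N is losing competence (no direct S_N -> S_F transition); this broken
detailed balance makes the chain a genuinely non-equilibrium model.

The stationary distribution has a closed form; two limiting regimes
(transport much faster / much slower than competence switching) reduce to
simple expressions in the equilibrium fractions ``f_s = k_S/(k_S+k_U)``
and ``f_d = k_R/(k_R+k_L)``.  A continuous-time Markov-chain simulator is
included as an independent cross-check of the algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FourStateRates",
    "StateDistribution",
    "DegenerateChainError",
    "steady_state",
    "localized_fraction",
    "limit_rapid_transport",
    "limit_slow_transport",
    "generator_matrix",
    "simulate_ctmc",
]

# state order used throughout: S_N, S_F, U_N, U_F
STATE_NAMES = ("S_N", "S_F", "U_N", "U_F")


class DegenerateChainError(ValueError):
    """Raised when a rate combination makes part of the chain absorbing."""


@dataclass(frozen=True)
class FourStateRates:
    """Rates of the four-state localization scheme (all 1/s).

    Parameters
    ----------
    k_S : rate of gaining binding competence (U -> S).
    k_U : rate of losing binding competence (S -> U).
    k_R : rate of reaching the mitochondria-proximal region (F -> N).
    k_L : rate of leaving the proximal region (N -> F, unbound mRNA only).
    """

    k_S: float
    k_U: float
    k_R: float
    k_L: float

    def __post_init__(self):
        for name in ("k_S", "k_U", "k_R", "k_L"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.k_S + self.k_U <= 0:
            raise ValueError("at least one of k_S, k_U must be positive")
        if self.k_R + self.k_L <= 0:
            raise ValueError("at least one of k_R, k_L must be positive")

    @property
    def f_s(self) -> float:
        """Equilibrium competent fraction k_S/(k_S+k_U)."""
        return self.k_S / (self.k_S + self.k_U)

    @property
    def f_d(self) -> float:
        """Equilibrium proximal volume fraction k_R/(k_R+k_L)."""
        return self.k_R / (self.k_R + self.k_L)


@dataclass(frozen=True)
class StateDistribution:
    """Stationary probabilities of the four states."""

    p_SN: float
    p_SF: float
    p_UN: float
    p_UF: float
    Z: float  # normalizer of the unnormalized steady-state weights

    def __post_init__(self):
        probs = self.as_array()
        if np.any(probs < -1e-15) or np.any(probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_SN, self.p_SF, self.p_UN, self.p_UF])

    @property
    def localized(self) -> float:
        """Probability of being in the proximal ('near') region."""
        return self.p_SN + self.p_UN


def generator_matrix(rates: FourStateRates) -> np.ndarray:
    """Infinitesimal generator Q (rows = from-state) of the scheme.

    Transitions: U_F -k_S-> S_F, U_N -k_S-> S_N, S_F -k_U-> U_F,
    S_N -k_U-> U_N, S_F -k_R-> S_N, U_F -k_R-> U_N, U_N -k_L-> U_F.
    There is no S_N -> S_F transition (bound mRNA cannot leave).
    """
    kS, kU, kR, kL = rates.k_S, rates.k_U, rates.k_R, rates.k_L
    Q = np.zeros((4, 4))
    # S_N (0): lose competence
    Q[0, 2] = kU
    # S_F (1): reach mitochondria (binds), or lose competence
    Q[1, 0] = kR
    Q[1, 3] = kU
    # U_N (2): gain competence (binds in place), or leave region
    Q[2, 0] = kS
    Q[2, 3] = kL
    # U_F (3): gain competence, or reach region
    Q[3, 1] = kS
    Q[3, 2] = kR
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def steady_state(rates: FourStateRates) -> StateDistribution:
    """Exact stationary distribution of the four-state scheme.

    Uses the closed-form solution of the master equation.  Requires
    ``k_U > 0`` and ``k_L > 0``: with ``k_U = 0`` the bound state S_N is
    absorbing and with ``k_L = 0`` the near states absorb all probability,
    in which case the expression below divides by zero.  Use the
    ``limit_*`` functions for those limits.
    """
    kS, kU, kR, kL = rates.k_S, rates.k_U, rates.k_R, rates.k_L
    if kU <= 0:
        raise DegenerateChainError(
            "k_U = 0 makes the bound state S_N absorbing (localized fraction -> 1)"
        )
    if kL <= 0:
        raise DegenerateChainError(
            "k_L = 0 makes the proximal region absorbing (localized fraction -> 1)"
        )
    s_n = kR * kS * (kL + kR + kS + kU) / (kL * kU * (kR + kU))
    s_f = kS / (kR + kU)
    u_n = kR * (kR + kS + kU) / (kL * (kR + kU))
    u_f = 1.0
    Z = (kS + kU) * (kL * (kR + kU) + kR * (kR + kS + kU)) / (kU * kL * (kU + kR))
    return StateDistribution(s_n / Z, s_f / Z, u_n / Z, u_f / Z, Z)


def localized_fraction(rates: FourStateRates) -> float:
    """Steady-state probability of residing in the proximal region."""
    return steady_state(rates).localized


def _check_fraction(x: float, name: str) -> float:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return float(x)


def limit_rapid_transport(f_s: float, f_d: float) -> float:
    """Localized fraction when transport is much faster than switching.

    Incompetent mRNA equilibrate spatially before switching, so
    ``f_loc = f_s + (1 - f_s) f_d``.
    """
    f_s = _check_fraction(f_s, "f_s")
    f_d = _check_fraction(f_d, "f_d")
    return f_s + (1.0 - f_s) * f_d


def limit_slow_transport(f_s: float, f_d: float) -> float:
    """Localized fraction when transport is much slower than switching.

    ``f_loc = 1 / (1 + (1-f_s)(1-f_d)/f_d)``.  As ``f_d -> 0`` with
    ``f_s < 1`` the localization probability goes to zero; the case
    ``f_d = 0`` returns that documented limit.
    """
    f_s = _check_fraction(f_s, "f_s")
    f_d = _check_fraction(f_d, "f_d")
    if f_d == 0.0:
        return 1.0 if f_s == 1.0 else 0.0
    return 1.0 / (1.0 + (1.0 - f_s) * (1.0 - f_d) / f_d)


def simulate_ctmc(
    rates: FourStateRates, duration: float, seed: int
) -> np.ndarray:
    """Occupancy fractions from one long CTMC trajectory started in U_F.

    Returns the fraction of ``duration`` spent in each state, ordered
    (S_N, S_F, U_N, U_F).  Serves as an independent stochastic oracle for
    :func:`steady_state`; steady-state occupancies do not depend on the
    initial condition.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    Q = generator_matrix(rates)
    rng = np.random.default_rng(seed)
    out_rates = -np.diag(Q)
    # jump probabilities, guarded for states with zero exit rate
    P = np.zeros_like(Q)
    for i in range(4):
        if out_rates[i] > 0:
            P[i] = Q[i] / out_rates[i]
            P[i, i] = 0.0
    occupancy = np.zeros(4)
    state = 3  # U_F
    t = 0.0
    while t < duration:
        if out_rates[state] == 0.0:  # absorbing
            occupancy[state] += duration - t
            break
        dwell = rng.exponential(1.0 / out_rates[state])
        occupancy[state] += min(dwell, duration - t)
        t += dwell
        if t < duration:
            state = rng.choice(4, p=P[state])
    return occupancy / duration
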