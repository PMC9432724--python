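"""First-passage sampling for radial diffusion in concentric cylinders.

The cytosol around a mitochondrial tubule is modelled as nested cylinders
(cross-sectional radii in micrometres):

* region 1, ``r_m < r < r_a``  — close enough for a competent mRNA to bind;
* region 2, ``r_a < r < r_b``  — appears mitochondrial in diffraction-limited
  imaging but cannot bind;
* region 3, ``r_b < r < R_out`` — bulk cytosol, reflecting outer wall.

``R_out`` encodes the mitochondrial volume fraction: it is the typical
half-separation between tubules of the network, not the cell radius.

Instead of fixed-step Brownian dynamics, transitions between regions are
sampled with an event-driven propagator: each region is an annulus with a
mixed absorbing/reflecting boundary condition, a small buffer ``eps`` is
added past each interface so the next region is entered a finite distance
from its own boundary (preventing vanishing time steps), and the exact
first-passage time (and, where two boundaries absorb, the exit side) is
drawn from the spectral (Bessel-eigenfunction) expansion of the radial
diffusion Green's function.  The axial coordinate never matters: region
membership is purely radial, so the problem is two-dimensional radial
diffusion in the cross-sectional plane.

A fixed-step Euler--Maruyama integrator of the radial SDE
``dr = (D/r) dt + sqrt(2D) dW`` is provided as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.special import erfinv, j0, j1, y0, y1

__all__ = [
    "CylinderGeometry",
    "GeometryError",
    "geometry_from_mvf",
    "RegionPropagators",
    "get_propagators",
    "sample_region1_exit",
    "sample_region2_transit",
    "sample_region3_return",
    "sample_unbinding_position",
    "splitting_probability_inner",
    "sde_first_passage",
]


class GeometryError(ValueError):
    """Raised for geometrically inadmissible parameter combinations."""


@dataclass(frozen=True)
class CylinderGeometry:
    """Concentric-cylinder geometry and transport parameters.

    Lengths in micrometres, diffusivity in um^2/s.  ``f_m`` is the
    *reported* mitochondrial volume fraction; only ``accessible_fraction``
    (default 0.8) of the cell volume is available to mitochondria and
    cytosol, so the simulated volume fraction is ``f_m/accessible_fraction``
    and ``R_out = r_m / sqrt(f_m / accessible_fraction)``.
    """

    r_m: float = 0.350          # mitochondrial tubule radius
    r_a: float = 0.375          # binding range: r_m + 25 nm
    r_b: float = 0.600          # imaging range: r_m + 250 nm
    R_out: float = 1.5652475842498528   # outer reflecting wall (f_m = 0.04)
    eps: float = 0.010          # boundary buffer
    D: float = 0.1              # mRNA diffusivity
    f_m: float = 0.04           # reported mitochondrial volume fraction
    accessible_fraction: float = 0.8
    V_cell: float = 42.0        # reference cell volume (um^3), informational

    def __post_init__(self):
        if not (0 < self.r_m < self.r_a < self.r_b < self.R_out):
            raise GeometryError(
                "radii must satisfy 0 < r_m < r_a < r_b < R_out, got "
                f"r_m={self.r_m}, r_a={self.r_a}, r_b={self.r_b}, R_out={self.R_out}"
            )
        if self.eps <= 0:
            raise GeometryError("eps must be positive")
        for gap, name in [
            (self.r_a - self.r_m, "r_a - r_m"),
            (self.r_b - self.r_a, "r_b - r_a"),
            (self.R_out - self.r_b, "R_out - r_b"),
        ]:
            if self.eps >= gap:
                raise GeometryError(f"eps={self.eps} must be smaller than {name}={gap}")
        if self.D <= 0:
            raise GeometryError("D must be positive")

    @property
    def annular_areas(self) -> np.ndarray:
        """Cross-sectional areas of regions 1..3 (unbound-accessible annuli)."""
        return np.pi * np.array(
            [
                self.r_a**2 - self.r_m**2,
                self.r_b**2 - self.r_a**2,
                self.R_out**2 - self.r_b**2,
            ]
        )

    @property
    def area_fractions(self) -> np.ndarray:
        """Equilibrium (uniform-measure) occupancy of regions 1..3."""
        a = self.annular_areas
        return a / a.sum()


def geometry_from_mvf(f_m: float, **overrides) -> CylinderGeometry:
    """Geometry whose outer wall realizes a reported volume fraction f_m.

    ``R_out = r_m / sqrt(f_m / accessible_fraction)``.  Raises
    :class:`GeometryError` when f_m is so large that region 3 vanishes
    (R_out must exceed r_b + eps).
    """
    base = dict(
        r_m=0.350, eps=0.010, D=0.1, accessible_fraction=0.8, V_cell=42.0
    )
    base.update({k: v for k, v in overrides.items() if k not in ("r_a", "r_b")})
    r_m = base["r_m"]
    r_a = overrides.get("r_a", r_m + 0.025)
    r_b = overrides.get("r_b", r_m + 0.250)
    acc = base["accessible_fraction"]
    if f_m <= 0:
        raise GeometryError("f_m must be positive")
    sim_vf = f_m / acc
    f_max = acc * (r_m / (r_b + base["eps"])) ** 2
    if sim_vf >= (r_m / (r_b + base["eps"])) ** 2:
        raise GeometryError(
            f"f_m={f_m} leaves no region 3: require f_m < "
            f"accessible_fraction*(r_m/(r_b+eps))^2 = {f_max:.4f}"
        )
    R_out = r_m / math.sqrt(sim_vf)
    return CylinderGeometry(r_m=r_m, r_a=r_a, r_b=r_b, R_out=R_out,
                            f_m=f_m, **{k: base[k] for k in
                                        ("eps", "D", "accessible_fraction", "V_cell")})


# --------------------------------------------------------------------------
# spectral machinery for one annulus
# --------------------------------------------------------------------------

@njit(cache=True)
def _series_eval(lam2D: np.ndarray, coef: np.ndarray, t: float) -> float:
    """Evaluate sum_n coef_n exp(-lam2D_n t); modes sorted ascending."""
    s = 0.0
    for n in range(lam2D.size):
        x = lam2D[n] * t
        if x > 40.0:
            break
        s += coef[n] * math.exp(-x)
    return s


@njit(cache=True)
def _invert_survival(
    lam2D: np.ndarray, coef: np.ndarray, U: float, t_floor: float
) -> float:
    """Solve S(t) = U for t >= t_floor by log-space bisection.

    Assumes S(t_floor) >= U and S monotone decreasing; inversion to
    1e-9 relative tolerance in t.
    """
    t_lo = t_floor
    t_hi = max(4.0 * t_floor, 1.0 / lam2D[0])
    while _series_eval(lam2D, coef, t_hi) > U:
        t_hi *= 4.0
    for _ in range(200):
        t_mid = math.sqrt(t_lo * t_hi)
        if _series_eval(lam2D, coef, t_mid) > U:
            t_lo = t_mid
        else:
            t_hi = t_mid
        if t_hi - t_lo < 1e-9 * t_hi:
            break
    return 0.5 * (t_lo + t_hi)


class _AnnulusModes:
    """Eigenmodes of radial diffusion on [r_in, r_out] with mixed BCs.

    Eigenfunctions are cylinder-function combinations of order 0 anchored
    at an absorbing boundary; eigenvalues found by bracketing sign changes
    of the remaining boundary condition and polishing with Brent's method.
    """

    def __init__(self, r_in: float, r_out: float, D: float,
                 bc_in: str, bc_out: str, n_modes: int = 220):
        if bc_in not in ("absorbing", "reflecting") or bc_out not in (
            "absorbing", "reflecting"
        ):
            raise ValueError("boundary conditions must be absorbing/reflecting")
        if bc_in == "reflecting" and bc_out == "reflecting":
            raise ValueError("at least one boundary must absorb")
        self.r_in, self.r_out, self.D = r_in, r_out, D
        self.bc_in, self.bc_out = bc_in, bc_out
        # anchor the eigenfunction at an absorbing boundary so u(anchor)=0
        self.anchor = r_in if bc_in == "absorbing" else r_out

        def u(lam, r):
            return j0(lam * r) * y0(lam * self.anchor) - y0(lam * r) * j0(
                lam * self.anchor
            )

        def v(lam, r):  # order-1 partner; u'(r) = -lam * v(r)
            return j1(lam * r) * y0(lam * self.anchor) - y1(lam * r) * j0(
                lam * self.anchor
            )

        self._u, self._v = u, v
        if bc_in == "absorbing" and bc_out == "absorbing":
            cond = lambda lam: u(lam, r_out)
        elif bc_in == "absorbing":  # reflecting outer
            cond = lambda lam: v(lam, r_out)
        else:  # reflecting inner, absorbing outer
            cond = lambda lam: v(lam, r_in)

        width = r_out - r_in
        spacing = math.pi / width
        grid = np.arange(spacing / 64.0, (n_modes + 2) * spacing, spacing / 16.0)
        vals = cond(grid)
        sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        lams = []
        for i in sign_change[: n_modes]:
            lams.append(brentq(cond, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-14))
        if len(lams) < n_modes:
            raise RuntimeError("eigenvalue bracketing found too few modes")
        self.lam = np.array(lams)
        self.lam2D = D * self.lam**2
        # mode norms and integrals (closed forms for cylinder functions)
        u_in, u_out = u(self.lam, r_in), u(self.lam, r_out)
        v_in, v_out = v(self.lam, r_in), v(self.lam, r_out)
        self.M = (r_out * v_out - r_in * v_in) / self.lam
        self.N = 0.5 * (
            r_out**2 * (u_out**2 + v_out**2) - r_in**2 * (u_in**2 + v_in**2)
        )
        # u'(boundary) for exit-flux (splitting) series
        self.uprime_in = -self.lam * v_in
        self.uprime_out = -self.lam * v_out
        # time below which the truncated series is unresolved
        self.t_floor = 8.0 / self.lam2D[-1]

    def u_at(self, r0: float) -> np.ndarray:
        return self._u(self.lam, r0)

    def survival_coefs(self, r0: float) -> np.ndarray:
        """Coefficients of S(t|r0); normalized so S(0) = 1."""
        c = self.M / self.N * self.u_at(r0)
        return c / c.sum()

    def exit_flux_weights(self, r0: float) -> tuple[np.ndarray, np.ndarray]:
        """Unnormalized per-mode exit weights (inner, outer boundary).

        Each array sums to the corresponding splitting probability (up to
        series truncation); normalizing one of them gives the coefficients
        of the exit-time survival function conditioned on that side.
        """
        ur0 = self.u_at(r0)
        w_in = self.r_in * self.uprime_in * ur0 / (self.N * self.lam**2)
        w_out = -self.r_out * self.uprime_out * ur0 / (self.N * self.lam**2)
        return w_in, w_out

    def survival(self, t, r0: float) -> np.ndarray:
        """Survival probability S(t | r0) (vectorized over t)."""
        c = self.survival_coefs(r0)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.array([_series_eval(self.lam2D, c, ti) for ti in t])
        return np.clip(out, 0.0, 1.0)

    def sample_fpt(self, coefs: np.ndarray, d_near: float, p_side: float,
                   rng: np.random.Generator) -> float:
        """Draw one passage time from a (possibly conditional) survival series.

        ``d_near`` is the distance from the start to the relevant absorbing
        boundary and ``p_side`` the probability of exiting there; both feed
        the flat-wall (half-space) fallback used for times too short for
        the truncated series to resolve:  S_tot(t) ~ erf(d/sqrt(4Dt)).
        """
        U = rng.random()
        s_floor = _series_eval(self.lam2D, coefs, self.t_floor)
        if U >= s_floor:
            z = 1.0 - p_side * (1.0 - U)
            z = min(z, 1.0 - 1e-16)
            x = float(erfinv(z))
            if x <= 0.0:
                return self.t_floor
            return min(d_near**2 / (4.0 * self.D * x * x), self.t_floor)
        return _invert_survival(self.lam2D, coefs, U, self.t_floor)


def splitting_probability_inner(r_in_abs: float, r_out_abs: float, r0: float) -> float:
    """P(exit at inner absorber | start r0) for 2-D radial diffusion.

    The harmonic measure in an annulus is logarithmic:
    ``ln(r_out/r0) / ln(r_out/r_in)``.
    """
    if not (r_in_abs <= r0 <= r_out_abs):
        raise ValueError("r0 must lie between the absorbing radii")
    return math.log(r_out_abs / r0) / math.log(r_out_abs / r_in_abs)


class RegionPropagators:
    """Exact region-transition samplers for one geometry.

    Eigenvalues, norms and the coefficient vectors for the canonical entry
    points are computed once per geometry and cached; arbitrary start radii
    (after unbinding) cost one Bessel evaluation per mode.
    """

    def __init__(self, geom: CylinderGeometry, n_modes: int = 220):
        g, e = geom, geom.eps
        self.geom = geom
        # region 1: reflecting mitochondrial wall, absorbed just inside region 2
        self.m1 = _AnnulusModes(g.r_m, g.r_a + e, g.D, "reflecting", "absorbing",
                                n_modes)
        # region 2: absorbed just inside region 1 / just inside region 3
        self.m2 = _AnnulusModes(g.r_a - e, g.r_b + e, g.D, "absorbing", "absorbing",
                                n_modes)
        # region 3: absorbed just inside region 2, reflecting outer wall
        self.m3 = _AnnulusModes(g.r_b - e, g.R_out, g.D, "absorbing", "reflecting",
                                n_modes)
        # canonical starts
        self._c1_entry = self.m1.survival_coefs(g.r_a - e)
        self._c2_from1 = self.m2.exit_flux_weights(g.r_a + e)
        self._c2_from3 = self.m2.exit_flux_weights(g.r_b - e)
        self._c3_inner = self.m3.survival_coefs(g.r_b + e)
        self._c3_wall = self.m3.survival_coefs(g.R_out)

    # -- region 1 ----------------------------------------------------------
    def sample_region1_exit(self, rng: np.random.Generator,
                            r0: float | None = None) -> float:
        """First-passage time from r0 (default entry point r_a - eps) to
        the absorber at r_a + eps, reflecting at the mitochondrial wall."""
        g = self.geom
        if r0 is None:
            coefs = self._c1_entry
            d = (g.r_a + g.eps) - (g.r_a - g.eps)
        else:
            if not (g.r_m <= r0 < g.r_a + g.eps):
                raise ValueError("r0 outside region 1 domain")
            coefs = self.m1.survival_coefs(r0)
            d = (g.r_a + g.eps) - r0
        return self.m1.sample_fpt(coefs, d, 1.0, rng)

    # -- region 2 ----------------------------------------------------------
    def splitting_inner(self, entry_side: Literal["inner", "outer"]) -> float:
        g = self.geom
        r0 = g.r_a + g.eps if entry_side == "inner" else g.r_b - g.eps
        return splitting_probability_inner(g.r_a - g.eps, g.r_b + g.eps, r0)

    def sample_region2_transit(
        self, entry_side: Literal["inner", "outer"], rng: np.random.Generator
    ) -> tuple[str, float]:
        """Exit side ('inner' -> region 1, 'outer' -> region 3) and time."""
        if entry_side not in ("inner", "outer"):
            raise ValueError("entry_side must be 'inner' or 'outer'")
        g = self.geom
        w_in, w_out = self._c2_from1 if entry_side == "inner" else self._c2_from3
        p_inner = self.splitting_inner(entry_side)
        r0 = g.r_a + g.eps if entry_side == "inner" else g.r_b - g.eps
        if rng.random() < p_inner:
            side, w, p = "inner", w_in, p_inner
            d = r0 - (g.r_a - g.eps)
        else:
            side, w, p = "outer", w_out, 1.0 - p_inner
            d = (g.r_b + g.eps) - r0
        coefs = w / w.sum()
        return side, self.m2.sample_fpt(coefs, d, p, rng)

    # -- region 3 ----------------------------------------------------------
    def sample_region3_return(
        self,
        rng: np.random.Generator,
        start: Literal["inner_edge", "outer_wall"] = "inner_edge",
        r0: float | None = None,
    ) -> float:
        """First-passage time to the absorber at r_b - eps.

        ``start='inner_edge'`` begins at r_b + eps (entry from region 2);
        ``start='outer_wall'`` begins at R_out (nuclear export).  An
        explicit ``r0`` overrides both.
        """
        g = self.geom
        if r0 is not None:
            if not (g.r_b - g.eps < r0 <= g.R_out):
                raise ValueError("r0 outside region 3 domain")
            coefs = self.m3.survival_coefs(r0)
            d = r0 - (g.r_b - g.eps)
        elif start == "inner_edge":
            coefs, d = self._c3_inner, 2 * g.eps
        elif start == "outer_wall":
            coefs, d = self._c3_wall, g.R_out - (g.r_b - g.eps)
        else:
            raise ValueError("start must be 'inner_edge' or 'outer_wall'")
        return self.m3.sample_fpt(coefs, d, 1.0, rng)

    # -- unbinding ---------------------------------------------------------
    def sample_unbinding_position(self, rng: np.random.Generator) -> float:
        """Radius with density proportional to r on [r_m, r_a].

        Inverse-CDF sampling of (r^2 - r_m^2)/(r_a^2 - r_m^2): a detached
        mRNA re-appears uniformly over the binding-shell cross-section.
        """
        g = self.geom
        u = rng.random()
        return math.sqrt(g.r_m**2 + u * (g.r_a**2 - g.r_m**2))


_PROPAGATOR_CACHE: dict[tuple, RegionPropagators] = {}


def get_propagators(geom: CylinderGeometry, n_modes: int = 220) -> RegionPropagators:
    """Cached :class:`RegionPropagators` for a geometry (modes are reusable)."""
    key = (geom, n_modes)
    if key not in _PROPAGATOR_CACHE:
        _PROPAGATOR_CACHE[key] = RegionPropagators(geom, n_modes)
    return _PROPAGATOR_CACHE[key]


# module-level convenience wrappers matching the operation names -----------

def sample_region1_exit(geom: CylinderGeometry, rng: np.random.Generator,
                        r0: float | None = None) -> float:
    return get_propagators(geom).sample_region1_exit(rng, r0)


def sample_region2_transit(geom: CylinderGeometry, entry_side: str,
                           rng: np.random.Generator) -> tuple[str, float]:
    return get_propagators(geom).sample_region2_transit(entry_side, rng)


def sample_region3_return(geom: CylinderGeometry, start: str,
                          rng: np.random.Generator) -> float:
    return get_propagators(geom).sample_region3_return(rng, start)


def sample_unbinding_position(geom: CylinderGeometry,
                              rng: np.random.Generator) -> float:
    return get_propagators(geom).sample_unbinding_position(rng)


# --------------------------------------------------------------------------
# fixed-step SDE oracle
# --------------------------------------------------------------------------

def sde_first_passage(
    r0: float,
    r_lo: float,
    r_hi: float,
    bc_lo: Literal["absorbing", "reflecting"],
    bc_hi: Literal["absorbing", "reflecting"],
    D: float,
    dt: float,
    n_samples: int,
    rng: np.random.Generator,
    max_steps: int = 50_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler--Maruyama first-passage sampler for 2-D radial diffusion.

    Integrates ``dr = (D/r) dt + sqrt(2D) dW`` from ``r0`` until a boundary
    absorbs the walker; reflecting boundaries mirror the position.  Returns
    ``(times, sides)`` with side -1 for the lower and +1 for the upper
    boundary.  This is the slow, assumption-light arbiter against which the
    spectral propagator is validated; the discretization bias is O(sqrt(dt)).
    """
    if bc_lo == "reflecting" and bc_hi == "reflecting":
        raise ValueError("at least one boundary must absorb")
    r = np.full(n_samples, float(r0))
    t = np.zeros(n_samples)
    out_t = np.empty(n_samples)
    out_side = np.empty(n_samples, dtype=np.int8)
    alive = np.arange(n_samples)
    sq = math.sqrt(2.0 * D * dt)
    work = 0
    while alive.size and work < max_steps:
        work += alive.size
        r[alive] += D / r[alive] * dt + sq * rng.standard_normal(alive.size)
        t[alive] += dt
        ra = r[alive]
        hit_lo = ra <= r_lo
        hit_hi = ra >= r_hi
        if bc_lo == "reflecting":
            r[alive[hit_lo]] = 2 * r_lo - ra[hit_lo]
            hit_lo[:] = False
        if bc_hi == "reflecting":
            r[alive[hit_hi]] = 2 * r_hi - ra[hit_hi]
            hit_hi[:] = False
        done = hit_lo | hit_hi
        if done.any():
            idx = alive[done]
            out_t[idx] = t[idx]
            out_side[idx] = np.where(hit_lo[done], -1, 1)
            alive = alive[~done]
    if alive.size:
        raise RuntimeError("SDE oracle exceeded max_steps before absorption")
    return out_t, out_side
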