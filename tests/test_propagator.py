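"""Spectral first-passage samplers validated against SDE and closed forms."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from mitoloc.closed_forms import mean_search_time
from mitoloc.propagator import (
    CylinderGeometry,
    GeometryError,
    RegionPropagators,
    geometry_from_mvf,
    get_propagators,
    sde_first_passage,
    splitting_probability_inner,
)

from conftest import mean_and_se


def region1_mean_exit_exact(geom, r0):
    """Closed-form mean first-passage time in the region-1 annulus
    (reflecting at r_m, absorbing at r_a + eps) from radius r0."""
    rc, rm = geom.r_a + geom.eps, geom.r_m
    return ((rc**2 - r0**2) / 2 - rm**2 * math.log(rc / r0)) / (2 * geom.D)


def test_geometry_from_mvf_outer_radius():
    assert geometry_from_mvf(0.04).R_out == pytest.approx(1.5652, abs=1e-4)
    assert geometry_from_mvf(0.01).R_out == pytest.approx(3.1305, abs=1e-4)


def test_geometry_inadmissible_mvf_raises():
    # f_m at which region 3 vanishes
    with pytest.raises(GeometryError, match="region 3"):
        geometry_from_mvf(0.8 * (0.350 / 0.600) ** 2)
    with pytest.raises(GeometryError):
        geometry_from_mvf(-0.01)
    with pytest.raises(GeometryError):
        CylinderGeometry(r_m=0.4, r_a=0.3, r_b=0.6, R_out=1.5)
    with pytest.raises(GeometryError):
        CylinderGeometry(eps=0.05)  # exceeds the r_a - r_m gap


def test_survival_functions_normalized(geom_4pct):
    """S(t -> 0) -> 1 and S decreases monotonically for every region."""
    P = get_propagators(geom_4pct)
    checks = [
        (P.m1, geom_4pct.r_a - geom_4pct.eps),
        (P.m2, geom_4pct.r_a + geom_4pct.eps),
        (P.m3, geom_4pct.r_b + geom_4pct.eps),
        (P.m3, geom_4pct.R_out),
    ]
    for modes, r0 in checks:
        ts = np.geomspace(modes.t_floor, 50 / modes.lam2D[0], 30)
        s = modes.survival(ts, r0)
        assert s[0] > 0.97
        assert np.all(np.diff(s) <= 1e-9)
        assert s[-1] < 0.05


def test_region1_exit_time_matches_exact_mean(geom_4pct, rng):
    P = get_propagators(geom_4pct)
    samples = np.array([P.sample_region1_exit(rng) for _ in range(15000)])
    assert np.all(samples > 0)
    mean, se = samples.mean(), samples.std(ddof=1) / math.sqrt(samples.size)
    exact = region1_mean_exit_exact(geom_4pct, geom_4pct.r_a - geom_4pct.eps)
    assert abs(mean - exact) <= 3 * se


def test_region1_exit_time_matches_sde_oracle(geom_4pct, rng):
    """Spectral sampler vs Euler--Maruyama radial diffusion, 3 SE."""
    P = get_propagators(geom_4pct)
    prop = np.array([P.sample_region1_exit(rng) for _ in range(15000)])
    sde, _ = sde_first_passage(
        geom_4pct.r_a - geom_4pct.eps, geom_4pct.r_m, geom_4pct.r_a + geom_4pct.eps,
        "reflecting", "absorbing", geom_4pct.D, 1e-6, 2500, rng,
    )
    se = math.hypot(prop.std(ddof=1) / math.sqrt(prop.size),
                    sde.std(ddof=1) / math.sqrt(sde.size))
    assert abs(prop.mean() - sde.mean()) <= 3 * se


def test_region1_exit_shrinks_with_eps(geom_4pct):
    """A nearer absorber (smaller eps) gives a shorter mean exit time."""
    means = []
    for eps in (0.002, 0.005, 0.010):
        g = geometry_from_mvf(0.04, eps=eps)
        P = RegionPropagators(g)
        c = P.m1.survival_coefs(g.r_a - eps)
        means.append(float(np.sum(c / P.m1.lam2D)))  # E[T] = integral of S
    assert means[0] < means[1] < means[2]


def test_region1_exit_from_unbinding_radius(geom_4pct, rng):
    P = get_propagators(geom_4pct)
    r0 = 0.36
    samples = np.array([P.sample_region1_exit(rng, r0) for _ in range(8000)])
    mean, se = samples.mean(), samples.std(ddof=1) / math.sqrt(samples.size)
    assert abs(mean - region1_mean_exit_exact(geom_4pct, r0)) <= 3 * se


def test_splitting_probability_formula(geom_4pct):
    # entry from region 1 with default radii: P(inner) ~ 0.8962
    p = splitting_probability_inner(0.365, 0.610, 0.385)
    assert p == pytest.approx(0.8962, abs=1e-4)
    # log-midpoint start splits 50/50
    mid = math.sqrt(0.365 * 0.610)
    assert splitting_probability_inner(0.365, 0.610, mid) == pytest.approx(0.5)
    P = get_propagators(geom_4pct)
    assert P.splitting_inner("inner") == pytest.approx(p, abs=1e-12)
    # spectral exit weights reproduce the splitting probability
    w_in, w_out = P.m2.exit_flux_weights(geom_4pct.r_a + geom_4pct.eps)
    assert w_in.sum() / (w_in.sum() + w_out.sum()) == pytest.approx(p, abs=2e-3)


def test_region2_transit_matches_sde_oracle(geom_4pct, rng):
    """Exit sides and side-conditioned mean transit times vs the SDE."""
    P = get_propagators(geom_4pct)
    sides, times = [], []
    for _ in range(20000):
        s, t = P.sample_region2_transit("inner", rng)
        sides.append(s)
        times.append(t)
    sides, times = np.array(sides), np.array(times)
    p_emp = (sides == "inner").mean()
    p_exact = P.splitting_inner("inner")
    assert abs(p_emp - p_exact) <= 3 * math.sqrt(p_exact * (1 - p_exact) / sides.size)

    sde_t, sde_side = sde_first_passage(
        geom_4pct.r_a + geom_4pct.eps, geom_4pct.r_a - geom_4pct.eps,
        geom_4pct.r_b + geom_4pct.eps, "absorbing", "absorbing",
        geom_4pct.D, 1e-5, 3000, rng,
    )
    for side_label, sde_mask in (("inner", sde_side == -1), ("outer", sde_side == 1)):
        a = times[sides == side_label]
        b = sde_t[sde_mask]
        se = math.hypot(a.std(ddof=1) / math.sqrt(a.size),
                        b.std(ddof=1) / math.sqrt(b.size))
        assert abs(a.mean() - b.mean()) <= 3 * se


@pytest.mark.parametrize("f_m", [0.01, 0.04, 0.15])
def test_region3_area_averaged_mfpt_matches_search_time(f_m, rng):
    """Mean return time from an area-uniform start equals the closed-form
    diffusive search time for the same annulus."""
    g = geometry_from_mvf(f_m)
    P = get_propagators(g)
    r1, r2 = g.r_b - g.eps, g.R_out
    samples = []
    for _ in range(4000):
        r0 = math.sqrt(r1**2 + rng.random() * (r2**2 - r1**2))
        samples.append(P.sample_region3_return(rng, r0=min(r0, r2)))
    mean, se = mean_and_se(samples)
    assert abs(mean - mean_search_time(r1, r2, g.D)) <= 3 * se


def test_region3_start_monotonicity(geom_4pct, rng):
    P = get_propagators(geom_4pct)
    inner = np.array([P.sample_region3_return(rng, "inner_edge") for _ in range(4000)])
    outer = np.array([P.sample_region3_return(rng, "outer_wall") for _ in range(4000)])
    assert np.all(inner > 0) and np.all(outer > 0)
    assert outer.mean() > inner.mean()


def test_sampler_consistent_with_own_survival(geom_4pct, rng):
    """Empirical survival of drawn times matches the spectral series at ten
    checkpoints (binomial 3 SE)."""
    P = get_propagators(geom_4pct)
    n = 10000
    samples = np.array([P.sample_region3_return(rng, "inner_edge") for _ in range(n)])
    checkpoints = np.quantile(samples, np.linspace(0.05, 0.95, 10))
    s_emp = np.array([(samples > c).mean() for c in checkpoints])
    s_series = P.m3.survival(checkpoints, geom_4pct.r_b + geom_4pct.eps)
    se = np.sqrt(s_series * (1 - s_series) / n)
    assert np.all(np.abs(s_emp - s_series) <= 3 * se + 1e-3)


def test_unbinding_position_distribution(geom_4pct, rng):
    """Radius density proportional to r on [r_m, r_a]: moment + KS test."""
    P = get_propagators(geom_4pct)
    samples = np.array([P.sample_unbinding_position(rng) for _ in range(30000)])
    assert np.all((samples >= geom_4pct.r_m) & (samples <= geom_4pct.r_a))
    rm, ra = geom_4pct.r_m, geom_4pct.r_a
    expected = 2 / 3 * (ra**3 - rm**3) / (ra**2 - rm**2)
    assert expected == pytest.approx(0.36265, abs=2e-5)
    se = samples.std(ddof=1) / math.sqrt(samples.size)
    assert abs(samples.mean() - expected) <= 3 * se
    cdf = lambda r: (r**2 - rm**2) / (ra**2 - rm**2)
    assert kstest(samples, cdf).pvalue > 0.01


def test_pure_diffusion_region_occupancy(geom_4pct, rng):
    """A never-binding walker pushed through the region machinery occupies
    each region in proportion to its annular area (detailed balance of the
    propagator scheme)."""
    P = get_propagators(geom_4pct)
    frac1 = geom_4pct.area_fractions[0]
    assert frac1 == pytest.approx(0.0077876, abs=1e-5)
    shares = []
    for rep in range(10):
        t_r = np.zeros(3)
        region, start, t = 3, "outer_wall", 0.0
        horizon = 3000.0
        while t < horizon:
            if region == 1:
                dt = P.sample_region1_exit(rng)
                nxt, entry = 2, "inner"
            elif region == 2:
                side, dt = P.sample_region2_transit(entry, rng)
                nxt = 1 if side == "inner" else 3
                start = "inner_edge"
            else:
                dt = P.sample_region3_return(rng, start)
                nxt, entry = 2, "outer"
            dt = min(dt, horizon - t)
            t_r[region - 1] += dt
            t += dt
            region = nxt
        shares.append(t_r / t_r.sum())
    mean = np.mean(shares, axis=0)
    se = np.std(shares, axis=0, ddof=1) / math.sqrt(len(shares))
    assert np.all(np.abs(mean - geom_4pct.area_fractions) <= 3 * se + 5e-4)
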