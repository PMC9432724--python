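"""Coupled translation + transport trajectories and ensemble statistics."""

import math

import numpy as np
import pytest

from mitoloc import (
    CompetenceModel,
    GeneKinetics,
    SimulationConfig,
    TrajectoryRecord,
    ensemble_chx_localization,
    ensemble_localization,
    geometry_from_mvf,
    simulate_ensemble,
    simulate_mrna,
    sweep,
)
from mitoloc.propagator import get_propagators
from mitoloc.simulate import _simulate_spatial



def make_record(f_binding, T, t_nuclear=0.0):
    """Record with a prescribed binding-localized fraction and lifetime."""
    t_loc = f_binding * T
    rest = T - t_loc - t_nuclear
    return TrajectoryRecord(
        T_lifetime=T, t_nuclear=t_nuclear, t_region1=0.0, t_region2=0.0,
        t_region3=rest, t_bound=t_loc, t_translated_mts=t_loc,
        t_competent_mts=t_loc, decayed=True, n_bindings=1,
    )


def test_ensemble_localization_weighting():
    """Lifetime weighting: {(0.5, 100 s), (1.0, 300 s)} averages to 0.875."""
    recs = [make_record(0.5, 100.0), make_record(1.0, 300.0)]
    assert ensemble_localization(recs, "binding") == pytest.approx(0.875)
    assert ensemble_localization(recs[:1], "binding") == pytest.approx(0.5)
    equal = [make_record(0.2, 50.0), make_record(0.6, 50.0)]
    assert ensemble_localization(equal, "binding") == pytest.approx(0.4)
    with pytest.raises(ValueError):
        ensemble_localization([], "binding")
    with pytest.raises(ValueError):
        ensemble_localization(recs, "fluorescence")


def test_time_bookkeeping_exact(conditional_median, geom_4pct):
    cfg = SimulationConfig(
        gene=conditional_median, competence=CompetenceModel.maturation(40.0),
        geometry=geom_4pct, seed=3, n_trajectories=8,
    )
    for rec in simulate_ensemble(cfg):
        total = (rec.t_nuclear + rec.t_region1 + rec.t_region2 + rec.t_region3
                 + rec.t_bound)
        assert total == pytest.approx(rec.T_lifetime, rel=1e-12)
        assert 0.0 <= rec.f_loc_binding <= rec.f_loc_imaging <= 1.0


def test_trajectory_bit_reproducible(conditional_median, geom_4pct):
    cfg = SimulationConfig(
        gene=conditional_median, competence=CompetenceModel.maturation(40.0),
        geometry=geom_4pct, seed=9, n_trajectories=4,
    )
    a = simulate_mrna(cfg, 2)
    b = simulate_mrna(cfg, 2)
    assert a == b
    assert simulate_mrna(cfg, 3) != a


def test_never_competent_equilibrium_occupancy(geom_4pct):
    """A transcript too short to finish an MTS never binds; its unbound
    residence splits between regions in proportion to annular area."""
    gene = GeneKinetics("short", 0.2, 8.0, 90, l_MTS=100)
    cfg = SimulationConfig(
        gene=gene, competence=CompetenceModel.instantaneous(),
        geometry=geom_4pct, k_decay=0.0, max_time=1500.0, seed=5,
        n_trajectories=24,
    )
    recs = simulate_ensemble(cfg)
    assert all(r.t_bound == 0.0 and r.t_translated_mts == 0.0 for r in recs)
    shares = np.array(
        [
            np.array([r.t_region1, r.t_region2, r.t_region3])
            / (r.T_lifetime - r.t_nuclear)
            for r in recs
        ]
    )
    mean = shares.mean(axis=0)
    se = shares.std(axis=0, ddof=1) / math.sqrt(len(recs))
    assert np.all(np.abs(mean - geom_4pct.area_fractions) <= 3 * se + 5e-4)


def test_forced_competence_binds_forever(geom_4pct, rng):
    """With the competence indicator pinned on, the first region-1 entry
    binds irreversibly and the localized fraction tends to one."""
    props = get_propagators(geom_4pct)
    t1, t2, t3, tb, nb = _simulate_spatial(
        props, np.array([0.0]), 3000.0, rng
    )
    assert nb == 1
    assert t1 == 0.0  # binds at the instant of entering region 1
    assert tb / 3000.0 > 0.9
    assert t1 + t2 + t3 + tb == pytest.approx(3000.0, rel=1e-12)


def test_chx_exceeds_binding_localization_with_maturation(
    conditional_median, geom_4pct
):
    """Arrested elongation (CHX) localizes every translated-MTS mRNA, so the
    CHX statistic exceeds the maturation-model binding localization."""
    cfg = SimulationConfig(
        gene=conditional_median, competence=CompetenceModel.maturation(40.0),
        geometry=geom_4pct, seed=21, n_trajectories=20,
    )
    recs = simulate_ensemble(cfg)
    chx = ensemble_chx_localization(recs)
    assert chx > ensemble_localization(recs, "binding")
    assert ensemble_localization(recs, "imaging") >= ensemble_localization(
        recs, "binding"
    )


def test_localization_monotone_in_mvf(conditional_median):
    """Binding localization grows with mitochondrial volume fraction
    (matched seeds across the axis)."""
    base = SimulationConfig(
        gene=conditional_median, competence=CompetenceModel.maturation(40.0),
        geometry=geometry_from_mvf(0.02), seed=11, n_trajectories=16,
    )
    table = sweep(base, "mvf", [0.02, 0.08, 0.15])
    f = table["f_binding"].to_numpy()
    assert np.all(np.diff(f) > 0)


def test_localization_decreases_with_elongation_rate(geom_4pct):
    """Faster elongation shortens MTS exposure and lowers localization."""
    gene = GeneKinetics("g", 0.1, 2.0, 400)
    base = SimulationConfig(
        gene=gene, competence=CompetenceModel.instantaneous(),
        geometry=geom_4pct, seed=13, n_trajectories=16,
    )
    table = sweep(base, "k_elong", [2.0, 10.0, 50.0])
    f = table["f_binding"].to_numpy()
    assert f[0] > f[1] > f[2]


def test_localization_decreases_with_maturation_time(conditional_median, geom_4pct):
    base = SimulationConfig(
        gene=conditional_median, competence=CompetenceModel.maturation(10.0),
        geometry=geom_4pct, seed=17, n_trajectories=16,
    )
    table = sweep(base, "tau_MTS", [5.0, 40.0, 200.0])
    f = table["f_binding"].to_numpy()
    assert f[0] > f[1] > f[2]


def test_sweep_reports_inadmissible_values_per_row(conditional_median, geom_4pct):
    base = SimulationConfig(
        gene=conditional_median, competence=CompetenceModel.instantaneous(),
        geometry=geom_4pct, seed=1, n_trajectories=2,
    )
    table = sweep(base, "mvf", [0.04, 0.9])
    assert table.loc[0, "error"] == ""
    assert "region 3" in table.loc[1, "error"]
    assert math.isnan(table.loc[1, "f_binding"])
    with pytest.raises(ValueError):
        sweep(base, "voltage", [1.0])


def test_cohort_group_separation_with_maturation(geom_4pct):
    """Full pipeline on a synthetic cohort: at tau_MTS = 40 s and 4% MVF the
    conditional group's median localization falls below the constitutive
    group's (the qualitative two-group separation)."""
    from mitoloc import build_gene_table, generate_synthetic_cohort
    from mitoloc.synthetic import SyntheticCohortSpec

    cohort = generate_synthetic_cohort(
        SyntheticCohortSpec(n_conditional=24, n_constitutive=24, seed=19)
    )
    table = build_gene_table(cohort).merge(
        cohort[["name", "group"]], on="name", suffixes=("", "_y")
    )
    medians = {}
    for group in ("conditional", "constitutive"):
        locs = []
        for _, row in table[table["group"] == group].iterrows():
            cfg = SimulationConfig(
                gene=GeneKinetics(row["name"], row["k_init"], row["k_elong"],
                                  int(row["L"])),
                competence=CompetenceModel.maturation(40.0),
                geometry=geom_4pct, seed=19, n_trajectories=20,
            )
            locs.append(ensemble_localization(simulate_ensemble(cfg), "binding"))
        medians[group] = np.median(locs)
    assert medians["conditional"] < medians["constitutive"]


def test_slow_gene_insensitive_to_mvf(geom_4pct):
    """When MTS exposure dwarfs the diffusive search time, localization is
    near-saturated and flat in the volume fraction (constitutive-like)."""
    slow = GeneKinetics("slow", 0.2, 1.0, 600)  # exposure 500 s
    base = SimulationConfig(
        gene=slow, competence=CompetenceModel.instantaneous(),
        geometry=geometry_from_mvf(0.01), seed=23, n_trajectories=16,
    )
    table = sweep(base, "mvf", [0.01, 0.15])
    f = table["f_binding"].to_numpy()
    # insensitivity to MVF is the property: a 15x volume-fraction change
    # barely moves localization, unlike the switch-like conditional genes
    assert np.all(f > 0.5)
    assert abs(f[1] - f[0]) < 0.10
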