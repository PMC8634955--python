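"""Engine mechanics: step ordering, conservation, prevalence, life-years lost."""

from dataclasses import replace

import numpy as np
import pytest

from prrpsim import (
    DemographySchedules,
    LifeTable,
    PopulationState,
    RateTable,
    RiskModel,
    ScenarioDefinition,
    SimulationConfig,
    StateSpace,
    build_scenario,
    compare_scenarios,
    initial_population,
    initial_population_for,
    life_years_lost,
    lyl_reduction,
    prevalence,
    run_scenario,
)
from prrpsim.demography import BIN_JUST_QUIT, N_AGES, N_BINS
from prrpsim.engine import lyl_reduction as _lyl_reduction  # noqa: F401
from prrpsim.transitions import geometric_relapse_multipliers

FLAT_RISK = RiskModel(rr_current_smoker=[("*", 0, 100, 1.0)])


def _scenario(table, risk=FLAT_RISK, **kwargs):
    return ScenarioDefinition("test", table, risk, **kwargs)


def test_zero_rates_zero_mortality_step_is_pure_aging(
    space1, zero_mortality_life_table, empty_schedules
):
    pop0 = PopulationState.empty(space1, 2001)
    pop0.counts[0, 30, space1.state_index["C"], BIN_JUST_QUIT] = 10.0
    cfg = SimulationConfig(start_year=2001, end_year=2003, keep_trajectory=True)
    res = run_scenario(pop0, _scenario(RateTable(space1)), zero_mortality_life_table,
                       empty_schedules, cfg)
    assert res.trajectory[2][0, 32, space1.state_index["C"], BIN_JUST_QUIT] == 10.0
    assert res.trajectory[2].sum() == 10.0


def test_single_quit_rate_moves_expected_fraction_to_bin_one(
    space1, zero_mortality_life_table, empty_schedules
):
    q = 0.3
    table = RateTable(space1)
    table.add("C>F", q)
    pop0 = PopulationState.empty(space1, 2001)
    pop0.counts[0, 30, space1.state_index["C"], BIN_JUST_QUIT] = 100.0
    cfg = SimulationConfig(start_year=2001, end_year=2002, keep_trajectory=True)
    res = run_scenario(pop0, _scenario(table), zero_mortality_life_table,
                       empty_schedules, cfg)
    end = res.trajectory[1]
    assert end[0, 31, space1.state_index["F"], 1] == pytest.approx(100.0 * q)
    assert end[0, 31, space1.state_index["C"], BIN_JUST_QUIT] == pytest.approx(100.0 * (1 - q))


def test_prrp_stocks_stay_empty_before_introduction_year(bundle):
    space, scen = build_scenario(bundle, "s3_thp")
    pop0 = initial_population_for(bundle, space)
    cfg = SimulationConfig(start_year=2001, end_year=2020, keep_trajectory=True)
    res = run_scenario(pop0, scen, bundle.life_table, bundle.schedules, cfg)
    prrp_states = [i for i, s in enumerate(space.states) if s.id[1] != "N"]
    for year, counts in zip(res.years, res.trajectory):
        occupancy = counts[:, :, prrp_states, :].sum()
        if year <= 2014:  # introduced during 2014, stocks occupied from 2015
            assert occupancy == 0.0
        if year == 2016:
            assert occupancy > 0.0


def test_prevalence_definitions(space2):
    pop = PopulationState.empty(space2, 2001)
    pop.counts[0, 20, space2.state_index["CN"], BIN_JUST_QUIT] = 1.0
    pop.counts[0, 30, space2.state_index["CC"], BIN_JUST_QUIT] = 1.0
    pop.counts[0, 40, space2.state_index["NN"], BIN_JUST_QUIT] = 8.0
    # 2 current smokers of 10 eligible
    assert prevalence(pop, "cigarette") == pytest.approx(20.0)
    # dual users count toward both products by default...
    assert prevalence(pop, "prrp") == pytest.approx(10.0)
    # ...but not under exclusive counting
    assert prevalence(pop, "prrp", counting="exclusive") == 0.0
    assert prevalence(pop, "cigarette", counting="exclusive") == pytest.approx(10.0)
    # empty and saturated edge cases
    assert prevalence(PopulationState.empty(space2, 2001), "cigarette") == 0.0
    full = PopulationState.empty(space2, 2001)
    full.counts[:, 14:, space2.state_index["CN"], BIN_JUST_QUIT] = 1.0
    assert prevalence(full, "cigarette") == pytest.approx(100.0)


def test_under_age_people_are_excluded_from_prevalence(space1):
    pop = PopulationState.empty(space1, 2001)
    pop.counts[0, 10, space1.state_index["C"], BIN_JUST_QUIT] = 5.0  # under 14
    pop.counts[0, 20, space1.state_index["N"], BIN_JUST_QUIT] = 5.0
    assert prevalence(pop, "cigarette", min_age=14) == 0.0


def test_life_years_lost_single_death_contributes_expectancy():
    m = np.zeros((2, N_AGES))
    m[:, -1] = 1.0
    e = np.zeros((2, N_AGES))
    e[0, 60] = 22.0
    lt = LifeTable({2001: m}, e)
    deaths = np.zeros((3, 2, N_AGES))
    deaths[1, 0, 60] = 1.0
    per_year, cumulative = life_years_lost(deaths, lt)
    assert per_year.tolist() == [0.0, 22.0, 0.0]
    assert cumulative.tolist() == [0.0, 22.0, 22.0]


def test_identical_scenarios_have_zero_lyl_reduction(bundle):
    space, scen = build_scenario(bundle, "s1_smoking_only")
    pop0 = initial_population_for(bundle, space)
    cfg = SimulationConfig(start_year=2001, end_year=2011)
    r1 = run_scenario(pop0, scen, bundle.life_table, bundle.schedules, cfg)
    r2 = run_scenario(pop0, scen, bundle.life_table, bundle.schedules, cfg)
    np.testing.assert_array_equal(lyl_reduction(r1, r2), 0.0)


def test_markov_oracle_equivalence_on_toy_population(
    space2, zero_mortality_life_table, empty_schedules
):
    """Engine state marginals equal an independent transition-matrix power.

    Toy setting: one gender occupied, 3 ages, no demography, no
    mortality below the horizon, age-independent rates, flat relapse, so
    the joint-state marginal follows an exact 9-state Markov chain.
    """
    rates = {
        "NN>CN": 0.04, "NN>NC": 0.02, "CN>FN": 0.05, "CN>CC": 0.03,
        "NC>CC": 0.01, "NC>NF": 0.20, "CC>FC": 0.10, "CC>CF": 0.15,
        "FN>CN": 0.06, "NF>NC": 0.04, "FC>CC": 0.05, "FF>CF": 0.02,
        "CF>FF": 0.05, "FC>FF": 0.10, "FN>CC": 0.01,
    }
    table = RateTable(space2)
    for key, p in rates.items():
        table.add(key, p)

    pop0 = PopulationState.empty(space2, 2001)
    rng = np.random.default_rng(5)
    for si, state in enumerate(space2.states):
        weights = rng.uniform(1, 10, 3)
        for k, age in enumerate((30, 31, 32)):
            if state.id[0] == "F":
                pop0.counts[0, age, si, 5] = weights[k]  # any populated bin
            else:
                pop0.counts[0, age, si, BIN_JUST_QUIT] = weights[k]
    v0 = pop0.counts.sum(axis=(0, 1, 3))
    v0 = v0 / v0.sum()

    # independent oracle: dense transition matrix powered T times
    P = np.eye(space2.n_states)
    for key, p in rates.items():
        frm, to = key.split(">")
        i, j = space2.state_index[frm], space2.state_index[to]
        P[i, i] -= p
        P[i, j] += p

    T = 50
    cfg = SimulationConfig(start_year=2001, end_year=2001 + T, keep_trajectory=True)
    scen = _scenario(table, relapse_bin_multipliers=np.ones(N_BINS))
    res = run_scenario(pop0, scen, zero_mortality_life_table, empty_schedules, cfg)

    expected = v0 @ np.linalg.matrix_power(P, T)
    got = res.trajectory[-1].sum(axis=(0, 1, 3))
    got = got / got.sum()
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_conservation_reconciles_every_year(bundle):
    space, scen = build_scenario(bundle, "s2_ecig")
    pop0 = initial_population_for(bundle, space)
    cfg = SimulationConfig(start_year=2001, end_year=2031)
    res = run_scenario(pop0, scen, bundle.life_table, bundle.schedules, cfg)
    assert res.conservation_residuals.max() <= 1e-9


def test_stronger_initiation_decline_never_raises_smoking_prevalence(bundle):
    space, scen = build_scenario(bundle, "s1_smoking_only")
    pop0 = initial_population_for(bundle, space)
    cfg = SimulationConfig(start_year=2001, end_year=2041)
    results = []
    for rate in (0.0, 0.03, 0.10):
        mods = replace(scen.modifiers, initiation_decline_rate=rate)
        results.append(
            run_scenario(pop0, replace(scen, modifiers=mods),
                         bundle.life_table, bundle.schedules, cfg)
        )
    for weaker, stronger in zip(results, results[1:]):
        assert np.all(stronger.smoking_prevalence <= weaker.smoking_prevalence + 1e-12)


def test_pseudo_prrp_weight_one_reproduces_sole_product_scenario(bundle):
    """Blending at weight 1 must equal the e-cigarette-only table run."""
    space, ecig = build_scenario(bundle, "s2_ecig")
    pseudo_cfg = dict(bundle.scenarios["s4_pseudo_5050"])
    pseudo_cfg["pseudo"] = {"table_a": "ecig", "table_b": "thp", "weight_a": 1.0}
    pseudo_cfg["risk_fractions"] = {"prrp": 0.05}
    pseudo_cfg["intro_years"] = {"prrp": 2010}
    bundle.scenarios["_w1"] = pseudo_cfg
    try:
        space_w, w1 = build_scenario(bundle, "_w1")
        pop0 = initial_population_for(bundle, space)
        cfg = SimulationConfig(start_year=2001, end_year=2031)
        r_ecig = run_scenario(pop0, ecig, bundle.life_table, bundle.schedules, cfg)
        r_w1 = run_scenario(pop0, w1, bundle.life_table, bundle.schedules, cfg)
        np.testing.assert_allclose(r_w1.smoking_prevalence, r_ecig.smoking_prevalence,
                                   atol=1e-12)
        np.testing.assert_allclose(r_w1.cumulative_lyl, r_ecig.cumulative_lyl, rtol=1e-12)
    finally:
        del bundle.scenarios["_w1"]


def test_comparison_table_layout(bundle):
    cfg = SimulationConfig(start_year=2001, end_year=2031)
    results = []
    for name in ("s1_smoking_only", "s2_ecig"):
        space, scen = build_scenario(bundle, name)
        pop0 = initial_population_for(bundle, space)
        results.append(run_scenario(pop0, scen, bundle.life_table, bundle.schedules, cfg))
    table = compare_scenarios(results, "s1_smoking_only", decades=[2010, 2020, 2030])
    assert set(table["metric"]) == {
        "smoking_prevalence_pct", "prrp_prevalence_pct", "lyl_reduction_million"
    }
    assert list(table.columns[2:]) == ["2010", "2020", "2030"]
    baseline_rows = table[table["scenario"] == "s1_smoking_only"]
    lyl_row = baseline_rows[baseline_rows["metric"] == "lyl_reduction_million"]
    assert (lyl_row[["2010", "2020", "2030"]].to_numpy() == 0).all()
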