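"""Rate tables, scenario modifiers, pseudo-PRRP blending, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prrpsim import (
    DemographySchedules,
    LifeTable,
    RateTable,
    ScenarioDefinition,
    ScenarioModifiers,
    SimulationConfig,
    StateSpace,
    calibrate_initiation_from_prevalence,
    combine_pseudo_prrp,
    combine_pseudo_risk,
    effective_rate,
    initial_population,
    normalize_outflows,
    run_scenario,
)
from prrpsim.demography import N_AGES
from prrpsim.risk import RiskModel


@pytest.fixture()
def two_product_table(space2):
    table = RateTable(space2)
    table.add("NN>NC", 0.01)  # PRRP initiation by never users
    table.add("NN>CN", 0.02)  # cigarette initiation
    table.add("CN>CC", 0.03)  # smoker starts PRRP
    return table


def test_pre_introduction_flows_are_gated_to_zero(two_product_table):
    mods = ScenarioModifiers(product_intro_year={"prrp": 2014})
    assert effective_rate(two_product_table, "NN>NC", "male", 20, 2012, mods) == 0.0
    assert effective_rate(two_product_table, "NN>NC", "male", 20, 2014, mods) == 0.01
    # cigarette flows unaffected by the PRRP gate
    assert effective_rate(two_product_table, "NN>CN", "male", 20, 2012, mods) == 0.02


@pytest.mark.parametrize(
    "year,expected",
    [(2020, 0.02), (2030, 0.02 * 0.97**10), (2019, 0.02)],
)
def test_initiation_decline_compounds_from_start_year(two_product_table, year, expected):
    mods = ScenarioModifiers(initiation_decline_rate=0.03, initiation_decline_start=2020)
    got = effective_rate(two_product_table, "NN>CN", "male", 20, year, mods)
    assert got == pytest.approx(expected, abs=1e-12)
    # the decline applies to cigarette initiation only, not PRRP flows
    assert effective_rate(two_product_table, "NN>NC", "male", 20, 2030, mods) == 0.01


def test_effective_rate_time_invariant_without_decline(two_product_table):
    mods = ScenarioModifiers(product_intro_year={"prrp": 2010})
    values = {
        effective_rate(two_product_table, "CN>CC", "female", 40, y, mods)
        for y in (2010, 2030, 2080)
    }
    assert values == {0.03}


def _uniform_table(space, value_a, value_b):
    t = RateTable(space)
    t.add("NN>NC", value_a, value_a * 0.5, min(1.0, value_a * 1.5))
    t.add("CN>CC", value_b)
    return t


@pytest.mark.parametrize(
    "weight,expected",
    [(1.0, 0.10), (0.5, 0.15), (0.63, 0.137)],
)
def test_pseudo_prrp_blend_is_weighted_average(space2, weight, expected):
    a = _uniform_table(space2, 0.10, 0.02)
    b = _uniform_table(space2, 0.20, 0.02)
    blended = combine_pseudo_prrp(a, b, weight)
    got = effective_rate(blended, "NN>NC", "male", 20, 2020)
    assert got == pytest.approx(expected, abs=1e-12)


@given(st.floats(min_value=0.0, max_value=1.0))
@settings(derandomize=True, max_examples=50)
def test_blending_a_table_with_itself_is_identity(weight):
    space = StateSpace(("cigarette", "prrp"))
    a = _uniform_table(space, 0.10, 0.02)
    blended = combine_pseudo_prrp(a, a, weight)
    for ea, eb in zip(sorted(a.entries, key=lambda e: e.flow_key),
                      sorted(blended.entries, key=lambda e: e.flow_key)):
        assert eb.prob.mean == pytest.approx(ea.prob.mean)
        assert eb.prob.lo95 == pytest.approx(ea.prob.lo95)
        assert eb.prob.hi95 == pytest.approx(ea.prob.hi95)


def test_blending_rejects_mismatched_flow_sets(space2):
    a = _uniform_table(space2, 0.1, 0.02)
    b = RateTable(space2)
    b.add("NN>NC", 0.2)
    with pytest.raises(ValueError, match="mismatched"):
        combine_pseudo_prrp(a, b, 0.5)


@pytest.mark.parametrize(
    "fa,fb,w,expected",
    [
        (0.05, 0.10, 0.50, 0.075),  # midpoint: 7.5% of cigarette risk
        (0.05, 0.10, 0.63, 0.0685),  # 63:37 split: 6.85%
        (0.05, 0.10, 1.0, 0.05),
    ],
)
def test_pseudo_risk_fraction_blend(fa, fb, w, expected):
    assert combine_pseudo_risk(fa, fb, w) == pytest.approx(expected, abs=1e-12)


def test_normalize_outflows_scales_only_overfull_stocks(space1):
    table = RateTable(space1)
    table.add("C>F", 0.8)  # quit
    # force the never stock over 1 is impossible with one outflow <= 1;
    # use the current stock's single outflow 0.8 (stays) and a synthetic
    # overfull pair on the never stock via two tables is not possible in
    # a 1-product space, so test on the 2-product space below.
    ra = normalize_outflows(table, years=[2001])
    fi = space1.flow_index["C>F"]
    assert ra.mean[fi, 0, 0, 50] == pytest.approx(0.8)


def test_normalize_outflows_proportional_scaling(space2):
    table = RateTable(space2)
    table.add("CN>FN", 0.8)  # quit smoking
    table.add("CN>CC", 0.6)  # start PRRP
    ra = normalize_outflows(table, years=[2001])
    qi = space2.flow_index["CN>FN"]
    si = space2.flow_index["CN>CC"]
    assert ra.mean[qi, 0, 0, 50] == pytest.approx(0.8 / 1.4)
    assert ra.mean[si, 0, 0, 50] == pytest.approx(0.6 / 1.4)
    # untouched stock unchanged
    assert ra.mean[space2.flow_index["NN>NC"], 0, 0, 50] == 0.0


def test_calibration_hazard_formula_and_floor():
    E = np.zeros((2, N_AGES))
    E[:, 15] = 0.10
    E[:, 16:] = 0.19
    h = calibrate_initiation_from_prevalence(E)
    assert h[0, 15] == pytest.approx((0.19 - 0.10) / (1 - 0.10))  # = 0.10
    # flat prevalence -> zero hazard
    assert np.all(h[:, 16:] == 0.0)
    # decreasing prevalence -> floored at zero
    E2 = np.zeros((2, N_AGES))
    E2[:, 15] = 0.3
    E2[:, 16] = 0.2
    h2 = calibrate_initiation_from_prevalence(E2)
    assert np.all(h2 >= 0)
    with pytest.raises(ValueError):
        calibrate_initiation_from_prevalence(np.ones((2, N_AGES)))


def test_calibration_round_trip_through_the_engine(space1, zero_mortality_life_table):
    """Simulating a cohort with calibrated hazards reproduces the curve <= 1e-6."""
    ages = np.arange(N_AGES, dtype=float)
    E = np.zeros((2, N_AGES))
    window = (11, 30)
    ramp = np.clip((ages - 11) / (30 - 11), 0, 1)
    E[0] = 0.55 * ramp
    E[1] = 0.40 * ramp
    h = calibrate_initiation_from_prevalence(E, window)

    table = RateTable(space1)
    for g, gender in enumerate(("male", "female")):
        for age in range(window[0], window[1] + 1):
            if h[g, age] > 0:
                table.add("N>C", h[g, age], gender=gender, age_lo=age, age_hi=age)

    pyramid = np.zeros((2, N_AGES))
    pyramid[:, 11] = 1000.0  # one birth cohort at the window start
    pop0 = initial_population(space1, pyramid, np.zeros((2, N_AGES)),
                              np.zeros((2, N_AGES)), _uniform_quit_dist(), 2001)
    scen = ScenarioDefinition(
        "calib", table, RiskModel(rr_current_smoker=[("*", 0, 100, 1.0)])
    )
    cfg = SimulationConfig(start_year=2001, end_year=2031, keep_trajectory=True)
    result = run_scenario(pop0, scen, zero_mortality_life_table,
                          DemographySchedules(), cfg)
    cur = space1.state_index["C"]
    for step, counts in enumerate(result.trajectory):
        age = 11 + step
        if age >= N_AGES:
            break
        cohort = counts[:, age, :, :].sum(axis=(1, 2))
        ever = counts[:, age, cur, :].sum(axis=1)
        frac = np.where(cohort > 0, ever / cohort, 0.0)
        np.testing.assert_allclose(frac, E[:, age], atol=1e-6)


def _uniform_quit_dist():
    d = np.zeros(21)
    d[0] = 1.0
    return d
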