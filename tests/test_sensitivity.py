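"""CI resampling: determinism, sampling distribution, summary statistics."""

from dataclasses import replace

import numpy as np
import pytest

from prrpsim import (
    RateTable,
    SensitivityConfig,
    SimulationConfig,
    build_scenario,
    initial_population_for,
    run_scenario,
    sample_rate_tables,
    summarize_runs,
)


def _one_flow_table(space2, mean, lo, hi):
    t = RateTable(space2)
    t.add("CN>CC", mean, lo, hi)
    return t


def _drawn_means(tables, flow_key="CN>CC"):
    return np.array(
        [next(e.prob.mean for e in t.entries if e.flow_key == flow_key) for t in tables]
    )


def test_degenerate_intervals_reproduce_the_deterministic_table(space2):
    table = _one_flow_table(space2, 0.03, 0.03, 0.03)
    tables = sample_rate_tables(table, SensitivityConfig(n_runs=5, seed=1))
    for t in tables:
        assert _drawn_means([t])[0] == 0.03


def test_same_seed_gives_identical_table_lists(space2):
    table = _one_flow_table(space2, 0.03, 0.0, 0.205)
    a = sample_rate_tables(table, SensitivityConfig(n_runs=20, seed=42))
    b = sample_rate_tables(table, SensitivityConfig(n_runs=20, seed=42))
    np.testing.assert_array_equal(_drawn_means(a), _drawn_means(b))
    c = sample_rate_tables(table, SensitivityConfig(n_runs=20, seed=43))
    assert not np.array_equal(_drawn_means(a), _drawn_means(c))


def test_uniform_sampling_mean_matches_interval_midpoint(space2):
    """Uniform draws on [0, 0.205] average ~0.1025 at n=1000."""
    table = _one_flow_table(space2, 0.03, 0.0, 0.205)
    tables = sample_rate_tables(table, SensitivityConfig(n_runs=1000, seed=7))
    means = _drawn_means(tables)
    assert means.mean() == pytest.approx(0.1025, abs=0.006)  # 3 sigma MC error
    assert means.min() >= 0.0 and means.max() <= 0.205


def test_truncated_normal_draws_stay_inside_the_interval(space2):
    table = _one_flow_table(space2, 0.03, 0.0, 0.205)
    cfg = SensitivityConfig(n_runs=200, seed=7, sampling="truncated_normal")
    means = _drawn_means(sample_rate_tables(table, cfg))
    assert means.min() >= 0.0 and means.max() <= 0.205
    # mass concentrates nearer the point estimate than under uniform
    assert abs(np.median(means) - 0.03) < abs(0.1025 - 0.03)


def test_widening_an_interval_widens_the_sampled_envelope(space2):
    narrow = _one_flow_table(space2, 0.10, 0.08, 0.12)
    wide = _one_flow_table(space2, 0.10, 0.02, 0.18)
    cfg = SensitivityConfig(n_runs=100, seed=9)
    mn = _drawn_means(sample_rate_tables(narrow, cfg))
    mw = _drawn_means(sample_rate_tables(wide, cfg))
    assert mw.min() <= mn.min() and mw.max() >= mn.max()


def test_targets_restrict_which_flows_are_sampled(space2):
    table = RateTable(space2)
    table.add("CN>CC", 0.03, 0.0, 0.2)
    table.add("NN>NC", 0.01, 0.0, 0.05)
    cfg = SensitivityConfig(n_runs=10, seed=3, targets=frozenset({"CN>CC"}))
    tables = sample_rate_tables(table, cfg)
    assert np.all(_drawn_means(tables, "NN>NC") == 0.01)
    assert np.any(_drawn_means(tables, "CN>CC") != 0.03)


def test_summary_statistics_and_percentiles(bundle):
    """Stats over four hand-made runs: mean 2.5, median 2.5, ordered percentiles."""
    space, scen = build_scenario(bundle, "s2_ecig")
    pop0 = initial_population_for(bundle, space)
    cfg = SimulationConfig(start_year=2001, end_year=2006)
    base = run_scenario(pop0, scen, bundle.life_table, bundle.schedules, cfg)

    runs = []
    for k in (1.0, 2.0, 3.0, 4.0):
        r = run_scenario(pop0, scen, bundle.life_table, bundle.schedules, cfg)
        r.product_prevalence = {
            label: np.full_like(series, k) for label, series in r.product_prevalence.items()
        }
        r.prrp_prevalence = np.full_like(r.prrp_prevalence, k)
        runs.append(r)

    summary = summarize_runs(runs, 2006, base)
    smoking = summary[summary["metric"] == "smoking_prevalence_pct"].iloc[0]
    assert smoking["mean"] == pytest.approx(2.5)
    assert smoking["median"] == pytest.approx(2.5)
    assert smoking["min"] == 1.0 and smoking["max"] == 4.0
    assert smoking["sd"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
    percentiles = [smoking[f"p{p}"] for p in (5, 10, 15, 20, 25)]
    assert percentiles == sorted(percentiles)  # non-decreasing in the level

    lyl = summary[summary["metric"] == "lyl_reduction"].iloc[0]
    assert lyl["fraction_negative"] == 0.0  # identical mortality -> no run below baseline


def test_all_identical_runs_collapse_the_summary(bundle):
    space, scen = build_scenario(bundle, "s2_ecig")
    pop0 = initial_population_for(bundle, space)
    cfg = SimulationConfig(start_year=2001, end_year=2004)
    r = run_scenario(pop0, scen, bundle.life_table, bundle.schedules, cfg)
    summary = summarize_runs([r, r, r], 2004, r)
    row = summary[summary["metric"] == "smoking_prevalence_pct"].iloc[0]
    assert row["min"] == row["max"] == row["mean"] == row["median"]
    assert row["sd"] == 0.0


def test_sensitivity_outputs_collapse_as_intervals_collapse(bundle):
    """Degenerate CIs: every sensitivity run equals the deterministic run."""
    space, scen = build_scenario(bundle, "s3_thp")
    pop0 = initial_population_for(bundle, space)
    cfg = SimulationConfig(start_year=2001, end_year=2021)
    deterministic = run_scenario(pop0, scen, bundle.life_table, bundle.schedules, cfg)

    degenerate = RateTable(scen.rate_table.space)
    for e in scen.rate_table.entries:
        degenerate.add(e.flow_key, e.prob.mean, e.prob.mean, e.prob.mean,
                       gender=e.gender, age_lo=e.age_lo, age_hi=e.age_hi, year=e.year)
    tables = sample_rate_tables(degenerate, SensitivityConfig(n_runs=3, seed=11))
    for t in tables:
        r = run_scenario(pop0, replace(scen, rate_table=t),
                         bundle.life_table, bundle.schedules, cfg)
        np.testing.assert_array_equal(r.smoking_prevalence, deterministic.smoking_prevalence)
        np.testing.assert_array_equal(r.cumulative_lyl, deterministic.cumulative_lyl)
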