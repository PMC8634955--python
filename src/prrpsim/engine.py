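"""The simulation engine: 1-year time steps from 2001 to 2100.

Each step applies, in a fixed audited order:

1. status-specific mortality (never-smoker baseline × joint-state RR);
2. product-use transitions (annual probabilities applied to survivors);
3. aging by one year (with quit-time clock advance and the age-100
   removal at 100% mortality);
4. births (age 0, all-NEVER);
5. net migration (resident-composition-matched).

Population totals reconcile every year:
``pop' = pop - deaths + births + net migration`` to within a configurable
relative tolerance.  Outputs per scenario are yearly smoking and PRRP
prevalence among people aged 14 and over, deaths by gender and age, and
cumulative life-years lost (deaths weighted by remaining life expectancy
at the age of death); scenarios are compared by the *reduction* in
life-years lost versus a baseline, sampled at decades as in the standard
projection-table layout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import (
    BIN_JUST_QUIT,
    GENDERS,
    N_AGES,
    N_BINS,
    DemographySchedules,
    LifeTable,
    PopulationState,
    age_population,
    apply_births,
    apply_migration,
)
from .risk import RiskModel, apply_status_mortality, joint_rr_array, never_mortality_scale
from .state_space import ProductStatus, StateSpace
from .transitions import (
    RateTable,
    ScenarioModifiers,
    effective_mean_arrays,
    geometric_relapse_multipliers,
)

__all__ = [
    "SimulationConfig",
    "ScenarioDefinition",
    "ProjectionResult",
    "initial_population",
    "step_year",
    "run_scenario",
    "prevalence",
    "life_years_lost",
    "compare_scenarios",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level settings shared by all scenarios of a comparison."""

    start_year: int = 2001
    end_year: int = 2100
    prevalence_min_age: int = 14
    dual_use_counting: str = "both"  # dual users count toward both products
    lyl_mode: str = "expectancy"  # or "person_years"
    keep_trajectory: bool = False
    conservation_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.dual_use_counting not in ("both", "exclusive"):
            raise ValueError("dual_use_counting must be 'both' or 'exclusive'")
        if self.lyl_mode not in ("expectancy", "person_years"):
            raise ValueError("lyl_mode must be 'expectancy' or 'person_years'")

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ScenarioDefinition:
    """Everything that distinguishes one scenario from another."""

    scenario_id: str
    rate_table: RateTable
    risk_model: RiskModel
    modifiers: ScenarioModifiers = field(default_factory=ScenarioModifiers)
    relapse_bin_multipliers: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.relapse_bin_multipliers is None:
            self.relapse_bin_multipliers = geometric_relapse_multipliers()
        self.relapse_bin_multipliers = np.asarray(self.relapse_bin_multipliers, dtype=float)
        if self.relapse_bin_multipliers.shape != (N_BINS,):
            raise ValueError(f"relapse multipliers must have shape ({N_BINS},)")
        if np.any(self.relapse_bin_multipliers < 0) or np.any(self.relapse_bin_multipliers > 1):
            raise ValueError("relapse multipliers must be in [0, 1]")


@dataclass
class ProjectionResult:
    """Yearly output series of one scenario run."""

    scenario_id: str
    years: np.ndarray
    product_prevalence: dict[str, np.ndarray]  # % of people aged >= min_age
    prrp_prevalence: np.ndarray  # current use of any non-cigarette product, %
    total_population: np.ndarray
    deaths_by_year: np.ndarray  # (n_years, 2, 101); final year not stepped -> 0
    lyl_by_year: np.ndarray
    cumulative_lyl: np.ndarray
    person_years: np.ndarray
    conservation_residuals: np.ndarray
    metadata: dict
    final_population: PopulationState
    trajectory: list[np.ndarray] | None = None

    @property
    def smoking_prevalence(self) -> np.ndarray:
        return self.product_prevalence[self.final_population.space.labels[0]]

    def at_year(self, series: np.ndarray, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} outside projection horizon")
        return float(series[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: (year, metric, value)."""
        rows = []
        for i, y in enumerate(self.years):
            rows.append((int(y), "total_population", self.total_population[i]))
            for label, series in self.product_prevalence.items():
                rows.append((int(y), f"prevalence_{label}_pct", series[i]))
            rows.append((int(y), "prevalence_prrp_pct", self.prrp_prevalence[i]))
            rows.append((int(y), "deaths", self.deaths_by_year[i].sum()))
            rows.append((int(y), "life_years_lost", self.lyl_by_year[i]))
            rows.append((int(y), "cumulative_life_years_lost", self.cumulative_lyl[i]))
            rows.append((int(y), "person_years", self.person_years[i]))
        frame = pd.DataFrame(rows, columns=["year", "metric", "value"])
        frame.insert(0, "scenario", self.scenario_id)
        return frame


def initial_population(
    space: StateSpace,
    pyramid: np.ndarray,
    current_prev: np.ndarray,
    former_prev: np.ndarray,
    quit_time_distribution: np.ndarray,
    year: int,
) -> PopulationState:
    """Initial stocks from a pyramid and smoking prevalence curves.

    ``pyramid``, ``current_prev`` and ``former_prev`` have shape
    (2, 101); PRRP stocks start empty (products enter via their
    introduction years).  ``quit_time_distribution`` gives 21
    proportions over bins 1..20 and "20+" for former smokers.
    """
    pyramid = np.asarray(pyramid, dtype=float)
    cur = np.asarray(current_prev, dtype=float)
    fmr = np.asarray(former_prev, dtype=float)
    qd = np.asarray(quit_time_distribution, dtype=float)
    for name, arr in (("pyramid", pyramid), ("current_prev", cur), ("former_prev", fmr)):
        if arr.shape != (2, N_AGES):
            raise ValueError(f"{name} must have shape (2, {N_AGES})")
    if np.any(cur < 0) or np.any(fmr < 0) or np.any(cur + fmr > 1 + 1e-12):
        raise ValueError("prevalence curves must be non-negative and sum to <= 1")
    if qd.shape != (N_BINS - 1,) or np.any(qd < 0) or not np.isclose(qd.sum(), 1.0):
        raise ValueError(f"quit-time distribution needs {N_BINS - 1} proportions summing to 1")

    never_idx = space.state_index["N" * space.n_products]
    smoker_idx = space.state_index["C" + "N" * (space.n_products - 1)]
    former_idx = space.state_index["F" + "N" * (space.n_products - 1)]

    counts = np.zeros((2, N_AGES, space.n_states, N_BINS))
    counts[:, :, never_idx, BIN_JUST_QUIT] = pyramid * (1.0 - cur - fmr)
    counts[:, :, smoker_idx, BIN_JUST_QUIT] = pyramid * cur
    counts[:, :, former_idx, 1:] = (pyramid * fmr)[:, :, None] * qd[None, None, :]
    counts = np.clip(counts, 0.0, None)
    return PopulationState(space, counts, year)


def _apply_transitions(
    pop: PopulationState,
    eff_year: np.ndarray,
    relapse_mult: np.ndarray,
) -> PopulationState:
    """Move survivors along every flow simultaneously (one annual step)."""
    space = pop.space
    c = pop.counts
    delta = np.zeros_like(c)
    for fi, flow in enumerate(space.flows):
        r = eff_year[fi]  # (2, 101)
        if not r.any():
            continue
        si = space.state_index[flow.from_state.id]
        ti = space.state_index[flow.to_state.id]
        src = c[:, :, si, :]
        if flow.move_of(0) == "relapse":
            # cigarette relapse empties the quit clock; probability
            # declines with time abstinent via the per-bin multipliers
            out = src * r[:, :, None] * relapse_mult[None, None, :]
            delta[:, :, si, :] -= out
            delta[:, :, ti, BIN_JUST_QUIT] += out.sum(axis=2)
        else:
            out = src * r[:, :, None]
            delta[:, :, si, :] -= out
            delta[:, :, ti, :] += out
    new = np.clip(c + delta, 0.0, None)
    return PopulationState(space, new, pop.year)


def step_year(
    pop: PopulationState,
    eff_year: np.ndarray,
    all_cause: np.ndarray,
    never_scale: np.ndarray,
    rr_array: np.ndarray,
    schedules: DemographySchedules,
    relapse_mult: np.ndarray,
) -> tuple[PopulationState, np.ndarray, dict]:
    """Advance the population one year.

    Sub-step order: mortality → transitions → aging → births →
    migration.  Returns the next-year population, deaths per
    (gender, age, state) and a conservation accounting dict.
    """
    year = pop.year
    total_before = pop.total()

    survivors, deaths = apply_status_mortality(pop, all_cause, never_scale, rr_array)
    moved = _apply_transitions(survivors, eff_year, relapse_mult)
    aged, aged_out = age_population(moved)
    with_births = apply_births(aged, schedules, year)
    final, applied_migration = apply_migration(with_births, schedules, year)
    final.year = year + 1

    births = sum(schedules.births_for(year))
    expected = total_before - deaths.sum() - aged_out + births + applied_migration
    residual = abs(final.total() - expected) / max(total_before, 1.0)
    accounting = {
        "year": year,
        "deaths": float(deaths.sum()),
        "aged_out": aged_out,
        "births": births,
        "net_migration": applied_migration,
        "residual": residual,
    }
    return final, deaths, accounting


def prevalence(
    pop: PopulationState,
    product: str,
    min_age: int = 14,
    counting: str = "both",
) -> float:
    """Current-use prevalence (%) of one product among people aged ≥ min_age.

    With ``counting="both"`` dual users count toward every product they
    currently use; with ``"exclusive"`` only sole users of the product
    are counted.
    """
    space = pop.space
    pi = space.labels.index(product)
    if counting == "both":
        states = [i for i, s in enumerate(space.states) if s.statuses[pi] is ProductStatus.CURRENT]
    elif counting == "exclusive":
        states = [
            i
            for i, s in enumerate(space.states)
            if s.statuses[pi] is ProductStatus.CURRENT
            and all(
                st is not ProductStatus.CURRENT for j, st in enumerate(s.statuses) if j != pi
            )
        ]
    else:
        raise ValueError("counting must be 'both' or 'exclusive'")
    eligible = pop.counts[:, min_age:, :, :].sum()
    if eligible <= 0:
        return 0.0
    users = pop.counts[:, min_age:, states, :].sum()
    return 100.0 * users / eligible


def _any_prrp_prevalence(pop: PopulationState, min_age: int) -> float:
    """Current use of any non-cigarette product, % of people aged ≥ min_age."""
    space = pop.space
    if space.n_products == 1:
        return 0.0
    states = [
        i
        for i, s in enumerate(space.states)
        if any(st is ProductStatus.CURRENT for st in s.statuses[1:])
    ]
    eligible = pop.counts[:, min_age:, :, :].sum()
    if eligible <= 0:
        return 0.0
    return 100.0 * pop.counts[:, min_age:, states, :].sum() / eligible


def life_years_lost(
    deaths_by_year: np.ndarray, life_table: LifeTable
) -> tuple[np.ndarray, np.ndarray]:
    """Expectancy-weighted life-years lost per year and cumulatively.

    ``LYL(Y) = sum_{y <= Y} sum_{g,a} deaths(g, a, y) * e(g, a)`` with
    ``e`` the reference remaining life expectancy at the age of death.
    """
    e = life_table.life_expectancy  # (2, 101)
    per_year = (deaths_by_year * e[None, :, :]).sum(axis=(1, 2))
    return per_year, np.cumsum(per_year)


def run_scenario(
    pop0: PopulationState,
    scenario: ScenarioDefinition,
    life_table: LifeTable,
    schedules: DemographySchedules,
    config: SimulationConfig = SimulationConfig(),
) -> ProjectionResult:
    """Project one scenario from start to end year.

    Deterministic given the inputs and configuration; prevalence series
    are recorded at the start of each calendar year.
    """
    space = pop0.space
    if pop0.year != config.start_year:
        raise ValueError("initial population year must equal config.start_year")

    years = np.arange(config.start_year, config.end_year + 1)
    n_years = len(years)

    ra = scenario.rate_table.compile(years)
    eff = effective_mean_arrays(ra, scenario.modifiers)
    # normalize outflows so no stock can lose more than its content;
    # gating already applied, so normalization sees the rates in force
    for flow_idx in space.flows_from:
        if not flow_idx:
            continue
        total = eff[flow_idx].sum(axis=0)
        over = total > 1.0
        if np.any(over):
            scale = np.ones_like(total)
            scale[over] = 1.0 / total[over]
            eff[flow_idx] *= scale
            logger.info("outflows normalized in %d cells", int(over.sum()))

    rr_array = joint_rr_array(space, scenario.risk_model)
    never_scale = never_mortality_scale(pop0, rr_array)
    relapse_mult = scenario.relapse_bin_multipliers

    prev = {label: np.zeros(n_years) for label in space.labels}
    prrp_prev = np.zeros(n_years)
    totals = np.zeros(n_years)
    deaths_by_year = np.zeros((n_years, 2, N_AGES))
    person_years = np.zeros(n_years)
    residuals = np.zeros(n_years)
    trajectory: list[np.ndarray] | None = [] if config.keep_trajectory else None

    pop = pop0.copy()
    min_age = config.prevalence_min_age
    for i, year in enumerate(years):
        for label in space.labels:
            prev[label][i] = prevalence(pop, label, min_age, config.dual_use_counting)
        prrp_prev[i] = _any_prrp_prevalence(pop, min_age)
        totals[i] = pop.total()
        person_years[i] = totals[i]
        if trajectory is not None:
            trajectory.append(pop.counts.copy())
        if year == config.end_year:
            break
        all_cause = life_table.mortality_for(int(year))
        pop, deaths, acct = step_year(
            pop, eff[:, i], all_cause, never_scale, rr_array, schedules, relapse_mult
        )
        deaths_by_year[i] = deaths.sum(axis=2)
        residuals[i] = acct["residual"]
        if acct["residual"] > config.conservation_tol:
            logger.warning(
                "conservation residual %.3e in year %d exceeds tolerance %.1e",
                acct["residual"],
                year,
                config.conservation_tol,
            )

    lyl_by_year, cumulative = life_years_lost(deaths_by_year, life_table)
    metadata = {
        "scenario_id": scenario.scenario_id,
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    return ProjectionResult(
        scenario_id=scenario.scenario_id,
        years=years,
        product_prevalence=prev,
        prrp_prevalence=prrp_prev,
        total_population=totals,
        deaths_by_year=deaths_by_year,
        lyl_by_year=lyl_by_year,
        cumulative_lyl=cumulative,
        person_years=person_years,
        conservation_residuals=residuals,
        metadata=metadata,
        final_population=pop,
        trajectory=trajectory,
    )


def lyl_reduction(
    result: ProjectionResult, baseline: ProjectionResult, mode: str = "expectancy"
) -> np.ndarray:
    """Reduction in life-years lost versus the baseline, per year (cumulative).

    ``expectancy`` differs the expectancy-weighted cumulative LYL series;
    ``person_years`` differs cumulative person-years lived (scenario −
    baseline), which is positive when the scenario keeps people alive.
    """
    if mode == "expectancy":
        return baseline.cumulative_lyl - result.cumulative_lyl
    if mode == "person_years":
        return np.cumsum(result.person_years) - np.cumsum(baseline.person_years)
    raise ValueError("mode must be 'expectancy' or 'person_years'")


def compare_scenarios(
    results: Sequence[ProjectionResult],
    baseline_id: str,
    decades: Sequence[int] | None = None,
    lyl_mode: str = "expectancy",
) -> pd.DataFrame:
    """Decade-sampled comparison table of prevalences and LYL reductions.

    One row per (metric, scenario); columns are the sampled years.  LYL
    reductions are reported in million person-years, mirroring the
    standard projection-table layout.
    """
    by_id = {r.scenario_id: r for r in results}
    if baseline_id not in by_id:
        raise ValueError(f"baseline scenario {baseline_id!r} not among results")
    baseline = by_id[baseline_id]
    if decades is None:
        lo = int(np.ceil(baseline.years[0] / 10) * 10)
        decades = list(range(lo, int(baseline.years[-1]) + 1, 10))

    rows = []
    for r in results:
        reduction = lyl_reduction(r, baseline, lyl_mode)
        metrics = {
            "smoking_prevalence_pct": r.smoking_prevalence,
            "prrp_prevalence_pct": r.prrp_prevalence,
            "lyl_reduction_million": reduction / 1e6,
        }
        for metric, series in metrics.items():
            row: dict = {"metric": metric, "scenario": r.scenario_id}
            for year in decades:
                row[str(year)] = r.at_year(series, year)
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(["metric", "scenario"], kind="stable").reset_index(drop=True)
    return frame
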