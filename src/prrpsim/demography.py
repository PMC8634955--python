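"""Cohort-component demography: life tables, the population array, aging,
births and net migration.

The population is a dense non-negative float array indexed by
``(gender, age, joint state, quit-time bin)``:

* gender: ``male`` (0), ``female`` (1);
* age: completed years 0–100 (a cohort reaching the top of the table is
  removed — the mortality rate at age 100 is forced to 100%);
* joint state: one stock per :class:`~prrpsim.state_space.JointState`;
* quit-time bin: years abstinent from smoking.  Bin 0 is a transient
  "quit this year" slot (also the only occupied slot for states whose
  cigarette status is not FORMER); bins 1–20 count whole years abstinent
  and bin 21 is the combined "20+" group.  A smoker who quits during
  year *t* sits in bin 0 until the aging sub-step and is therefore in
  bin 1 at the start of year *t+1*.

Counts are continuous (fractional persons): the model is a deterministic
system of difference equations, not an individual-level simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .state_space import ProductStatus, StateSpace

__all__ = [
    "GENDERS",
    "N_AGES",
    "N_BINS",
    "BIN_JUST_QUIT",
    "BIN_20_PLUS",
    "LifeTable",
    "DemographySchedules",
    "PopulationState",
    "age_population",
    "apply_births",
    "apply_migration",
]

logger = logging.getLogger(__name__)

GENDERS: tuple[str, str] = ("male", "female")
N_AGES = 101  # ages 0..100 inclusive
N_BINS = 22  # bin 0 transient/just-quit, 1..20 years abstinent, 21 = "20+"
BIN_JUST_QUIT = 0
BIN_20_PLUS = 21


@dataclass
class LifeTable:
    """Period life table: mortality probability and remaining life expectancy.

    ``mortality`` maps year -> array of shape ``(2, 101)`` (gender, age);
    years between published tables use step-wise carry-forward of the
    latest available year (and carry-backward of the earliest before it).
    ``life_expectancy`` has shape ``(2, 101)``.
    """

    mortality: dict[int, np.ndarray]
    life_expectancy: np.ndarray

    def __post_init__(self) -> None:
        if not self.mortality:
            raise ValueError("life table needs at least one year of mortality rates")
        for year, m in self.mortality.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (2, N_AGES):
                raise ValueError(f"mortality for {year} must have shape (2, {N_AGES})")
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError(f"mortality for {year} outside [0, 1]")
            if not np.allclose(m[:, -1], 1.0):
                raise ValueError("mortality rate at age 100 must be 1 for all genders")
            self.mortality[year] = m
        self.life_expectancy = np.asarray(self.life_expectancy, dtype=float)
        if self.life_expectancy.shape != (2, N_AGES):
            raise ValueError(f"life_expectancy must have shape (2, {N_AGES})")
        self._years = sorted(self.mortality)

    def mortality_for(self, year: int) -> np.ndarray:
        """Mortality rates for ``year`` (carry-forward, shape (2, 101))."""
        chosen = self._years[0]
        for y in self._years:
            if y <= year:
                chosen = y
            else:
                break
        return self.mortality[chosen]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for year in self._years:
            m = self.mortality[year]
            for g, gender in enumerate(GENDERS):
                for age in range(N_AGES):
                    rows.append(
                        {
                            "gender": gender,
                            "age": age,
                            "year": year,
                            "mortality_rate": m[g, age],
                            "life_expectancy": self.life_expectancy[g, age],
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class DemographySchedules:
    """Birth and net-migration schedules.

    ``births`` maps year -> (male, female) newborn counts;
    ``net_migration`` maps year -> signed total net migrants;
    ``migration_age_distribution`` has shape ``(2, 101)`` and sums to 1
    over genders and ages.  Years not present are treated as 0 births /
    0 net migration (carry-forward is deliberately not applied so that
    truncated schedules fail loudly in totals rather than silently
    extrapolating).
    """

    births: dict[int, tuple[float, float]] = field(default_factory=dict)
    net_migration: dict[int, float] = field(default_factory=dict)
    migration_age_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.migration_age_distribution is not None:
            dist = np.asarray(self.migration_age_distribution, dtype=float)
            if dist.shape != (2, N_AGES):
                raise ValueError(f"migration age distribution must have shape (2, {N_AGES})")
            if np.any(dist < 0):
                raise ValueError("migration age distribution must be non-negative")
            total = dist.sum()
            if total > 0 and not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError("migration age distribution must sum to 1")
            self.migration_age_distribution = dist

    def births_for(self, year: int) -> tuple[float, float]:
        return self.births.get(year, (0.0, 0.0))

    def net_migration_for(self, year: int) -> float:
        return self.net_migration.get(year, 0.0)


@dataclass
class PopulationState:
    """Person counts by (gender, age, joint state, quit-time bin)."""

    space: StateSpace
    counts: np.ndarray
    year: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (2, N_AGES, self.space.n_states, N_BINS)
        if self.counts.shape != expected:
            raise ValueError(f"counts must have shape {expected}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def empty(cls, space: StateSpace, year: int) -> "PopulationState":
        return cls(space, np.zeros((2, N_AGES, space.n_states, N_BINS)), year)

    def total(self) -> float:
        return float(self.counts.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(self.space, self.counts.copy(), self.year)

    def by_gender_age(self) -> np.ndarray:
        """Counts summed over state and bin, shape (2, 101)."""
        return self.counts.sum(axis=(2, 3))

    def cigarette_former_state_indices(self) -> list[int]:
        return [
            i
            for i, s in enumerate(self.space.states)
            if s.statuses[0] is ProductStatus.FORMER
        ]


def age_population(pop: PopulationState) -> tuple[PopulationState, float]:
    """Advance every cohort by one year of age and one year of quit time.

    The age-100 cell empties (its occupants should already have been
    removed by the 100% mortality rate; any numerical residue is
    returned as ``aged_out`` for the death ledger).  Quit-time bins of
    cigarette-FORMER states advance by one year, saturating in the "20+"
    group; the transient "just quit" bin 0 becomes bin 1.
    """
    c = pop.counts
    new = np.zeros_like(c)
    new[:, 1:] = c[:, :-1]
    aged_out = float(c[:, -1].sum())

    former = pop.cigarette_former_state_indices()
    if former:
        block = new[:, :, former, :]
        shifted = np.zeros_like(block)
        shifted[..., 1:] = block[..., :-1]
        shifted[..., BIN_20_PLUS] += block[..., BIN_20_PLUS]
        new[:, :, former, :] = shifted

    return PopulationState(pop.space, new, pop.year), aged_out


def apply_births(
    pop: PopulationState, schedules: DemographySchedules, year: int
) -> PopulationState:
    """Add newborns at age 0, all-NEVER status, split by gender."""
    male, female = schedules.births_for(year)
    if male < 0 or female < 0:
        raise ValueError("birth counts must be non-negative")
    never_idx = pop.space.state_index["N" * pop.space.n_products]
    new = pop.counts.copy()
    new[0, 0, never_idx, BIN_JUST_QUIT] += male
    new[1, 0, never_idx, BIN_JUST_QUIT] += female
    return PopulationState(pop.space, new, pop.year)


def apply_migration(
    pop: PopulationState, schedules: DemographySchedules, year: int
) -> tuple[PopulationState, float]:
    """Add (or remove) net migrants per the age distribution.

    Migrants take on the product-status composition of the resident
    population of the same gender and age — a neutral assumption that
    leaves prevalence untouched.  Migrants into an empty cell enter as
    all-NEVER.  Removals larger than a cell are clamped to empty it, with
    a logged warning.  Returns the new population and the net migration
    actually applied (after clamping), for conservation accounting.
    """
    net = schedules.net_migration_for(year)
    if net == 0 or schedules.migration_age_distribution is None:
        return pop.copy(), 0.0

    dist = schedules.migration_age_distribution
    cell_net = net * dist  # (2, 101), signed
    counts = pop.counts.copy()
    cell_tot = pop.counts.sum(axis=(2, 3))  # (2, 101)
    never_idx = pop.space.state_index["N" * pop.space.n_products]

    applied = 0.0
    clamped_cells = 0
    for g in range(2):
        for a in range(N_AGES):
            delta = cell_net[g, a]
            if delta == 0:
                continue
            tot = cell_tot[g, a]
            if delta > 0:
                if tot > 0:
                    counts[g, a] += delta * (pop.counts[g, a] / tot)
                else:
                    counts[g, a, never_idx, BIN_JUST_QUIT] += delta
                applied += delta
            else:
                removal = min(-delta, tot)
                if removal < -delta:
                    clamped_cells += 1
                if tot > 0 and removal > 0:
                    counts[g, a] -= removal * (pop.counts[g, a] / tot)
                applied -= removal
    if clamped_cells:
        logger.warning(
            "migration removal clamped to empty %d (gender, age) cells in year %d",
            clamped_cells,
            year,
        )
    counts = np.clip(counts, 0.0, None)  # guard tiny negative float residue
    return PopulationState(pop.space, counts, pop.year), applied
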