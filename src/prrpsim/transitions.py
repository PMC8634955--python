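"""Transition-probability tables, scenario-time modifiers, pseudo-PRRP
blending and initiation calibration.

Rates are annual transition *probabilities* (not instantaneous hazards),
applied once per 1-year step.  A :class:`RateTable` is a list of entry
rows, each giving the (mean, lo95, hi95) probability of one flow for a
gender (or both), an age band and a year (or all years); bands are
expanded by repetition and year-specific rows carry forward until
superseded.  Compilation produces dense per-flow arrays over a year
range (:class:`RateArrays`) that the simulation engine consumes.

Scenario-time modifiers gate every flow that touches a product to zero
before that product's market-introduction year, and optionally apply a
compounding decline to cigarette initiation: with decline rate *r*
starting in year *s*, the initiation probability in year *y ≥ s* is
multiplied by ``(1 - r)**(y - s)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .demography import GENDERS, N_AGES, N_BINS, BIN_20_PLUS
from .state_space import FlowSpec, StateSpace

__all__ = [
    "TransitionProbability",
    "RateEntry",
    "RateTable",
    "RateArrays",
    "ScenarioModifiers",
    "effective_rate",
    "effective_mean_arrays",
    "combine_pseudo_prrp",
    "combine_pseudo_risk",
    "normalize_outflows",
    "calibrate_initiation_from_prevalence",
    "geometric_relapse_multipliers",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransitionProbability:
    """An annual transition probability with its 95% confidence interval."""

    mean: float
    lo95: float
    hi95: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", float(self.mean))
        object.__setattr__(self, "lo95", float(self.lo95))
        object.__setattr__(self, "hi95", float(self.hi95))
        if not (0.0 <= self.lo95 <= self.mean <= self.hi95 <= 1.0):
            raise ValueError(
                f"require 0 <= lo95 <= mean <= hi95 <= 1, got "
                f"({self.lo95}, {self.mean}, {self.hi95})"
            )


@dataclass(frozen=True)
class RateEntry:
    """One rate-table row: a flow, a (gender, age-band, year) cell, a probability.

    ``gender`` is ``"male"``, ``"female"`` or ``"*"``; ``year`` is a
    calendar year or ``None`` for all years; the age band is inclusive.
    """

    flow_key: str
    gender: str
    age_lo: int
    age_hi: int
    year: int | None
    prob: TransitionProbability

    def __post_init__(self) -> None:
        if self.gender not in (*GENDERS, "*"):
            raise ValueError(f"gender must be one of {GENDERS} or '*', got {self.gender!r}")
        if not (0 <= self.age_lo <= self.age_hi <= N_AGES - 1):
            raise ValueError(f"bad age band [{self.age_lo}, {self.age_hi}]")


@dataclass
class RateTable:
    """Transition probabilities for the flows of one state space."""

    space: StateSpace
    entries: list[RateEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.flow_key not in self.space.flow_index:
                raise ValueError(f"unknown flow key {e.flow_key!r}")

    def add(
        self,
        flow_key: str,
        mean: float,
        lo95: float | None = None,
        hi95: float | None = None,
        gender: str = "*",
        age_lo: int = 0,
        age_hi: int = N_AGES - 1,
        year: int | None = None,
    ) -> None:
        lo95 = mean if lo95 is None else lo95
        hi95 = mean if hi95 is None else hi95
        if flow_key not in self.space.flow_index:
            raise ValueError(f"unknown flow key {flow_key!r}")
        self.entries.append(
            RateEntry(flow_key, gender, age_lo, age_hi, year, TransitionProbability(mean, lo95, hi95))
        )

    def compile(self, years: np.ndarray | list[int]) -> "RateArrays":
        """Dense (flow, year, gender, age) arrays over ``years``.

        Flows without entries default to probability 0.  Wildcard-year
        rows are applied first, then year-specific rows in ascending
        year order, each carrying forward to all later years until
        overridden.
        """
        years = np.asarray(years, dtype=int)
        shape = (self.space.n_flows, len(years), 2, N_AGES)
        mean = np.zeros(shape)
        lo = np.zeros(shape)
        hi = np.zeros(shape)
        ordered = [e for e in self.entries if e.year is None] + sorted(
            (e for e in self.entries if e.year is not None), key=lambda e: e.year
        )
        for e in ordered:
            fi = self.space.flow_index[e.flow_key]
            ymask = slice(None) if e.year is None else years >= e.year
            gsel = slice(None) if e.gender == "*" else [GENDERS.index(e.gender)]
            asel = slice(e.age_lo, e.age_hi + 1)
            mean[fi, ymask, gsel, asel] = e.prob.mean
            lo[fi, ymask, gsel, asel] = e.prob.lo95
            hi[fi, ymask, gsel, asel] = e.prob.hi95
        return RateArrays(self.space, years, mean, lo, hi)


@dataclass
class RateArrays:
    """Compiled dense probabilities: shape (n_flows, n_years, 2, 101)."""

    space: StateSpace
    years: np.ndarray
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not compiled")
        return int(idx[0])


@dataclass(frozen=True)
class ScenarioModifiers:
    """Scenario-time gates and the optional initiation decline.

    ``product_intro_year`` maps product label -> first calendar year the
    product is on the market; products not listed are available from the
    model start.  Every flow that moves a product is forced to 0 before
    its introduction year (so its stocks stay empty), and the cigarette
    never→current initiation probability is multiplied by
    ``(1 - initiation_decline_rate)**(year - initiation_decline_start)``
    from the start year onwards.
    """

    product_intro_year: dict[str, int] = field(default_factory=dict)
    initiation_decline_rate: float = 0.0
    initiation_decline_start: int = 2020

    def __post_init__(self) -> None:
        if not (0.0 <= self.initiation_decline_rate < 1.0):
            raise ValueError("initiation_decline_rate must be in [0, 1)")

    def intro_year_of(self, label: str) -> int | None:
        return self.product_intro_year.get(label)

    def decline_multiplier(self, year: int) -> float:
        if self.initiation_decline_rate == 0.0 or year < self.initiation_decline_start:
            return 1.0
        return (1.0 - self.initiation_decline_rate) ** (year - self.initiation_decline_start)


def _flow_gate_year(flow: FlowSpec, mods: ScenarioModifiers) -> int | None:
    """First year the flow is allowed, or None if always allowed."""
    labels = flow.from_state.product_labels
    intro_years = [
        mods.product_intro_year[labels[i]]
        for i in flow.changed_products
        if labels[i] in mods.product_intro_year
    ]
    return max(intro_years) if intro_years else None


def effective_mean_arrays(ra: RateArrays, mods: ScenarioModifiers) -> np.ndarray:
    """Mean probabilities with intro-year gates and initiation decline applied.

    Returns an array shaped like ``ra.mean``.  The decline multiplier is
    applied to flows whose cigarette (product 0) move is ``initiate``.
    """
    eff = ra.mean.copy()
    years = ra.years
    for fi, flow in enumerate(ra.space.flows):
        gate = _flow_gate_year(flow, mods)
        if gate is not None:
            eff[fi, years < gate] = 0.0
        if flow.move_of(0) == "initiate" and mods.initiation_decline_rate > 0:
            mult = np.array([mods.decline_multiplier(int(y)) for y in years])
            eff[fi] *= mult[:, None, None]
    return eff


def effective_rate(
    table: RateTable,
    flow: FlowSpec | str,
    gender: str,
    age: int,
    year: int,
    mods: ScenarioModifiers | None = None,
) -> float:
    """Scalar effective mean probability of one flow in one cell.

    Base mean rate × intro-year gate × cigarette-initiation decline
    multiplier.  Flows absent from the table default to 0.
    """
    mods = mods or ScenarioModifiers()
    key = flow if isinstance(flow, str) else flow.key
    fi = table.space.flow_index[key]
    ra = table.compile([year])
    eff = effective_mean_arrays(ra, mods)
    return float(eff[fi, 0, GENDERS.index(gender), age])


def combine_pseudo_prrp(table_a: RateTable, table_b: RateTable, weight_a: float) -> RateTable:
    """Blend two structurally identical rate tables into a pseudo-PRRP table.

    Every corresponding probability (mean, lo95 and hi95 alike) becomes
    ``weight_a * A + (1 - weight_a) * B``.  Entries are matched by
    (flow, gender, age band, year); mismatched entry sets are rejected.
    """
    if not (0.0 <= weight_a <= 1.0):
        raise ValueError("weight_a must be in [0, 1]")
    if table_a.space.n_products != table_b.space.n_products:
        raise ValueError("tables must describe structurally identical models")

    def keyed(table: RateTable) -> dict[tuple, RateEntry]:
        out: dict[tuple, RateEntry] = {}
        for e in table.entries:
            k = (e.flow_key, e.gender, e.age_lo, e.age_hi, e.year)
            if k in out:
                raise ValueError(f"duplicate entry cell {k} prevents blending")
            out[k] = e
        return out

    a, b = keyed(table_a), keyed(table_b)
    if set(a) != set(b):
        missing = set(a).symmetric_difference(b)
        raise ValueError(f"mismatched flow sets; {len(missing)} unmatched entry cells")

    w = weight_a
    blended = [
        replace(
            ea,
            prob=TransitionProbability(
                mean=w * ea.prob.mean + (1 - w) * b[k].prob.mean,
                lo95=w * ea.prob.lo95 + (1 - w) * b[k].prob.lo95,
                hi95=w * ea.prob.hi95 + (1 - w) * b[k].prob.hi95,
            ),
        )
        for k, ea in a.items()
    ]
    return RateTable(table_a.space, blended)


def combine_pseudo_risk(f_a: float, f_b: float, weight_a: float) -> float:
    """Weight-blend two product risk fractions: ``w·f_A + (1-w)·f_B``.

    With the e-cigarette (5%) and THP (10%) excess-risk fractions this
    gives 7.5% at equal weights and 6.85% at a 63:37 split.
    """
    if not (0.0 <= weight_a <= 1.0):
        raise ValueError("weight_a must be in [0, 1]")
    return weight_a * f_a + (1.0 - weight_a) * f_b


def normalize_outflows(ra: RateArrays | RateTable, years: list[int] | None = None) -> RateArrays:
    """Rescale outflows so no stock loses more than its whole content.

    For every (state, gender, age, year) whose mean outflow
    probabilities sum to S > 1, all outflows from that stock (and their
    CI bounds, to preserve lo ≤ mean ≤ hi) are scaled by 1/S.  Accepts a
    compiled :class:`RateArrays`, or a :class:`RateTable` plus the years
    to compile.
    """
    if isinstance(ra, RateTable):
        if years is None:
            raise ValueError("years required when normalizing a RateTable")
        ra = ra.compile(years)
    mean = ra.mean.copy()
    lo = ra.lo95.copy()
    hi = ra.hi95.copy()
    n_scaled = 0
    for si, flow_idx in enumerate(ra.space.flows_from):
        if not flow_idx:
            continue
        total = mean[flow_idx].sum(axis=0)  # (years, gender, age)
        over = total > 1.0
        if np.any(over):
            scale = np.ones_like(total)
            scale[over] = 1.0 / total[over]
            mean[flow_idx] *= scale
            lo[flow_idx] *= scale
            hi[flow_idx] *= scale
            n_scaled += int(over.sum())
    if n_scaled:
        logger.info("normalized outflows in %d (state, year, gender, age) cells", n_scaled)
    return RateArrays(ra.space, ra.years, mean, lo, hi)


def calibrate_initiation_from_prevalence(
    ever_prevalence: np.ndarray, age_window: tuple[int, int] = (11, 30)
) -> np.ndarray:
    """Initiation hazards reproducing an ever-use prevalence age curve.

    Given ever-use prevalence ``E`` per (gender, age 0–100), the age-*a*
    hazard is ``h(a) = (E(a+1) - E(a)) / (1 - E(a))``, floored at 0,
    inside the initiation window (inclusive) and 0 outside.  Simulating
    a never/ever cohort with these hazards and no differential mortality
    reproduces the input curve exactly.
    """
    E = np.asarray(ever_prevalence, dtype=float)
    if E.shape != (2, N_AGES):
        raise ValueError(f"ever_prevalence must have shape (2, {N_AGES})")
    if np.any(E >= 1.0):
        raise ValueError("ever-prevalence must be < 1 at every age")
    if np.any(E < 0.0):
        raise ValueError("ever-prevalence must be non-negative")
    lo_age, hi_age = age_window
    h = np.zeros_like(E)
    diff = E[:, 1:] - E[:, :-1]
    if np.any(diff[:, lo_age : hi_age + 1] < 0):
        logger.warning("ever-prevalence decreases inside initiation window; hazards floored at 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        hz = np.clip(diff, 0.0, None) / (1.0 - E[:, :-1])
    h[:, :-1] = np.nan_to_num(hz, nan=0.0, posinf=0.0)
    mask = np.zeros(N_AGES, dtype=bool)
    mask[lo_age : hi_age + 1] = True
    h[:, ~mask] = 0.0
    return h


def geometric_relapse_multipliers(ratio: float = 0.85) -> np.ndarray:
    """Default per-quit-time-bin relapse multipliers (geometric decline).

    Bin *b* (years abstinent) multiplies the base relapse probability by
    ``ratio**(b - 1)``; the 20+ bin uses ``ratio**20``.  Bin 0 (the
    transient just-quit slot) is never occupied at transition time and
    keeps multiplier 1.
    """
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must be in (0, 1]")
    mult = np.ones(N_BINS)
    bins = np.arange(1, BIN_20_PLUS)
    mult[1:BIN_20_PLUS] = ratio ** (bins - 1)
    mult[BIN_20_PLUS] = ratio**20
    return mult
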