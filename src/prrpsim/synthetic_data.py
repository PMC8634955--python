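"""Seeded generator of Italy-shaped synthetic fixtures.

Real runs of the model consume national statistics (a population
pyramid, period life tables, birth/migration schedules, smoking
prevalence with a quit-time distribution, and per-flow transition
probabilities with confidence intervals).  This module fabricates a
complete, schema-valid input bundle with the same shape — ages 0–100,
two genders, a Gompertz-like mortality age curve, a logistic ever-
smoking curve calibrated so that adult (14+) smoking prevalence hits a
target level (19.7% by default), and two-product transition tables in
two styles:

* ``ecig_like`` — a PRRP with appreciable never-user initiation and
  moderate smoker switching;
* ``thp_like``  — the same table but with never-user initiation a
  quarter of the e-cigarette value and smoker→PRRP switching double it,
  reflecting the relative Japanese-THP vs US-e-cigarette dynamics.

Everything is deterministic given the spec's seed.  These fixtures are
synthetic: they emulate the *structure* of the public inputs, not their
values, so simulations on them demonstrate model mechanics (orderings,
conservation, calibration), never country-level projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import (
    GENDERS,
    N_AGES,
    N_BINS,
    DemographySchedules,
    LifeTable,
)
from .io import InputBundle
from .state_space import ProductStatus, StateSpace
from .transitions import RateTable, calibrate_initiation_from_prevalence, combine_pseudo_risk

__all__ = [
    "FixtureSpec",
    "generate_fixtures",
    "generate_two_product_rates",
    "generate_cigarette_rates",
]

TWO_PRODUCT_LABELS = ("cigarette", "prrp")


@dataclass
class FixtureSpec:
    """Parameters of the synthetic input bundle (all rates are annual)."""

    seed: int = 0
    population_size: float = 59_000_000.0  # Italy-scale
    start_year: int = 2001
    end_year: int = 2100
    target_smoking_prevalence_pct: float = 19.7  # age 14+, both genders

    # mortality: infant hump + Gompertz baseline, per gender (male, female)
    gompertz_a: tuple[float, float] = (4.0e-5, 2.0e-5)
    gompertz_b: float = 0.095
    infant_mortality: float = 0.004

    # ever-smoking logistic curve and current-share decline with age
    ever_max: tuple[float, float] = (0.55, 0.42)
    ever_midpoint_age: float = 17.0
    ever_scale_age: float = 2.5
    current_share_peak: float = 0.92
    current_share_decline_per_year: float = 0.012  # beyond age 30

    quit_dist_geometric_p: float = 0.08
    birth_rate: float = 0.008  # births per person per year
    migration_rate: float = 0.0025  # net migrants per person per year
    pyramid_jitter: float = 0.02  # seeded multiplicative noise on the pyramid

    # cigarette transitions
    cig_quit: float = 0.04
    cig_relapse: float = 0.05
    dual_quit_smoking: float = 0.08  # dual users quit smoking faster (switching)
    initiation_window: tuple[int, int] = (11, 30)

    # PRRP transitions (e-cigarette-like baseline)
    ecig_never_init: float = 0.006
    ecig_smoker_switch: float = 0.025
    prrp_quit: float = 0.20
    prrp_relapse: float = 0.05
    prrp_init_age_hi: int = 40
    thp_never_init_factor: float = 0.25  # THP never-initiation = 1/4 of e-cig
    thp_smoker_switch_factor: float = 2.0  # THP smoker-switching = 2x e-cig
    ci_rel_width: float = 0.5  # lo/hi = mean * (1 -/+ width) for PRRP flows

    # risk
    rr_bands: list = field(
        default_factory=lambda: [
            ("*", 0, 34, 1.5),
            ("*", 35, 54, 2.8),
            ("*", 55, 74, 2.5),
            ("*", 75, 100, 1.8),
        ]
    )
    decay_halflife: float = 10.0
    f_ecig: float = 0.05
    f_thp: float = 0.10
    pseudo_weight_5050: float = 0.50
    pseudo_weight_6337: float = 0.63
    ecig_intro: int = 2010
    thp_intro: int = 2014


def _mortality_curve(spec: FixtureSpec) -> np.ndarray:
    ages = np.arange(N_AGES, dtype=float)
    m = np.zeros((2, N_AGES))
    for g in range(2):
        gompertz = spec.gompertz_a[g] * np.exp(spec.gompertz_b * ages)
        infant = spec.infant_mortality * np.exp(-ages / 1.5)
        m[g] = np.clip(infant + gompertz, 0.0, 1.0)
    m[:, -1] = 1.0
    return m


def _life_expectancy_from_mortality(m: np.ndarray) -> np.ndarray:
    """Period remaining life expectancy from qx, closed at age 100."""
    e = np.zeros_like(m)
    for g in range(2):
        l = np.ones(N_AGES + 1)
        for a in range(N_AGES):
            l[a + 1] = l[a] * (1.0 - m[g, a])
        # person-years lived: survivors to a+1 plus half a year for deaths in [a, a+1)
        person_years = l[1:] + 0.5 * (l[:-1] - l[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            tail = np.cumsum(person_years[::-1])[::-1]
            e[g] = np.where(l[:-1] > 0, tail / l[:-1], 0.0)
    return e


def _pyramid(spec: FixtureSpec, m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    ages = np.arange(N_AGES, dtype=float)
    pyr = np.zeros((2, N_AGES))
    bulge = 1.0 + 0.35 * np.exp(-(((ages - 45.0) / 22.0) ** 2))  # middle-aged bulge
    for g in range(2):
        survivorship = np.cumprod(np.concatenate(([1.0], 1.0 - m[g, :-1])))
        pyr[g] = survivorship * bulge
    pyr *= 1.0 + spec.pyramid_jitter * rng.standard_normal(pyr.shape)
    pyr = np.clip(pyr, 0.0, None)
    if pyr.sum() > 0:
        pyr *= spec.population_size / pyr.sum()
    return pyr


def _smoking_curves(
    spec: FixtureSpec, pyramid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ever/current/former prevalence per (gender, age), calibrated to target."""
    ages = np.arange(N_AGES, dtype=float)
    ever = np.zeros((2, N_AGES))
    for g in range(2):
        ever[g] = spec.ever_max[g] / (
            1.0 + np.exp(-(ages - spec.ever_midpoint_age) / spec.ever_scale_age)
        )
    share = np.clip(
        spec.current_share_peak
        - spec.current_share_decline_per_year * np.clip(ages - 30.0, 0.0, None),
        0.25,
        1.0,
    )
    current = ever * share[None, :]

    eligible = pyramid[:, 14:].sum()
    if eligible > 0 and spec.target_smoking_prevalence_pct > 0:
        achieved = 100.0 * (current[:, 14:] * pyramid[:, 14:]).sum() / eligible
        k = spec.target_smoking_prevalence_pct / achieved
        ever = np.clip(ever * k, 0.0, 0.97)
        current = np.clip(current * k, 0.0, ever)
    elif spec.target_smoking_prevalence_pct == 0:
        ever = np.zeros_like(ever)
        current = np.zeros_like(current)
    former = ever - current
    return ever, current, former


def _quit_distribution(spec: FixtureSpec) -> np.ndarray:
    p = spec.quit_dist_geometric_p
    bins = np.arange(1, N_BINS - 1)  # 1..20
    weights = (1.0 - p) ** (bins - 1) * p
    dist = np.zeros(N_BINS - 1)
    dist[:-1] = weights
    dist[-1] = (1.0 - p) ** 20  # mass beyond 20 years -> "20+"
    return dist / dist.sum()


def _cigarette_entries(
    table: RateTable, h: np.ndarray, spec: FixtureSpec
) -> None:
    """Cigarette initiate/quit/relapse rows, one per PRRP status context."""
    space = table.space
    lo_age, hi_age = spec.initiation_window
    for state in space.states:
        cig = state.statuses[0]
        new_status, kind = {
            ProductStatus.NEVER: (ProductStatus.CURRENT, "initiate"),
            ProductStatus.CURRENT: (ProductStatus.FORMER, "quit"),
            ProductStatus.FORMER: (ProductStatus.CURRENT, "relapse"),
        }[cig]
        target = state.statuses[:0] + (new_status,) + state.statuses[1:]
        key = f"{state.id}>{''.join(s.code for s in target)}"
        if kind == "initiate":
            for g, gender in enumerate(GENDERS):
                for age in range(lo_age, hi_age + 1):
                    if h[g, age] > 0:
                        table.add(key, h[g, age], gender=gender, age_lo=age, age_hi=age)
        elif kind == "quit":
            # dual users quit smoking faster (switching to the other product)
            dual = any(s is ProductStatus.CURRENT for s in state.statuses[1:])
            rate = spec.dual_quit_smoking if dual else spec.cig_quit
            table.add(key, rate, age_lo=14, age_hi=N_AGES - 1)
        else:
            table.add(key, spec.cig_relapse, age_lo=14, age_hi=N_AGES - 1)


def _calibrated_initiation(spec: FixtureSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    _, current, former = _smoking_curves(spec, _pyramid(spec, _mortality_curve(spec), rng))
    return calibrate_initiation_from_prevalence(current + former, spec.initiation_window)


def generate_cigarette_rates(
    spec: FixtureSpec | None = None, labels: tuple[str, ...] = ("cigarette",)
) -> RateTable:
    """Cigarette-only transitions on a state space of any product count.

    Initiation hazards are calibrated from the synthetic ever-smoking
    curve; quit and relapse are flat adult rates.  Rows are written for
    every context of the other products, which all carry zero rates —
    useful both as the smoking-only scenario and as the cigarette core
    of multi-product tables.
    """
    spec = spec or FixtureSpec()
    table = RateTable(StateSpace(labels))
    _cigarette_entries(table, _calibrated_initiation(spec), spec)
    return table


def generate_two_product_rates(style: str, spec: FixtureSpec | None = None) -> RateTable:
    """Two-product (cigarette + PRRP) rate table in one of two styles.

    ``thp_like`` differs from ``ecig_like`` only structurally as the
    relative Japan/USA dynamics suggest: never-user PRRP initiation is
    ``thp_never_init_factor`` (default ¼) of the e-cigarette value and
    smoker→PRRP switching is ``thp_smoker_switch_factor`` (default 2×)
    the e-cigarette value; all other flows are shared.  PRRP rows carry
    symmetric relative confidence intervals of width ``ci_rel_width``.
    """
    spec = spec or FixtureSpec()
    if style not in ("ecig_like", "thp_like"):
        raise ValueError("style must be 'ecig_like' or 'thp_like'")
    table = generate_cigarette_rates(spec, TWO_PRODUCT_LABELS)

    never_init = spec.ecig_never_init
    switch = spec.ecig_smoker_switch
    if style == "thp_like":
        never_init *= spec.thp_never_init_factor
        switch *= spec.thp_smoker_switch_factor

    w = spec.ci_rel_width

    def ci(mean: float) -> tuple[float, float]:
        return max(0.0, mean * (1 - w)), min(1.0, mean * (1 + w))

    lo, hi = ci(never_init)
    table.add("NN>NC", never_init, lo, hi, age_lo=11, age_hi=spec.prrp_init_age_hi)
    lo, hi = ci(switch)
    table.add("CN>CC", switch, lo, hi, age_lo=14, age_hi=N_AGES - 1)
    for ctx in "NCF":  # PRRP quit and relapse in every cigarette context
        lo, hi = ci(spec.prrp_quit)
        table.add(f"{ctx}C>{ctx}F", spec.prrp_quit, lo, hi, age_lo=11, age_hi=N_AGES - 1)
        lo, hi = ci(spec.prrp_relapse)
        table.add(f"{ctx}F>{ctx}C", spec.prrp_relapse, lo, hi, age_lo=11, age_hi=N_AGES - 1)
    return table


def _scenario_configs(spec: FixtureSpec) -> dict[str, dict]:
    base: dict[str, dict] = {
        "s1_smoking_only": {
            "products": ["cigarette"],
            "rate_table": "smoking_only",
        },
        "s2_ecig": {
            "products": list(TWO_PRODUCT_LABELS),
            "rate_table": "ecig",
            "intro_years": {"prrp": spec.ecig_intro},
            "risk_fractions": {"prrp": spec.f_ecig},
        },
        "s3_thp": {
            "products": list(TWO_PRODUCT_LABELS),
            "rate_table": "thp",
            "intro_years": {"prrp": spec.thp_intro},
            "risk_fractions": {"prrp": spec.f_thp},
        },
        "s4_pseudo_5050": {
            "products": list(TWO_PRODUCT_LABELS),
            "pseudo": {"table_a": "ecig", "table_b": "thp", "weight_a": spec.pseudo_weight_5050},
            "intro_years": {"prrp": spec.ecig_intro},
            "risk_fractions": {
                "prrp": combine_pseudo_risk(spec.f_ecig, spec.f_thp, spec.pseudo_weight_5050)
            },
        },
        "s5_pseudo_6337": {
            "products": list(TWO_PRODUCT_LABELS),
            "pseudo": {"table_a": "ecig", "table_b": "thp", "weight_a": spec.pseudo_weight_6337},
            "intro_years": {"prrp": spec.ecig_intro},
            "risk_fractions": {
                "prrp": combine_pseudo_risk(spec.f_ecig, spec.f_thp, spec.pseudo_weight_6337)
            },
        },
    }
    declined: dict[str, dict] = {}
    for name, cfg in base.items():
        d = dict(cfg)
        d["initiation_decline_rate"] = 0.03
        d["initiation_decline_start"] = 2020
        declined[f"{name}_decline"] = d
    return base | declined


def generate_fixtures(spec: FixtureSpec | None = None) -> InputBundle:
    """Generate the full synthetic input bundle for one seed.

    Deterministic given ``spec`` (byte-identical files when written
    twice); with ``population_size = 0`` the bundle is empty but still
    schema-valid.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)

    m = _mortality_curve(spec)
    expectancy = _life_expectancy_from_mortality(m)
    life_table = LifeTable({spec.start_year: m}, expectancy)
    pyramid = _pyramid(spec, m, rng)
    ever, current, former = _smoking_curves(spec, pyramid)
    quit_dist = _quit_distribution(spec)

    years = range(spec.start_year, spec.end_year + 1)
    births_total = spec.birth_rate * spec.population_size
    migration_total = spec.migration_rate * spec.population_size
    ages = np.arange(N_AGES, dtype=float)
    mig_shape = np.exp(-(((ages - 27.0) / 12.0) ** 2))
    mig_shape[:15] = 0.0
    mig_dist = np.stack([mig_shape, mig_shape])
    if mig_dist.sum() > 0:
        mig_dist /= mig_dist.sum()
    schedules = DemographySchedules(
        births={y: (0.512 * births_total, 0.488 * births_total) for y in years},
        net_migration={y: migration_total for y in years},
        migration_age_distribution=mig_dist if migration_total > 0 else None,
    )

    rate_tables = {
        "smoking_only": generate_cigarette_rates(spec),
        "ecig": generate_two_product_rates("ecig_like", spec),
        "thp": generate_two_product_rates("thp_like", spec),
    }
    risk_params = {
        "rr_current_smoker": [tuple(b) for b in spec.rr_bands],
        "decay_halflife": spec.decay_halflife,
        "twentyplus_quit_years": 25.0,
        "prrp_former_quit_years": 1.0,
    }
    return InputBundle(
        pyramid=pyramid,
        life_table=life_table,
        schedules=schedules,
        current_prev=current,
        former_prev=former,
        quit_time_distribution=quit_dist,
        rate_tables=rate_tables,
        risk_params=risk_params,
        scenarios=_scenario_configs(spec),
        start_year=spec.start_year,
    )
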