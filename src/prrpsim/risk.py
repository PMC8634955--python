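"""Product-status-specific mortality risk.

Current smokers carry an all-cause relative risk ``rr >= 1`` versus
never-smokers (by gender and age band).  A potentially reduced-risk
product (PRRP) carries a configurable *fraction f* of smoking's excess
risk: its current-user relative risk is ``1 + f * (rr - 1)`` (so a 5%
risk fraction on rr = 2 gives 1.05, never-users stay at 1).  After
quitting, excess risk decays along a negative-exponential with a
configurable half-life: ``1 + (rr - 1) * 2**(-t / halflife)`` after *t*
years abstinent.  Dual use is scored by the riskiest product (smoking
dominates), and the never-smoker mortality rate is derived from the
observed all-cause rate by prevalence-weighted decomposition so that the
stratified model reproduces the life table exactly at initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import (
    BIN_20_PLUS,
    BIN_JUST_QUIT,
    GENDERS,
    N_AGES,
    N_BINS,
    PopulationState,
)
from .state_space import JointState, ProductStatus, StateSpace

__all__ = [
    "RiskModel",
    "former_excess_rr",
    "joint_state_rr",
    "joint_rr_array",
    "derive_never_mortality",
    "never_mortality_scale",
    "apply_status_mortality",
]


@dataclass
class RiskModel:
    """All-cause mortality risk attached to product-use statuses.

    Parameters
    ----------
    rr_current_smoker:
        Entries ``(gender, age_lo, age_hi, rr)`` with gender ``"*"``,
        ``"male"`` or ``"female"``; bands expand by repetition.
    decay_halflife:
        Years for half the excess risk of a former user to disappear.
    prrp_excess_fraction:
        Fraction of smoking's *excess* risk (rr − 1) carried by each
        non-cigarette product, keyed by product label.  The cigarette
        itself has fraction 1 by definition.
    twentyplus_quit_years:
        Representative abstinence time (years) at which the open-ended
        "20+" quit-time bin is evaluated.
    prrp_former_quit_years:
        Abstinence time assumed for a former PRRP user in a joint state
        that carries no cigarette quit-time clock (cigarette status not
        FORMER, so no bin ledger exists for the cell).
    dual_use_rule:
        Only ``"max_product_risk"`` is supported: a person's relative
        risk is 1 plus the largest single-product excess.
    """

    rr_current_smoker: list[tuple[str, int, int, float]]
    decay_halflife: float = 10.0
    prrp_excess_fraction: dict[str, float] = field(default_factory=dict)
    twentyplus_quit_years: float = 25.0
    prrp_former_quit_years: float = 1.0
    dual_use_rule: str = "max_product_risk"

    def __post_init__(self) -> None:
        if self.decay_halflife <= 0:
            raise ValueError("decay_halflife must be positive")
        if self.dual_use_rule != "max_product_risk":
            raise ValueError(f"unsupported dual_use_rule {self.dual_use_rule!r}")
        for label, f in self.prrp_excess_fraction.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"excess fraction for {label!r} must be in [0, 1]")
        for gender, age_lo, age_hi, rr in self.rr_current_smoker:
            if gender not in (*GENDERS, "*"):
                raise ValueError(f"bad gender {gender!r} in rr entry")
            if not (0 <= age_lo <= age_hi <= N_AGES - 1):
                raise ValueError(f"bad rr age band [{age_lo}, {age_hi}]")
            if rr < 1.0:
                raise ValueError("current-smoker relative risk must be >= 1")

    def excess_fraction(self, label: str, product_index: int) -> float:
        if product_index == 0:
            return 1.0
        return self.prrp_excess_fraction.get(label, 0.0)

    def rr_smoker_grid(self) -> np.ndarray:
        """Current-smoker relative risk per (gender, age), shape (2, 101)."""
        rr = np.ones((2, N_AGES))
        for gender, age_lo, age_hi, value in self.rr_current_smoker:
            gsel = slice(None) if gender == "*" else [GENDERS.index(gender)]
            rr[gsel, age_lo : age_hi + 1] = value
        return rr


def former_excess_rr(rr: float, quit_years: float, halflife: float) -> float:
    """Relative risk of a former user after ``quit_years`` abstinent.

    Negative-exponential decay of the excess:
    ``1 + (rr - 1) * 2**(-quit_years / halflife)``.
    """
    if halflife <= 0:
        raise ValueError("halflife must be positive")
    if quit_years < 0:
        raise ValueError("quit_years must be non-negative")
    return 1.0 + (rr - 1.0) * 2.0 ** (-quit_years / halflife)


def _bin_quit_years(quit_bin: int, model: RiskModel) -> float:
    """Years abstinent represented by a cigarette quit-time bin."""
    if quit_bin == BIN_JUST_QUIT:
        return 0.0
    if quit_bin == BIN_20_PLUS:
        return model.twentyplus_quit_years
    return float(quit_bin)


def joint_state_rr(
    state: JointState,
    quit_bin: int,
    model: RiskModel,
    gender: str,
    age: int,
) -> float:
    """Relative risk of one joint product-use state.

    Per-product excess: ``f_p * (rr - 1)`` while CURRENT (``f`` = 1 for
    the cigarette), decayed per :func:`former_excess_rr` while FORMER
    (all former clocks share the cigarette quit-time bin ledger; states
    without one use the model's representative PRRP quit time), and 0
    while NEVER.  Combined RR = 1 + max over products of the excesses.
    """
    rr = model.rr_smoker_grid()[GENDERS.index(gender), age]
    base_excess = rr - 1.0
    has_clock = state.statuses[0] is ProductStatus.FORMER
    best = 0.0
    for i, (label, status) in enumerate(zip(state.product_labels, state.statuses)):
        f = model.excess_fraction(label, i)
        if status is ProductStatus.CURRENT:
            excess = f * base_excess
        elif status is ProductStatus.FORMER:
            t = _bin_quit_years(quit_bin, model) if has_clock else model.prrp_former_quit_years
            excess = f * base_excess * 2.0 ** (-t / model.decay_halflife)
        else:
            excess = 0.0
        best = max(best, excess)
    return 1.0 + best


def joint_rr_array(space: StateSpace, model: RiskModel) -> np.ndarray:
    """Relative risks on the full grid, shape (2, 101, n_states, n_bins).

    Vectorised equivalent of :func:`joint_state_rr` used by the engine.
    """
    rr = model.rr_smoker_grid()  # (2, 101)
    base_excess = rr - 1.0  # (2, 101)

    # decay factor per bin for states that carry a cigarette quit clock
    quit_years = np.array(
        [_bin_quit_years(b, model) for b in range(N_BINS)], dtype=float
    )
    decay_binned = 2.0 ** (-quit_years / model.decay_halflife)  # (n_bins,)
    decay_unclocked = 2.0 ** (-model.prrp_former_quit_years / model.decay_halflife)

    out = np.ones((2, N_AGES, space.n_states, N_BINS))
    for si, state in enumerate(space.states):
        has_clock = state.statuses[0] is ProductStatus.FORMER
        # max over products of the excess multiplier (applied to rr - 1),
        # as a function of bin: shape (n_bins,)
        mult = np.zeros(N_BINS)
        for i, (label, status) in enumerate(zip(state.product_labels, state.statuses)):
            f = model.excess_fraction(label, i)
            if status is ProductStatus.CURRENT:
                m = np.full(N_BINS, f)
            elif status is ProductStatus.FORMER:
                m = f * (decay_binned if has_clock else np.full(N_BINS, decay_unclocked))
            else:
                continue
            mult = np.maximum(mult, m)
        out[:, :, si, :] = 1.0 + base_excess[:, :, None] * mult[None, None, :]
    return out


def derive_never_mortality(
    all_cause_rate: float,
    composition: np.ndarray,
    rrs: np.ndarray,
) -> float:
    """Never-smoker mortality consistent with an observed all-cause rate.

    Solves ``sum_s n_s * m_never * rr_s / N == all_cause_rate`` for
    ``m_never``; status-*s* mortality is then ``m_never * rr_s`` and the
    prevalence-weighted average reconstructs the all-cause rate exactly.
    """
    n = np.asarray(composition, dtype=float)
    rr = np.asarray(rrs, dtype=float)
    if n.shape != rr.shape:
        raise ValueError("composition and rrs must have matching shapes")
    if np.any(n < 0):
        raise ValueError("composition must be non-negative")
    total = n.sum()
    if total <= 0:
        raise ValueError("composition must contain at least one person")
    weight = float((n * rr).sum())
    if weight <= 0:
        raise ValueError("all relative-risk weights are zero")
    return float(all_cause_rate) * total / weight


def never_mortality_scale(pop: PopulationState, rr_array: np.ndarray) -> np.ndarray:
    """Per-(gender, age) ratio of never-smoker to all-cause mortality.

    Derived once at initialization from the initial product-status
    composition: ``scale[g, a] = N / sum_cells n * rr``; the engine then
    uses ``m_never(g, a, year) = all_cause(g, a, year) * scale[g, a]``
    so year-varying life tables keep a fixed stratification.  Empty
    (gender, age) cells get scale 1.
    """
    totals = pop.counts.sum(axis=(2, 3))  # (2, 101)
    weights = (pop.counts * rr_array).sum(axis=(2, 3))
    scale = np.ones_like(totals)
    occupied = totals > 0
    scale[occupied] = totals[occupied] / weights[occupied]
    return scale


def apply_status_mortality(
    pop: PopulationState,
    all_cause: np.ndarray,
    never_scale: np.ndarray,
    rr_array: np.ndarray,
) -> tuple[PopulationState, np.ndarray]:
    """Remove one year of status-specific mortality.

    Each cell dies at ``clip(all_cause * never_scale * rr, 0, 1)``, with
    the age-100 rate forced to 1.  Returns the surviving population and
    deaths per (gender, age, state).
    """
    m = all_cause * never_scale  # (2, 101) never-smoker rate
    rates = np.clip(m[:, :, None, None] * rr_array, 0.0, 1.0)
    rates[:, -1, :, :] = 1.0
    deaths_cells = pop.counts * rates
    survivors = pop.counts - deaths_cells
    new = PopulationState(pop.space, survivors, pop.year)
    return new, deaths_cells.sum(axis=3)
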