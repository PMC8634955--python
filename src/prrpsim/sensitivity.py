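"""Monte-Carlo sensitivity over transition-probability confidence intervals.

Each sensitivity run replaces the mean of every targeted rate-table row
with a random draw from inside its 95% confidence interval (clamped to
[0, 1]); the perturbed tables are then projected like any deterministic
scenario and the run-level outputs are summarised (min/max/mean/median/
SD and low percentiles, plus the fraction of runs where the intervention
*increases* life-years lost).

Randomness protocol: one master seed spawns an independent, reproducible
substream per run via ``numpy.random.SeedSequence``; within a run, draws
are made in the table's canonical entry order.  The same seed therefore
always yields the same list of tables, independently of how runs are
scheduled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import ProjectionResult, lyl_reduction
from .transitions import RateTable, TransitionProbability

__all__ = ["SensitivityConfig", "sample_rate_tables", "summarize_runs"]

#: percentile levels reported in the summary, as in the published layout
SUMMARY_PERCENTILES = (5, 10, 15, 20, 25)


@dataclass(frozen=True)
class SensitivityConfig:
    """Settings for a CI-resampling sensitivity assessment.

    ``sampling`` is ``"uniform_in_ci"`` (uniform on [lo95, hi95]; the
    least-informative reading of "selected from within the 95%
    confidence interval") or ``"truncated_normal"`` (normal with the
    mean at the point estimate and sigma = CI width / 3.92, truncated to
    the interval).  ``targets`` optionally restricts sampling to a set
    of flow keys; by default every row with a non-degenerate interval is
    sampled.
    """

    n_runs: int = 1000
    seed: int = 0
    sampling: str = "uniform_in_ci"
    targets: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.sampling not in ("uniform_in_ci", "truncated_normal"):
            raise ValueError("sampling must be 'uniform_in_ci' or 'truncated_normal'")


def _draw(prob: TransitionProbability, rng: np.random.Generator, sampling: str) -> float:
    lo = max(0.0, prob.lo95)
    hi = min(1.0, prob.hi95)
    if hi <= lo:
        return lo
    if sampling == "uniform_in_ci":
        return float(rng.uniform(lo, hi))
    sigma = (hi - lo) / 3.92
    a, b = (lo - prob.mean) / sigma, (hi - prob.mean) / sigma
    return float(stats.truncnorm.rvs(a, b, loc=prob.mean, scale=sigma, random_state=rng))


def sample_rate_tables(table: RateTable, cfg: SensitivityConfig) -> list[RateTable]:
    """Draw ``cfg.n_runs`` perturbed rate tables from the CI envelope.

    Every targeted row's mean is replaced by an independent draw inside
    [lo95, hi95] per run (its CI collapses to the drawn point so that
    downstream consumers see a deterministic table); untargeted rows and
    rows with degenerate intervals keep their means.  Outflow
    normalization happens at compile time in the engine, exactly as for
    deterministic tables.
    """
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_runs)

    def targeted(entry) -> bool:
        if cfg.targets is not None and entry.flow_key not in cfg.targets:
            return False
        return entry.prob.hi95 > entry.prob.lo95

    tables: list[RateTable] = []
    for child in children:
        rng = np.random.Generator(np.random.Philox(child))
        entries = []
        for entry in table.entries:
            if targeted(entry):
                value = _draw(entry.prob, rng, cfg.sampling)
                entries.append(
                    replace(entry, prob=TransitionProbability(value, value, value))
                )
            else:
                entries.append(entry)
        tables.append(RateTable(table.space, entries))
    return tables


def _stats_row(values: np.ndarray) -> dict[str, float]:
    row = {
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
    }
    # linear interpolation between order statistics, pinned for comparability
    for p in SUMMARY_PERCENTILES:
        row[f"p{p}"] = float(np.percentile(values, p, method="linear"))
    return row


def summarize_runs(
    results: Sequence[ProjectionResult],
    at_year: int,
    baseline: ProjectionResult,
    lyl_mode: str = "expectancy",
) -> pd.DataFrame:
    """Summary table across sensitivity runs, evaluated at one year.

    Rows: smoking prevalence (%), PRRP prevalence (%) and LYL reduction
    versus the baseline; columns: min, max, mean, median, SD and the
    5/10/15/20/25 percentiles.  The LYL-reduction row also reports
    ``fraction_negative`` — the share of runs in which the scenario
    *adds* life-years lost relative to the baseline.
    """
    if not results:
        raise ValueError("results must be non-empty")
    smoking = np.array([r.at_year(r.smoking_prevalence, at_year) for r in results])
    prrp = np.array([r.at_year(r.prrp_prevalence, at_year) for r in results])
    lyl = np.array(
        [r.at_year(lyl_reduction(r, baseline, lyl_mode), at_year) for r in results]
    )
    rows = {
        "smoking_prevalence_pct": _stats_row(smoking),
        "prrp_prevalence_pct": _stats_row(prrp),
        "lyl_reduction": _stats_row(lyl) | {"fraction_negative": float((lyl < 0).mean())},
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "metric"
    frame["at_year"] = at_year
    frame["n_runs"] = len(results)
    return frame.reset_index()
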