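"""Delimited-text input/output, config schema and run manifests.

Everything the model consumes or emits is plain UTF-8 comma-separated
text with a header row (auditable, diffable), plus one YAML manifest
(``bundle.yaml``) that names the files, the global risk parameters and
the scenario configurations.  Readers validate schemas strictly and
report the offending file and line.

Conventions: ages are integer completed years 0–100; a calendar year
labels the population state at 1 January of that year; status vectors in
rate tables use one letter per product (N/C/F) in product order, e.g.
``CN>CC`` for a smoker initiating the second product.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demography import (
    GENDERS,
    N_AGES,
    N_BINS,
    DemographySchedules,
    LifeTable,
    PopulationState,
)
from .engine import (
    ProjectionResult,
    ScenarioDefinition,
    SimulationConfig,
    initial_population,
)
from .risk import RiskModel
from .state_space import StateSpace
from .transitions import (
    RateEntry,
    RateTable,
    ScenarioModifiers,
    TransitionProbability,
    combine_pseudo_prrp,
    geometric_relapse_multipliers,
)

__all__ = [
    "InputValidationError",
    "InputBundle",
    "RunManifest",
    "read_inputs",
    "write_inputs",
    "read_rate_table",
    "write_rate_table",
    "build_scenario",
    "initial_population_for",
    "write_results",
    "write_comparison",
    "write_manifest",
]

BUNDLE_FORMAT = "prrpsim-input-bundle-v1"


class InputValidationError(ValueError):
    """A malformed input file, with file and line context."""

    def __init__(self, path: Path | str, message: str, line: int | None = None):
        where = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{where}: {message}")
        self.path = str(path)
        self.line = line


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise InputValidationError(path, "file not found")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputValidationError(path, f"missing mandatory column(s): {', '.join(missing)}")
    return df


def _check_range(df: pd.DataFrame, col: str, lo: float, hi: float, path: Path) -> None:
    bad = df.index[(df[col] < lo) | (df[col] > hi)]
    if len(bad):
        # +2: header line plus 1-based indexing
        raise InputValidationError(
            path, f"column {col!r} outside [{lo}, {hi}]", line=int(bad[0]) + 2
        )


def _gender_age_grid(df: pd.DataFrame, value_col: str, path: Path) -> np.ndarray:
    grid = np.zeros((2, N_AGES))
    seen = np.zeros((2, N_AGES), dtype=bool)
    for i, row in df.iterrows():
        if row["gender"] not in GENDERS:
            raise InputValidationError(path, f"unknown gender {row['gender']!r}", line=int(i) + 2)
        age = int(row["age"])
        if not (0 <= age <= N_AGES - 1):
            raise InputValidationError(path, f"age {age} outside 0..{N_AGES - 1}", line=int(i) + 2)
        g = GENDERS.index(row["gender"])
        grid[g, age] = float(row[value_col])
        seen[g, age] = True
    if not seen.all():
        g, a = np.argwhere(~seen)[0]
        raise InputValidationError(path, f"missing value for ({GENDERS[g]}, age {a})")
    return grid


# ---------------------------------------------------------------------------
# individual artifact readers/writers


def read_pyramid(path: Path) -> np.ndarray:
    df = _read_csv(path, ["gender", "age", "count"])
    _check_range(df, "count", 0, np.inf, path)
    return _gender_age_grid(df, "count", path)


def write_pyramid(pyramid: np.ndarray, path: Path) -> None:
    rows = [
        {"gender": gender, "age": age, "count": repr(float(pyramid[g, age]))}
        for g, gender in enumerate(GENDERS)
        for age in range(N_AGES)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_life_table(path: Path) -> LifeTable:
    df = _read_csv(path, ["gender", "age", "year", "mortality_rate", "life_expectancy"])
    _check_range(df, "mortality_rate", 0, 1, path)
    _check_range(df, "life_expectancy", 0, np.inf, path)
    mortality: dict[int, np.ndarray] = {}
    expectancy = np.zeros((2, N_AGES))
    for year, sub in df.groupby("year"):
        mortality[int(year)] = _gender_age_grid(sub.reset_index(drop=True), "mortality_rate", path)
        expectancy = _gender_age_grid(sub.reset_index(drop=True), "life_expectancy", path)
    try:
        return LifeTable(mortality, expectancy)
    except ValueError as exc:
        raise InputValidationError(path, str(exc)) from exc


def write_life_table(lt: LifeTable, path: Path) -> None:
    df = lt.to_frame()
    for col in ("mortality_rate", "life_expectancy"):
        df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)


def read_schedules(births_path: Path, migration_path: Path, dist_path: Path) -> DemographySchedules:
    bdf = _read_csv(births_path, ["year", "gender", "count"])
    _check_range(bdf, "count", 0, np.inf, births_path)
    births: dict[int, list[float]] = {}
    for i, row in bdf.iterrows():
        if row["gender"] not in GENDERS:
            raise InputValidationError(births_path, f"unknown gender {row['gender']!r}", line=int(i) + 2)
        pair = births.setdefault(int(row["year"]), [0.0, 0.0])
        pair[GENDERS.index(row["gender"])] = float(row["count"])
    mdf = _read_csv(migration_path, ["year", "net_migration"])
    migration = {int(r["year"]): float(r["net_migration"]) for _, r in mdf.iterrows()}
    ddf = _read_csv(dist_path, ["gender", "age", "proportion"])
    _check_range(ddf, "proportion", 0, 1, dist_path)
    dist = _gender_age_grid(ddf, "proportion", dist_path)
    try:
        return DemographySchedules(
            births={y: (m, f) for y, (m, f) in births.items()},
            net_migration=migration,
            migration_age_distribution=dist,
        )
    except ValueError as exc:
        raise InputValidationError(dist_path, str(exc)) from exc


def write_schedules(
    sched: DemographySchedules, births_path: Path, migration_path: Path, dist_path: Path
) -> None:
    brows = [
        {"year": y, "gender": gender, "count": repr(float(pair[g]))}
        for y, pair in sorted(sched.births.items())
        for g, gender in enumerate(GENDERS)
    ]
    pd.DataFrame(brows, columns=["year", "gender", "count"]).to_csv(births_path, index=False)
    mrows = [
        {"year": y, "net_migration": repr(float(v))} for y, v in sorted(sched.net_migration.items())
    ]
    pd.DataFrame(mrows, columns=["year", "net_migration"]).to_csv(migration_path, index=False)
    dist = (
        sched.migration_age_distribution
        if sched.migration_age_distribution is not None
        else np.zeros((2, N_AGES))
    )
    drows = [
        {"gender": gender, "age": age, "proportion": repr(float(dist[g, age]))}
        for g, gender in enumerate(GENDERS)
        for age in range(N_AGES)
    ]
    pd.DataFrame(drows).to_csv(dist_path, index=False)


def read_prevalence(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path, ["gender", "age", "current", "former"])
    _check_range(df, "current", 0, 1, path)
    _check_range(df, "former", 0, 1, path)
    current = _gender_age_grid(df, "current", path)
    former = _gender_age_grid(df, "former", path)
    if np.any(current + former > 1 + 1e-9):
        raise InputValidationError(path, "current + former prevalence exceeds 1")
    return current, former


def write_prevalence(current: np.ndarray, former: np.ndarray, path: Path) -> None:
    rows = [
        {
            "gender": gender,
            "age": age,
            "current": repr(float(current[g, age])),
            "former": repr(float(former[g, age])),
        }
        for g, gender in enumerate(GENDERS)
        for age in range(N_AGES)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


_QUIT_BINS = [str(b) for b in range(1, N_BINS - 1)] + ["20+"]


def read_quit_distribution(path: Path) -> np.ndarray:
    df = _read_csv(path, ["bin", "proportion"])
    _check_range(df, "proportion", 0, 1, path)
    props = {str(r["bin"]): float(r["proportion"]) for _, r in df.iterrows()}
    missing = [b for b in _QUIT_BINS if b not in props]
    if missing:
        raise InputValidationError(path, f"missing quit-time bin(s): {', '.join(missing)}")
    dist = np.array([props[b] for b in _QUIT_BINS])
    if not np.isclose(dist.sum(), 1.0, atol=1e-6):
        raise InputValidationError(path, f"quit-time proportions sum to {dist.sum():.6f}, not 1")
    return dist


def write_quit_distribution(dist: np.ndarray, path: Path) -> None:
    rows = [{"bin": b, "proportion": repr(float(p))} for b, p in zip(_QUIT_BINS, dist)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rate_table(path: Path, space: StateSpace) -> RateTable:
    df = _read_csv(
        path,
        [
            "product_moves",
            "from_status_vector",
            "to_status_vector",
            "gender",
            "age_lo",
            "age_hi",
            "year",
            "mean",
            "lo95",
            "hi95",
        ],
    )
    for col in ("mean", "lo95", "hi95"):
        _check_range(df, col, 0, 1, path)
    entries: list[RateEntry] = []
    for i, row in df.iterrows():
        key = f"{row['from_status_vector']}>{row['to_status_vector']}"
        if key not in space.flow_index:
            raise InputValidationError(path, f"unknown or inadmissible flow {key!r}", line=int(i) + 2)
        flow = space.flow(key)
        if str(row["product_moves"]) != flow.moves_label:
            raise InputValidationError(
                path,
                f"product_moves {row['product_moves']!r} does not match flow {key!r} "
                f"(expected {flow.moves_label!r})",
                line=int(i) + 2,
            )
        year = None if str(row["year"]) in ("*", "nan") else int(float(row["year"]))
        try:
            entries.append(
                RateEntry(
                    flow_key=key,
                    gender=str(row["gender"]),
                    age_lo=int(row["age_lo"]),
                    age_hi=int(row["age_hi"]),
                    year=year,
                    prob=TransitionProbability(
                        float(row["mean"]), float(row["lo95"]), float(row["hi95"])
                    ),
                )
            )
        except ValueError as exc:
            raise InputValidationError(path, str(exc), line=int(i) + 2) from exc
    return RateTable(space, entries)


def write_rate_table(table: RateTable, path: Path) -> None:
    rows = []
    for e in table.entries:
        flow = table.space.flow(e.flow_key)
        rows.append(
            {
                "product_moves": flow.moves_label,
                "from_status_vector": flow.from_state.id,
                "to_status_vector": flow.to_state.id,
                "gender": e.gender,
                "age_lo": e.age_lo,
                "age_hi": e.age_hi,
                "year": "*" if e.year is None else e.year,
                "mean": repr(e.prob.mean),
                "lo95": repr(e.prob.lo95),
                "hi95": repr(e.prob.hi95),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "product_moves",
            "from_status_vector",
            "to_status_vector",
            "gender",
            "age_lo",
            "age_hi",
            "year",
            "mean",
            "lo95",
            "hi95",
        ],
    ).to_csv(path, index=False)


def read_risk_rr(path: Path) -> list[tuple[str, int, int, float]]:
    df = _read_csv(path, ["gender", "age_lo", "age_hi", "rr"])
    _check_range(df, "rr", 1, np.inf, path)
    return [
        (str(r["gender"]), int(r["age_lo"]), int(r["age_hi"]), float(r["rr"]))
        for _, r in df.iterrows()
    ]


def write_risk_rr(entries: list[tuple[str, int, int, float]], path: Path) -> None:
    rows = [
        {"gender": g, "age_lo": lo, "age_hi": hi, "rr": repr(float(rr))}
        for g, lo, hi, rr in entries
    ]
    pd.DataFrame(rows, columns=["gender", "age_lo", "age_hi", "rr"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class InputBundle:
    """Everything one comparison needs, in memory."""

    pyramid: np.ndarray
    life_table: LifeTable
    schedules: DemographySchedules
    current_prev: np.ndarray
    former_prev: np.ndarray
    quit_time_distribution: np.ndarray
    rate_tables: dict[str, RateTable]
    risk_params: dict
    scenarios: dict[str, dict]
    start_year: int = 2001

    def scenario_ids(self) -> list[str]:
        return list(self.scenarios)


def write_inputs(bundle: InputBundle, out_dir: Path | str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pyramid(bundle.pyramid, out / "pyramid.csv")
    write_life_table(bundle.life_table, out / "life_table.csv")
    write_schedules(
        bundle.schedules, out / "births.csv", out / "migration.csv",
        out / "migration_age_distribution.csv",
    )
    write_prevalence(bundle.current_prev, bundle.former_prev, out / "smoking_prevalence.csv")
    write_quit_distribution(bundle.quit_time_distribution, out / "quit_time_distribution.csv")
    rate_files = {}
    for name, table in bundle.rate_tables.items():
        fname = f"rates_{name}.csv"
        write_rate_table(table, out / fname)
        rate_files[name] = {"file": fname, "products": list(table.space.labels)}
    risk = dict(bundle.risk_params)
    write_risk_rr(risk.pop("rr_current_smoker"), out / "risk_rr.csv")
    manifest = {
        "format": BUNDLE_FORMAT,
        "start_year": bundle.start_year,
        "files": {
            "pyramid": "pyramid.csv",
            "life_table": "life_table.csv",
            "births": "births.csv",
            "migration": "migration.csv",
            "migration_age_distribution": "migration_age_distribution.csv",
            "smoking_prevalence": "smoking_prevalence.csv",
            "quit_time_distribution": "quit_time_distribution.csv",
            "risk_rr": "risk_rr.csv",
        },
        "rate_tables": rate_files,
        "risk": risk,
        "scenarios": bundle.scenarios,
    }
    with open(out / "bundle.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_inputs(in_dir: Path | str) -> InputBundle:
    root = Path(in_dir)
    manifest_path = root / "bundle.yaml"
    if not manifest_path.exists():
        raise InputValidationError(manifest_path, "bundle manifest not found")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("format") != BUNDLE_FORMAT:
        raise InputValidationError(manifest_path, f"unsupported format {manifest.get('format')!r}")
    files = manifest["files"]
    current, former = read_prevalence(root / files["smoking_prevalence"])
    tables: dict[str, RateTable] = {}
    for name, spec in manifest.get("rate_tables", {}).items():
        space = StateSpace(tuple(spec["products"]))
        tables[name] = read_rate_table(root / spec["file"], space)
    risk = dict(manifest.get("risk", {}))
    risk["rr_current_smoker"] = read_risk_rr(root / files["risk_rr"])
    return InputBundle(
        pyramid=read_pyramid(root / files["pyramid"]),
        life_table=read_life_table(root / files["life_table"]),
        schedules=read_schedules(
            root / files["births"], root / files["migration"],
            root / files["migration_age_distribution"],
        ),
        current_prev=current,
        former_prev=former,
        quit_time_distribution=read_quit_distribution(root / files["quit_time_distribution"]),
        rate_tables=tables,
        risk_params=risk,
        scenarios=manifest.get("scenarios", {}),
        start_year=int(manifest.get("start_year", 2001)),
    )


# ---------------------------------------------------------------------------
# scenario assembly


def build_scenario(bundle: InputBundle, name: str) -> tuple[StateSpace, ScenarioDefinition]:
    """Materialise one scenario from its bundle configuration."""
    if name not in bundle.scenarios:
        raise KeyError(f"unknown scenario {name!r}; have {sorted(bundle.scenarios)}")
    cfg = bundle.scenarios[name]
    pseudo = cfg.get("pseudo")
    if pseudo:
        table = combine_pseudo_prrp(
            bundle.rate_tables[pseudo["table_a"]],
            bundle.rate_tables[pseudo["table_b"]],
            float(pseudo["weight_a"]),
        )
    else:
        table = bundle.rate_tables[cfg["rate_table"]]
    space = table.space
    products = cfg.get("products")
    if products is not None and tuple(products) != space.labels:
        raise ValueError(
            f"scenario {name!r} products {products} do not match rate table {space.labels}"
        )
    risk = RiskModel(
        rr_current_smoker=bundle.risk_params["rr_current_smoker"],
        decay_halflife=float(bundle.risk_params.get("decay_halflife", 10.0)),
        prrp_excess_fraction={k: float(v) for k, v in cfg.get("risk_fractions", {}).items()},
        twentyplus_quit_years=float(bundle.risk_params.get("twentyplus_quit_years", 25.0)),
        prrp_former_quit_years=float(bundle.risk_params.get("prrp_former_quit_years", 1.0)),
    )
    mods = ScenarioModifiers(
        product_intro_year={k: int(v) for k, v in cfg.get("intro_years", {}).items()},
        initiation_decline_rate=float(cfg.get("initiation_decline_rate", 0.0)),
        initiation_decline_start=int(cfg.get("initiation_decline_start", 2020)),
    )
    relapse = geometric_relapse_multipliers(float(cfg.get("relapse_decline_ratio", 0.85)))
    return space, ScenarioDefinition(
        scenario_id=name,
        rate_table=table,
        risk_model=risk,
        modifiers=mods,
        relapse_bin_multipliers=relapse,
    )


def initial_population_for(bundle: InputBundle, space: StateSpace) -> PopulationState:
    return initial_population(
        space,
        bundle.pyramid,
        bundle.current_prev,
        bundle.former_prev,
        bundle.quit_time_distribution,
        bundle.start_year,
    )


# ---------------------------------------------------------------------------
# results and manifests


def write_results(result: ProjectionResult, out_dir: Path | str) -> Path:
    """Write one scenario's tidy yearly series; returns the file path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"projection_{result.scenario_id}.csv"
    df = result.to_frame()
    df["value"] = df["value"].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)
    return path


def write_comparison(comparison: pd.DataFrame, path: Path | str) -> None:
    """Decade-sampled wide table; values rounded to 1 decimal as printed."""
    rounded = comparison.copy()
    for col in rounded.columns:
        if col not in ("metric", "scenario"):
            rounded[col] = rounded[col].astype(float).round(1)
    rounded.to_csv(path, index=False)


@dataclass
class RunManifest:
    """Provenance record written next to every output set."""

    config_digest: str
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    artifact_version: str = "0.1.0"
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "input_digests": self.input_digests,
            "artifact_version": self.artifact_version,
            "timestamp": self.timestamp,
        }


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: Path | str,
    config: SimulationConfig,
    input_dir: Path | str | None = None,
    seed: int = 0,
) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests = {}
    if input_dir is not None:
        for p in sorted(Path(input_dir).glob("*.csv")) + sorted(Path(input_dir).glob("*.yaml")):
            digests[p.name] = _digest_file(p)
    manifest = RunManifest(
        config_digest=config.digest(),
        seed=seed,
        input_digests=digests,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    return manifest
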