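"""Cohort file formats, validation and run configuration.

The canonical interchange format is a flat CSV with one row per radiograph:
``individual_id, sex, role, imaging_date`` followed by 32 state columns
named by FDI code (``t18`` .. ``t38`` in canonical order).  Dates are
ISO-8601; a reader shim also accepts legacy six-digit YYMMDD stamps with a
1950-2049 century pivot.  A JSON mirror of the same schema is provided for
pipelines that prefer nested documents.  Validation collects every offense
(bad state code, bad date, duplicate id/role, broken pairing) with its line
number before raising, so a malformed file is reported once, completely.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import tomllib
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .dentition import (
    FDI_POSITIONS,
    Dentition,
    ToothState,
    TransitionGraph,
    default_transition_graph,
)
from .matching import DentitionRecord
from .similarity import ScoringParams
from .simulate import CohortConfig, NoiseParams

__all__ = [
    "STATE_COLUMNS",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_cohort_json",
    "write_cohort_json",
    "RunConfig",
    "load_run_config",
]

STATE_COLUMNS: tuple[str, ...] = tuple(f"t{pos}" for pos in FDI_POSITIONS)
BASE_COLUMNS: tuple[str, ...] = ("individual_id", "sex", "role", "imaging_date")


class CohortValidationError(ValueError):
    """Raised with the full list of per-line validation problems."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid cohort file:\n" + "\n".join(f"  - {p}" for p in problems)
        )


def parse_imaging_date(raw: str) -> datetime.date:
    """Parse ISO-8601 dates, or six-digit YYMMDD with a 1950-2049 pivot."""
    raw = str(raw).strip()
    if len(raw) == 6 and raw.isdigit():
        yy = int(raw[:2])
        century = 1900 if yy >= 50 else 2000
        return datetime.date(century + yy, int(raw[2:4]), int(raw[4:6]))
    return datetime.date.fromisoformat(raw)


def _records_from_frame(
    frame: pd.DataFrame, paired: bool, source: str
) -> list[DentitionRecord]:
    problems: list[str] = []
    missing_cols = [
        c for c in BASE_COLUMNS + STATE_COLUMNS if c not in frame.columns
    ]
    if missing_cols:
        raise CohortValidationError(
            [f"{source}: missing columns {missing_cols}"]
        )
    records: list[DentitionRecord] = []
    seen: set[tuple[str, str]] = set()
    for row_idx, row in frame.iterrows():
        # header is line 1, first data row line 2
        line = int(row_idx) + 2
        ok = True
        ind_id = str(row["individual_id"])
        sex = str(row["sex"])
        role = str(row["role"])
        if sex not in ("M", "F"):
            problems.append(f"line {line}: sex must be M or F, got {sex!r}")
            ok = False
        if role not in ("AM", "PM"):
            problems.append(f"line {line}: role must be AM or PM, got {role!r}")
            ok = False
        if (ind_id, role) in seen:
            problems.append(f"line {line}: duplicate record ({ind_id}, {role})")
            ok = False
        seen.add((ind_id, role))
        try:
            date = parse_imaging_date(row["imaging_date"])
        except (ValueError, TypeError):
            problems.append(
                f"line {line}: unparseable imaging_date {row['imaging_date']!r}"
            )
            ok = False
        states = []
        for col in STATE_COLUMNS:
            try:
                states.append(ToothState(str(row[col]).strip()))
            except ValueError:
                problems.append(
                    f"line {line}: invalid state code {row[col]!r} in {col}"
                )
                ok = False
        if ok:
            records.append(
                DentitionRecord(
                    individual_id=ind_id,
                    sex=sex,  # type: ignore[arg-type]
                    imaging_date=date,
                    role=role,  # type: ignore[arg-type]
                    dentition=Dentition.from_codes(states),
                )
            )
    if paired and not problems:
        by_id: dict[str, dict[str, DentitionRecord]] = {}
        for rec in records:
            by_id.setdefault(rec.individual_id, {})[rec.role] = rec
        for ind_id, roles in sorted(by_id.items()):
            if set(roles) != {"AM", "PM"}:
                problems.append(
                    f"{source}: individual {ind_id} lacks an "
                    f"{'AM' if 'AM' not in roles else 'PM'} record"
                )
            elif roles["PM"].imaging_date < roles["AM"].imaging_date:
                problems.append(
                    f"{source}: individual {ind_id} has PM date before AM date"
                )
    if problems:
        raise CohortValidationError(problems)
    return records


def read_cohort(path: str | Path, paired: bool = False) -> list[DentitionRecord]:
    """Read and validate a cohort CSV.

    With ``paired=True`` additionally checks that every individual has
    exactly one AM and one PM record and that dates are ordered.
    """
    frame = pd.read_csv(path, dtype=str)
    return _records_from_frame(frame, paired=paired, source=str(path))


def cohort_frame(records: Sequence[DentitionRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, Any] = {
            "individual_id": rec.individual_id,
            "sex": rec.sex,
            "role": rec.role,
            "imaging_date": rec.imaging_date.isoformat(),
        }
        row.update(
            {col: state.value for col, state in zip(STATE_COLUMNS, rec.dentition.codes())}
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(BASE_COLUMNS + STATE_COLUMNS))


def write_cohort(records: Sequence[DentitionRecord], path: str | Path) -> None:
    """Write records to the canonical cohort CSV."""
    cohort_frame(records).to_csv(path, index=False, lineterminator="\n")


def write_cohort_json(
    records: Sequence[DentitionRecord], path: str | Path
) -> None:
    """JSON mirror of the cohort schema (list of row objects)."""
    payload = cohort_frame(records).to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_cohort_json(
    path: str | Path, paired: bool = False
) -> list[DentitionRecord]:
    payload = json.loads(Path(path).read_text())
    frame = pd.DataFrame(payload)
    return _records_from_frame(frame, paired=paired, source=str(path))


# -- run configuration ----------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Materialized configuration for a full pipeline run."""

    scoring: ScoringParams = dataclasses.field(default_factory=ScoringParams)
    graph: TransitionGraph = dataclasses.field(
        default_factory=default_transition_graph
    )
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    p_list: tuple[float, ...] = (0.20, 0.10, 0.05)
    unit_days: int = 100
    ttest_variant: str = "student"
    trend_criterion: str = "first_difference"

    def describe(self) -> dict:
        """JSON-serializable dump of every materialized setting."""
        return {
            "scoring": dataclasses.asdict(self.scoring),
            "graph_edges": sorted(
                [a.value, b.value] for a, b in self.graph.edges
            ),
            "cohort": _cohort_config_dict(self.cohort),
            "p_list": list(self.p_list),
            "unit_days": self.unit_days,
            "ttest_variant": self.ttest_variant,
            "trend_criterion": self.trend_criterion,
        }


def _cohort_config_dict(config: CohortConfig) -> dict:
    return {
        "n_individuals": config.n_individuals,
        "sex_ratio_female": config.sex_ratio_female,
        "age_range": list(config.age_range),
        "interval_mean": config.interval_mean,
        "interval_sd": config.interval_sd,
        "interval_min": config.interval_min,
        "interval_max": config.interval_max,
        "baseline_priors": {
            s.value: p for s, p in config.baseline_priors.items()
        },
        "transition_hazards": {
            f"{a.value}->{b.value}": h
            for (a, b), h in sorted(config.transition_hazards.items())
        },
        "female_hazard_multiplier": config.female_hazard_multiplier,
        "noise": None
        if config.noise is None
        else {
            "recall": {s.value: r for s, r in config.noise.recall.items()},
            "confusions": {
                s.value: [t.value for t in ts]
                for s, ts in config.noise.confusions.items()
            },
        },
        "noise_on_am": config.noise_on_am,
        "seed": config.seed,
    }


_KNOWN_SECTIONS = {"scoring", "graph", "analysis", "simulate"}


def load_run_config(path: str | Path) -> RunConfig:
    """Load a TOML or JSON run configuration; unknown keys are rejected."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        raw = tomllib.loads(path.read_text())
    else:
        raw = json.loads(path.read_text())
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    scoring = ScoringParams(**raw.get("scoring", {}))
    graph_spec = raw.get("graph", "default")
    if graph_spec == "default" or graph_spec == {}:
        graph = default_transition_graph()
    else:
        graph = TransitionGraph(
            (ToothState(a), ToothState(b)) for a, b in graph_spec["edges"]
        )
    analysis = dict(raw.get("analysis", {}))
    sim = dict(raw.get("simulate", {}))
    if "baseline_priors" in sim:
        sim["baseline_priors"] = {
            ToothState(k): v for k, v in sim["baseline_priors"].items()
        }
    if "transition_hazards" in sim:
        sim["transition_hazards"] = {
            (ToothState(a), ToothState(b)): h
            for (a, b), h in (
                (k.split("->"), v) for k, v in sim["transition_hazards"].items()
            )
        }
    if sim.get("noise"):
        noise = sim["noise"]
        sim["noise"] = NoiseParams(
            recall={ToothState(k): v for k, v in noise.get("recall", {}).items()}
            or dict(NoiseParams().recall),
            confusions={
                ToothState(k): tuple(ToothState(t) for t in ts)
                for k, ts in noise.get("confusions", {}).items()
            }
            or dict(NoiseParams().confusions),
        )
    if "age_range" in sim:
        sim["age_range"] = tuple(sim["age_range"])
    cohort = CohortConfig(**sim)
    return RunConfig(
        scoring=scoring,
        graph=graph,
        cohort=cohort,
        p_list=tuple(analysis.get("p_list", (0.20, 0.10, 0.05))),
        unit_days=int(analysis.get("unit_days", 100)),
        ttest_variant=analysis.get("ttest_variant", "student"),
        trend_criterion=analysis.get("trend_criterion", "first_difference"),
    )
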