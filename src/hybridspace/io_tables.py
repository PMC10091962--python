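"""Tabular input/output for trait tables, trial logs, and count summaries.

The package exchanges data as plain CSV (comma-separated, UTF-8, header row
mandatory, ``.`` decimal separator, empty string = missing).  Two tables are
understood:

* the **trait table** — one row per fish: crossing group, generation, sex,
  body length, brain weight, and length/width/height of six brain regions;
* the **trial log** — one row per training trial: fish id, task, 1-based
  trial index, and a binary correct/incorrect outcome.

Crossing groups are generic (``P1``/``P2`` for the two parental species,
reciprocal ``F1``/``F2`` hybrids encoded mother×father); a config alias map
can attach species names without the pipeline caring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GROUPS",
    "GENERATION_OF",
    "REGIONS",
    "DIMS",
    "SchemaError",
    "ValidationError",
    "IndividualRecord",
    "TrialLog",
    "CountTable",
    "read_trait_table",
    "write_trait_table",
    "read_trial_log",
    "write_trial_log",
    "aggregate_counts",
    "percentage_half_up",
]

GROUPS = ("P1", "P2", "F1_P1xP2", "F1_P2xP1", "F2_P1xP2", "F2_P2xP1")
HYBRID_GROUPS = ("F1_P1xP2", "F1_P2xP1", "F2_P1xP2", "F2_P2xP1")
GENERATION_OF = {
    "P1": "parental",
    "P2": "parental",
    "F1_P1xP2": "F1",
    "F1_P2xP1": "F1",
    "F2_P1xP2": "F2",
    "F2_P2xP1": "F2",
}
SEXES = ("F", "M")
TASKS = ("associative", "reversal")
STAGES = ("pretraining", "associative", "reversal")

REGIONS = (
    "telencephalon",
    "optic_tectum",
    "cerebellum",
    "dorsal_medulla",
    "hypothalamus",
    "olfactory_bulbs",
)
DIMS = ("length", "width", "height")

TRAIT_COLUMNS = [
    "individual_id",
    "group",
    "generation",
    "sex",
    "body_length_mm",
    "brain_weight_mg",
] + [f"{region}_{dim}_mm" for region in REGIONS for dim in DIMS]

TRIAL_COLUMNS = ["individual_id", "group", "sex", "task", "trial_index", "correct"]


class SchemaError(ValueError):
    """A table is missing mandatory columns or has the wrong layout."""


class ValidationError(ValueError):
    """A row violates a data invariant; the message names row and column."""


@dataclass
class IndividualRecord:
    """One fish: identity, cross, and raw morphometrics.

    ``region_dims`` maps region name to an (length, width, height) triple in
    mm; regions not measured are simply absent from the mapping.  Optional
    measurements are ``None`` when missing, never zero.
    """

    individual_id: str
    group: str
    sex: str
    body_length_mm: float
    brain_weight_mg: float | None = None
    region_dims: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def generation(self) -> str:
        return GENERATION_OF[self.group]

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        _require_positive(self.body_length_mm, "body_length_mm")
        if self.brain_weight_mg is not None:
            _require_positive(self.brain_weight_mg, "brain_weight_mg")
        for region, dims in self.region_dims.items():
            if region not in REGIONS:
                raise ValidationError(f"unknown brain region {region!r}")
            if len(dims) != 3:
                raise ValidationError(f"{region}: need (length, width, height)")
            for dim_name, value in zip(DIMS, dims):
                _require_positive(value, f"{region}_{dim_name}_mm")


def _require_positive(value: float, name: str) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be strictly positive and finite, got {value!r}")


def _parse_float(cell, row: int, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ValidationError(f"row {row}: column {column!r}: not a number: {cell!r}") from exc


def read_trait_table(path: str | Path) -> list[IndividualRecord]:
    """Read a trait-table CSV into validated :class:`IndividualRecord` objects.

    Rows are validated one by one; the first offending row raises a
    :class:`ValidationError` naming the row (1-based, excluding the header)
    and column.  Missing optional cells become absent values.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRAIT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trait table {path}: missing columns {missing}")

    records: list[IndividualRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        individual_id = row["individual_id"].strip()
        if not individual_id:
            raise ValidationError(f"row {i}: empty individual_id")
        if individual_id in seen:
            raise ValidationError(f"row {i}: duplicate individual_id {individual_id!r}")
        seen.add(individual_id)
        group = row["group"].strip()
        if group not in GROUPS:
            raise ValidationError(f"row {i}: unknown group {group!r}")
        generation = row["generation"].strip()
        if generation != GENERATION_OF[group]:
            raise ValidationError(
                f"row {i}: generation {generation!r} inconsistent with group {group!r}"
            )
        body_length = _parse_float(row["body_length_mm"], i, "body_length_mm")
        if body_length is None:
            raise ValidationError(f"row {i}: body_length_mm is mandatory")
        brain_weight = _parse_float(row["brain_weight_mg"], i, "brain_weight_mg")
        region_dims: dict[str, tuple[float, float, float]] = {}
        for region in REGIONS:
            dims = [
                _parse_float(row[f"{region}_{dim}_mm"], i, f"{region}_{dim}_mm")
                for dim in DIMS
            ]
            if all(v is None for v in dims):
                continue
            if any(v is None for v in dims):
                raise ValidationError(
                    f"row {i}: region {region!r} has a partial (length,width,height) triple"
                )
            region_dims[region] = (dims[0], dims[1], dims[2])
        record = IndividualRecord(
            individual_id=individual_id,
            group=group,
            sex=row["sex"].strip(),
            body_length_mm=body_length,
            brain_weight_mg=brain_weight,
            region_dims=region_dims,
        )
        try:
            record.validate()
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(record)
    return records


def write_trait_table(records: Iterable[IndividualRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical column order (round-trip safe)."""
    rows = []
    for rec in records:
        rec.validate()
        row: dict[str, object] = {
            "individual_id": rec.individual_id,
            "group": rec.group,
            "generation": rec.generation,
            "sex": rec.sex,
            "body_length_mm": repr(rec.body_length_mm),
            "brain_weight_mg": "" if rec.brain_weight_mg is None else repr(rec.brain_weight_mg),
        }
        for region in REGIONS:
            dims = rec.region_dims.get(region)
            for k, dim in enumerate(DIMS):
                row[f"{region}_{dim}_mm"] = "" if dims is None else repr(dims[k])
        rows.append(row)
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, index=False)


@dataclass
class TrialLog:
    """Per-(individual, task) trial sequences plus fish metadata.

    ``sequences`` maps ``(individual_id, task)`` to the chronological list of
    binary outcomes; ``meta`` maps individual id to ``(group, sex)``.
    """

    sequences: dict[tuple[str, str], list[int]]
    meta: dict[str, tuple[str, str]]

    def sequence(self, individual_id: str, task: str) -> list[int]:
        return self.sequences[(individual_id, task)]


def read_trial_log(path: str | Path) -> TrialLog:
    """Read a trial-log CSV; sequences are returned sorted by trial index.

    Gaps or duplicates in the 1-based trial indices of any (fish, task)
    sequence are errors, as are non-binary outcomes.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial log {path}: missing columns {missing}")

    raw: dict[tuple[str, str], dict[int, int]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        individual_id = row["individual_id"].strip()
        task = row["task"].strip()
        if task not in TASKS:
            raise ValidationError(f"row {i}: unknown task {task!r}")
        group = row["group"].strip()
        if group not in GROUPS:
            raise ValidationError(f"row {i}: unknown group {group!r}")
        sex = row["sex"].strip()
        if sex not in SEXES:
            raise ValidationError(f"row {i}: unknown sex {sex!r}")
        prior = meta.setdefault(individual_id, (group, sex))
        if prior != (group, sex):
            raise ValidationError(f"row {i}: inconsistent group/sex for {individual_id!r}")
        try:
            trial_index = int(row["trial_index"])
        except ValueError:
            raise ValidationError(f"row {i}: trial_index not an integer") from None
        if trial_index < 1:
            raise ValidationError(f"row {i}: trial_index must be >= 1")
        correct = str(row["correct"]).strip()
        if correct not in ("0", "1"):
            raise ValidationError(f"row {i}: correct must be 0 or 1, got {correct!r}")
        key = (individual_id, task)
        trials = raw.setdefault(key, {})
        if trial_index in trials:
            raise ValidationError(
                f"row {i}: duplicate trial {trial_index} for {individual_id!r}/{task}"
            )
        trials[trial_index] = int(correct)

    sequences: dict[tuple[str, str], list[int]] = {}
    for key, trials in raw.items():
        n = len(trials)
        if sorted(trials) != list(range(1, n + 1)):
            raise ValidationError(
                f"{key[0]!r}/{key[1]}: trial indices not contiguous from 1 "
                f"(got {sorted(trials)[:5]}...)"
            )
        sequences[key] = [trials[t] for t in range(1, n + 1)]
    return TrialLog(sequences=sequences, meta=meta)


def write_trial_log(log: TrialLog, path: str | Path) -> None:
    rows = []
    for (individual_id, task), seq in sorted(log.sequences.items()):
        group, sex = log.meta[individual_id]
        for t, correct in enumerate(seq, start=1):
            rows.append(
                {
                    "individual_id": individual_id,
                    "group": group,
                    "sex": sex,
                    "task": task,
                    "trial_index": t,
                    "correct": int(correct),
                }
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def percentage_half_up(numerator: int, denominator: int) -> int | None:
    """Integer percentage with ties rounded half-up; ``None`` when undefined.

    Matches the conventional reporting style for success rates
    (e.g., 19/24 -> 79).
    """
    if denominator == 0:
        return None
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass
class CountTable:
    """Per-(group, stage) success counts with derived totals and percentages."""

    cells: dict[tuple[str, str], tuple[int, int]]

    def __post_init__(self) -> None:
        for (group, stage), (num, den) in self.cells.items():
            if stage not in STAGES:
                raise ValidationError(f"unknown stage {stage!r}")
            if not (0 <= num <= den):
                raise ValidationError(
                    f"cell ({group}, {stage}): need 0 <= numerator <= denominator"
                )

    def cell(self, group: str, stage: str) -> tuple[int, int]:
        return self.cells.get((group, stage), (0, 0))

    def percentage(self, group: str, stage: str) -> int | None:
        num, den = self.cell(group, stage)
        return percentage_half_up(num, den)

    def total(self, stage: str) -> tuple[int, int]:
        num = sum(v[0] for (g, s), v in self.cells.items() if s == stage)
        den = sum(v[1] for (g, s), v in self.cells.items() if s == stage)
        return num, den

    def total_percentage(self, stage: str) -> int | None:
        return percentage_half_up(*self.total(stage))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "stage": s,
                "numerator": num,
                "denominator": den,
                "percentage": percentage_half_up(num, den),
            }
            for (g, s), (num, den) in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["group", "stage", "numerator", "denominator", "percentage"])


def aggregate_counts(
    outcomes: Iterable,
    pretraining: Mapping[str, bool] | None = None,
    pretraining_groups: Mapping[str, str] | None = None,
) -> CountTable:
    """Aggregate learning outcomes (and optional pretraining flags) per group.

    ``outcomes`` is any iterable of objects with ``individual_id``, ``task``,
    ``group`` and ``reached_criterion`` attributes (see
    :class:`~hybridspace.learning_metrics.LearningOutcome`).  ``pretraining``
    maps fish id to a passed/failed flag and contributes the ``pretraining``
    stage; group labels for those fish come from ``pretraining_groups``.
    Each fish may appear at most once per stage.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    seen: set[tuple[str, str]] = set()

    if pretraining is not None:
        if pretraining_groups is None:
            raise ValueError("pretraining flags require pretraining_groups (id -> group)")
        for individual_id, passed in pretraining.items():
            group = pretraining_groups[individual_id]
            if group not in GROUPS:
                raise ValidationError(f"unknown group {group!r}")
            cell = counts.setdefault((group, "pretraining"), [0, 0])
            cell[1] += 1
            cell[0] += int(bool(passed))

    for outcome in outcomes:
        group = outcome.group
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        key = (outcome.individual_id, outcome.task)
        if key in seen:
            raise ValidationError(
                f"{outcome.individual_id!r} appears twice for stage {outcome.task!r}"
            )
        seen.add(key)
        cell = counts.setdefault((group, outcome.task), [0, 0])
        cell[1] += 1
        cell[0] += int(bool(outcome.reached_criterion))

    return CountTable({k: (v[0], v[1]) for k, v in counts.items()})
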