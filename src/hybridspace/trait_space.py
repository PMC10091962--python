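"""Construction of the analysis trait spaces from raw measurements.

Brain-region volumes are estimated from linear dimensions with the ellipsoid
formula V = L·W·H·π/6.  "Relative" traits are residuals from pooled
ordinary-least-squares allometric fits on the log10 scale: brain weight is
taken relative to body length, and each focal region volume relative to the
brain remainder (total brain volume minus the focal region), which avoids
including the region in its own covariate.

Two spaces feed the dispersion/transgression machinery:

* a 3-D **brain morphospace** — relative brain weight, relative telencephalon
  volume, relative optic-tectum volume (sexes pooled);
* a 2-D **cognitive space** — log10 trials-to-criterion in the associative
  and reversal tasks, restricted to fish that reached criterion in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_tables import IndividualRecord, REGIONS, ValidationError
from .learning_metrics import LearningOutcome

__all__ = [
    "TraitMatrix",
    "AllometricFit",
    "ExclusionReport",
    "ellipsoid_volume",
    "allometric_residuals",
    "build_brain_morphospace",
    "build_cognitive_space",
]

BRAIN_TRAIT_NAMES = (
    "rel_log10_brain_weight",
    "rel_log10_telencephalon_volume",
    "rel_log10_optic_tectum_volume",
)
COGNITIVE_TRAIT_NAMES = (
    "log10_trials_associative",
    "log10_trials_reversal",
)


class InsufficientDataError(ValueError):
    """Fewer usable individuals than the operation requires."""


@dataclass
class TraitMatrix:
    """An n×d numeric trait space with aligned ids and group labels."""

    values: np.ndarray
    trait_names: tuple[str, ...]
    individual_ids: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("trait matrix must be 2-D")
        n, d = self.values.shape
        if n < 1:
            raise ValidationError("trait matrix needs at least one row")
        if len(self.trait_names) != d:
            raise ValidationError("trait_names length must equal the number of columns")
        if len(self.individual_ids) != n or len(self.groups) != n:
            raise ValidationError("ids/groups must align with rows")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trait matrix entries must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def group_values(self, group: str) -> np.ndarray:
        mask = np.asarray([g == group for g in self.groups])
        return self.values[mask]

    def subset(self, group: str) -> "TraitMatrix":
        mask = [g == group for g in self.groups]
        if not any(mask):
            raise InsufficientDataError(f"no individuals in group {group!r}")
        idx = np.flatnonzero(mask)
        return TraitMatrix(
            values=self.values[idx],
            trait_names=self.trait_names,
            individual_ids=tuple(self.individual_ids[i] for i in idx),
            groups=tuple(self.groups[i] for i in idx),
        )

    def group_mean(self, group: str) -> np.ndarray:
        return self.group_values(group).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.trait_names))
        frame.insert(0, "group", list(self.groups))
        frame.insert(0, "individual_id", list(self.individual_ids))
        return frame


@dataclass
class AllometricFit:
    """Pooled log10–log10 OLS fit of a trait on a size covariate."""

    slope: float
    intercept: float
    residuals: np.ndarray
    covariate_name: str
    response_name: str


@dataclass
class ExclusionReport:
    """Individuals dropped while building a trait space, with reasons."""

    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def add(self, individual_id: str, reason: str) -> None:
        self.exclusions.append((individual_id, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["individual_id", "reason"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def ellipsoid_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Ellipsoid volume estimate V = L·W·H·π/6 from three linear dimensions.

    Works element-wise on array inputs.  All dimensions must be strictly
    positive.
    """
    length = np.asarray(length_mm, dtype=float)
    width = np.asarray(width_mm, dtype=float)
    height = np.asarray(height_mm, dtype=float)
    if np.any(~np.isfinite(length)) or np.any(length <= 0) \
            or np.any(~np.isfinite(width)) or np.any(width <= 0) \
            or np.any(~np.isfinite(height)) or np.any(height <= 0):
        raise ValidationError("ellipsoid dimensions must be strictly positive and finite")
    out = length * width * height * math.pi / 6.0
    return float(out) if out.ndim == 0 else out


def allometric_residuals(
    response: Sequence[float],
    covariate: Sequence[float],
    response_name: str = "response",
    covariate_name: str = "covariate",
) -> AllometricFit:
    """Pooled OLS of log10(response) on log10(covariate), residuals per fish.

    All groups enter one common fit so that residuals are comparable across
    groups; the residual vector sums to zero by the OLS normal equations.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("response and covariate must be 1-D of equal length")
    if y.size < 3:
        raise InsufficientDataError("allometric fit needs at least 3 individuals")
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValidationError("allometric fit requires strictly positive values")
    log_y = np.log10(y)
    log_x = np.log10(x)
    if np.ptp(log_x) == 0:
        raise ValidationError("degenerate fit: covariate has zero variance")
    model = sm.OLS(log_y, sm.add_constant(log_x)).fit()
    intercept, slope = model.params
    return AllometricFit(
        slope=float(slope),
        intercept=float(intercept),
        residuals=np.asarray(model.resid, dtype=float),
        covariate_name=covariate_name,
        response_name=response_name,
    )


def _region_volumes(record: IndividualRecord) -> dict[str, float] | None:
    """All six region volumes, or None if any region is unmeasured."""
    if set(record.region_dims) != set(REGIONS):
        return None
    return {
        region: ellipsoid_volume(*record.region_dims[region])
        for region in REGIONS
    }


def build_brain_morphospace(
    records: Iterable[IndividualRecord],
) -> tuple[TraitMatrix, ExclusionReport]:
    """Assemble the 3-D brain morphospace from raw morphometrics.

    Axis 1 is the residual of log10 brain weight on log10 body length;
    axes 2–3 are residuals of log10 telencephalon / optic-tectum volume on
    log10 brain-remainder volume.  Total brain volume is the sum of the six
    ellipsoid region volumes; the remainder subtracts the focal region.
    Sexes are pooled.  Individuals missing any input are excluded and listed
    in the report.
    """
    report = ExclusionReport()
    usable: list[tuple[IndividualRecord, dict[str, float]]] = []
    for rec in records:
        rec.validate()
        if rec.brain_weight_mg is None:
            report.add(rec.individual_id, "missing brain weight")
            continue
        volumes = _region_volumes(rec)
        if volumes is None:
            missing = sorted(set(REGIONS) - set(rec.region_dims))
            report.add(rec.individual_id, f"missing region dimensions: {', '.join(missing)}")
            continue
        usable.append((rec, volumes))

    if len(usable) < 3:
        raise InsufficientDataError(
            f"brain morphospace needs >= 3 usable individuals, got {len(usable)}"
        )

    body_length = np.array([rec.body_length_mm for rec, _ in usable])
    brain_weight = np.array([rec.brain_weight_mg for rec, _ in usable])
    total_volume = np.array([sum(v.values()) for _, v in usable])
    telencephalon = np.array([v["telencephalon"] for _, v in usable])
    optic_tectum = np.array([v["optic_tectum"] for _, v in usable])

    axis1 = allometric_residuals(
        brain_weight, body_length, "log10_brain_weight_mg", "log10_body_length_mm"
    ).residuals
    axis2 = allometric_residuals(
        telencephalon,
        total_volume - telencephalon,
        "log10_telencephalon_volume_mm3",
        "log10_brain_remainder_mm3",
    ).residuals
    axis3 = allometric_residuals(
        optic_tectum,
        total_volume - optic_tectum,
        "log10_optic_tectum_volume_mm3",
        "log10_brain_remainder_mm3",
    ).residuals

    matrix = TraitMatrix(
        values=np.column_stack([axis1, axis2, axis3]),
        trait_names=BRAIN_TRAIT_NAMES,
        individual_ids=tuple(rec.individual_id for rec, _ in usable),
        groups=tuple(rec.group for rec, _ in usable),
    )
    return matrix, report


def build_cognitive_space(
    outcomes: Iterable[LearningOutcome],
) -> tuple[TraitMatrix, ExclusionReport]:
    """Assemble the 2-D cognitive space from learning outcomes.

    Axes are log10 trials-to-criterion for the associative and reversal
    tasks.  Only fish that reached criterion in both tasks enter; everyone
    else lands in the exclusion report with the failing task named.
    """
    report = ExclusionReport()
    per_fish: dict[str, dict[str, LearningOutcome]] = {}
    for outcome in outcomes:
        per_fish.setdefault(outcome.individual_id, {})[outcome.task] = outcome

    ids: list[str] = []
    groups: list[str] = []
    rows: list[tuple[float, float]] = []
    for individual_id, tasks in sorted(per_fish.items()):
        associative = tasks.get("associative")
        reversal = tasks.get("reversal")
        if associative is None or not associative.reached_criterion:
            report.add(individual_id, "did not reach criterion in associative task")
            continue
        if reversal is None:
            report.add(individual_id, "no reversal task record")
            continue
        if not reversal.reached_criterion:
            report.add(individual_id, "did not reach criterion in reversal task")
            continue
        ids.append(individual_id)
        groups.append(associative.group)
        rows.append(
            (
                math.log10(associative.trials_to_criterion),
                math.log10(reversal.trials_to_criterion),
            )
        )

    if not rows:
        raise InsufficientDataError("no individuals reached criterion in both tasks")

    matrix = TraitMatrix(
        values=np.asarray(rows, dtype=float),
        trait_names=COGNITIVE_TRAIT_NAMES,
        individual_ids=tuple(ids),
        groups=tuple(groups),
    )
    return matrix, report
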