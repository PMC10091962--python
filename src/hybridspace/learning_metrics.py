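"""Scoring of trial-level learning logs.

An individual "learns" a discrimination when it completes a run of seven
consecutive correct choices (significant under a binomial null at p = 0.5).
The score analysed downstream is the 1-based index of the trial on which the
first such run completes.  Individuals that never complete a run within the
task maximum (40 trials for the associative task, 60 for reversal) are
censored and flagged as not having reached criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_tables import GROUPS, TrialLog, ValidationError, percentage_half_up

__all__ = [
    "DEFAULT_RUN_LENGTH",
    "DEFAULT_MAX_TRIALS",
    "LearningOutcome",
    "trials_to_criterion",
    "score_trial_log",
    "success_rates",
]

DEFAULT_RUN_LENGTH = 7
DEFAULT_MAX_TRIALS = {"associative": 40, "reversal": 60}


@dataclass
class LearningOutcome:
    """Criterion outcome for one fish on one task.

    ``trials_to_criterion`` is the 1-based trial at which the first run of
    ``run_length`` consecutive correct choices ends, or ``None`` if the run
    never completes within ``censored_at`` trials.
    """

    individual_id: str
    task: str
    reached_criterion: bool
    trials_to_criterion: int | None
    n_trials_run: int
    censored_at: int
    group: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.reached_criterion:
            if self.trials_to_criterion is None:
                raise ValidationError("reached_criterion requires trials_to_criterion")
            if not (self.trials_to_criterion <= min(self.censored_at, self.n_trials_run)):
                raise ValidationError(
                    "trials_to_criterion must lie within both the run and the censoring bound"
                )
        elif self.trials_to_criterion is not None:
            raise ValidationError("trials_to_criterion must be absent when criterion not reached")


def trials_to_criterion(
    sequence: Sequence[int],
    run_length: int = DEFAULT_RUN_LENGTH,
    max_trials: int | None = None,
    *,
    individual_id: str = "",
    task: str = "associative",
    group: str | None = None,
    sex: str | None = None,
) -> LearningOutcome:
    """Locate the first criterion run in a chronological binary sequence.

    Parameters
    ----------
    sequence
        Binary outcomes in chronological order (1 = correct).
    run_length
        Number of consecutive correct choices constituting the criterion.
    max_trials
        Censoring bound; runs completing after this trial do not count.
        Defaults per task (40 associative / 60 reversal).
    """
    if len(sequence) == 0:
        raise ValidationError("empty trial sequence")
    if max_trials is None:
        try:
            max_trials = DEFAULT_MAX_TRIALS[task]
        except KeyError:
            raise ValidationError(f"unknown task {task!r} and no max_trials given") from None

    run = 0
    reached_at: int | None = None
    for t, outcome in enumerate(sequence, start=1):
        if outcome not in (0, 1):
            raise ValidationError(f"trial {t}: outcome must be 0 or 1, got {outcome!r}")
        run = run + 1 if outcome == 1 else 0
        if run >= run_length and t <= max_trials and reached_at is None:
            reached_at = t
            # keep scanning only to validate remaining entries
    return LearningOutcome(
        individual_id=individual_id,
        task=task,
        reached_criterion=reached_at is not None,
        trials_to_criterion=reached_at,
        n_trials_run=len(sequence),
        censored_at=max_trials,
        group=group,
        sex=sex,
    )


def score_trial_log(
    log: TrialLog,
    run_length: int = DEFAULT_RUN_LENGTH,
    max_trials: Mapping[str, int] = DEFAULT_MAX_TRIALS,
) -> list[LearningOutcome]:
    """Score every (fish, task) sequence in a trial log."""
    outcomes = []
    for (individual_id, task), seq in sorted(log.sequences.items()):
        group, sex = log.meta[individual_id]
        outcomes.append(
            trials_to_criterion(
                seq,
                run_length=run_length,
                max_trials=max_trials[task],
                individual_id=individual_id,
                task=task,
                group=group,
                sex=sex,
            )
        )
    return outcomes


def success_rates(
    outcomes: Iterable[LearningOutcome],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-(group, task) fraction of fish reaching criterion.

    Returns a tidy frame with integer percentages rounded half-up; groups
    with no tested fish report a missing percentage.  Unknown group labels
    are an error.
    """
    if groups is None:
        groups = GROUPS
    counts: dict[tuple[str, str], list[int]] = {}
    tasks: list[str] = []
    for outcome in outcomes:
        if outcome.group not in groups:
            raise ValidationError(f"unknown group label {outcome.group!r}")
        if outcome.task not in tasks:
            tasks.append(outcome.task)
        cell = counts.setdefault((outcome.group, outcome.task), [0, 0])
        cell[1] += 1
        cell[0] += int(outcome.reached_criterion)

    rows = []
    for task in tasks:
        for group in groups:
            num, den = counts.get((group, task), (0, 0))
            rows.append(
                {
                    "group": group,
                    "task": task,
                    "numerator": num,
                    "denominator": den,
                    "percentage": percentage_half_up(num, den),
                }
            )
    return pd.DataFrame(rows, columns=["group", "task", "numerator", "denominator", "percentage"])
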