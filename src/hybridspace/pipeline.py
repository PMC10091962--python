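"""End-to-end orchestration: trait spaces → KDEs → transgression → geometry.

:func:`run_full_analysis` drives the whole analysis from an
:class:`AnalysisConfig`: it builds the requested trait spaces (3-D brain
morphospace from the trait table, 2-D cognitive space from the trial log),
fits per-group KDEs, measures dispersion hypervolumes, classifies
transgressive hybrids against the parental 95% regions, computes parental
bias and phenotypic mismatch for every hybrid group, and places the observed
statistics within a simulated-hybrid (midparent resampling) null.  Results
are written as one JSON report plus tidy CSV tables; the report is
byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import io_tables, learning_metrics
from .hybrid_null import build_ensemble, percentile_of
from .io_tables import HYBRID_GROUPS
from .kde_space import fit_kde
from .trait_space import TraitMatrix, build_brain_morphospace, build_cognitive_space
from .transgression import classify_transgressive

__all__ = ["AnalysisConfig", "StageError", "run_full_analysis"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Configuration for a full analysis run (YAML/JSON loadable).

    ``n_sim`` defaults mirror the experimental group sizes: 35 simulated
    hybrids for brain morphology, 25 for cognitive performance, 100
    replicates.  Sexes are pooled for brain traits; the cognitive space uses
    females only unless ``cognition_females_only`` is disabled.
    """

    trait_csv: str | None = None
    trial_csv: str | None = None
    spaces: tuple[str, ...] = ("brain", "cognition")
    level: float = 0.95
    n_sim: Mapping[str, int] = field(default_factory=lambda: {"brain": 35, "cognition": 25})
    reps: int = 100
    seed: int = 0
    grid_points_per_axis: int | None = None
    cognition_females_only: bool = True
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        unknown = set(self.spaces) - {"brain", "cognition"}
        if unknown:
            raise ValueError(f"unknown trait spaces: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        if "spaces" in data:
            data["spaces"] = tuple(data["spaces"])
        return cls(**data)

    def echo(self) -> dict:
        payload = asdict(self)
        payload["spaces"] = list(self.spaces)
        payload["n_sim"] = dict(self.n_sim)
        return payload


def _space_seed(seed: int, space: str) -> int:
    # stable small sub-seed per trait space
    offset = {"brain": 1, "cognition": 2}[space]
    return (seed * 1000 + offset) % (2**31 - 1)


def _analyse_space(
    matrix: TraitMatrix,
    space: str,
    config: AnalysisConfig,
    out_dir: Path,
) -> dict:
    """KDE dispersion, transgression, and null geometry for one trait space."""
    present = sorted(set(matrix.groups), key=list(io_tables.GROUPS).index)
    if "P1" not in present or "P2" not in present:
        raise ValueError("both parental groups are required")

    kde_kwargs = dict(level=config.level, grid_points_per_axis=config.grid_points_per_axis)
    parental_kde = {g: fit_kde(matrix.group_values(g), **kde_kwargs) for g in ("P1", "P2")}

    hypervolumes: dict[str, float] = {}
    group_kdes = dict(parental_kde)
    for group in present:
        if group not in group_kdes:
            group_kdes[group] = fit_kde(matrix.group_values(group), **kde_kwargs)
        hypervolumes[group] = group_kdes[group].hypervolume()

    ensemble = build_ensemble(
        matrix.group_values("P1"),
        matrix.group_values("P2"),
        n_sim=config.n_sim[space],
        reps=config.reps,
        seed=_space_seed(config.seed, space),
        level=config.level,
        grid_points_per_axis=config.grid_points_per_axis,
    )
    ensemble.stats.to_csv(out_dir / f"{space}_ensemble.csv", index=False)

    mean_p1 = matrix.group_mean("P1")
    mean_p2 = matrix.group_mean("P2")

    transgression_frames = []
    transgression: dict[str, dict] = {}
    geometry: dict[str, dict] = {}
    for group in present:
        if group not in HYBRID_GROUPS:
            continue
        subset = matrix.subset(group)
        result = classify_transgressive(subset, parental_kde["P1"], parental_kde["P2"])
        transgression[group] = result.to_dict()
        transgression_frames.append(result.flags)

        from .geometry import hybrid_geometry

        geom = hybrid_geometry(subset.values.mean(axis=0), mean_p1, mean_p2)
        entry = geom.to_dict()
        entry["percentiles"] = {}
        for stat, observed in (
            ("hypervolume", hypervolumes[group]),
            ("parental_bias", geom.parental_bias),
            ("phenotypic_mismatch", geom.phenotypic_mismatch),
        ):
            pct, outside = percentile_of(observed, ensemble.stat_values(stat))
            entry["percentiles"][stat] = {"percentile": pct, "outside_central_95": outside}
        geometry[group] = entry

    if transgression_frames:
        import pandas as pd

        pd.concat(transgression_frames, ignore_index=True).to_csv(
            out_dir / f"{space}_transgression.csv", index=False
        )

    return {
        "n_individuals": matrix.n,
        "group_sizes": {g: int(sum(x == g for x in matrix.groups)) for g in present},
        "trait_names": list(matrix.trait_names),
        "parental_kde": {
            g: {
                "bandwidth": parental_kde[g].bandwidth.tolist(),
                "threshold_95": parental_kde[g].threshold_95,
            }
            for g in ("P1", "P2")
        },
        "hypervolumes": hypervolumes,
        "transgression": transgression,
        "geometry": geometry,
        "ensemble": {
            "n_sim": ensemble.n_sim,
            "reps": ensemble.reps,
            "seed": ensemble.seed,
        },
    }


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every configured stage and write the machine-readable report.

    Any stage failure aborts the run with a :class:`StageError` naming the
    stage; partial CSV outputs already written are flagged in the report of
    the failed run only by their absence from ``report.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config": config.echo(), "spaces": {}}
    log_lines = [f"seed={config.seed}", f"spaces={','.join(config.spaces)}"]

    if "brain" in config.spaces:
        try:
            if config.trait_csv is None:
                raise ValueError("brain space requested but no trait_csv configured")
            records = io_tables.read_trait_table(config.trait_csv)
            matrix, exclusions = build_brain_morphospace(records)
            exclusions.write_csv(out_dir / "brain_exclusions.csv")
            space_report = _analyse_space(matrix, "brain", config, out_dir)
            space_report["n_excluded"] = len(exclusions.exclusions)
            report["spaces"]["brain"] = space_report
            log_lines.append(
                f"brain: n={matrix.n} excluded={len(exclusions.exclusions)} "
                f"ensemble_seed={space_report['ensemble']['seed']}"
            )
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("brain", exc) from exc

    if "cognition" in config.spaces:
        try:
            if config.trial_csv is None:
                raise ValueError("cognition space requested but no trial_csv configured")
            log = io_tables.read_trial_log(config.trial_csv)
            outcomes = learning_metrics.score_trial_log(log)
            rates = learning_metrics.success_rates(outcomes)
            rates.to_csv(out_dir / "cognition_success_rates.csv", index=False)
            outcome_rows = [
                {
                    "individual_id": o.individual_id,
                    "group": o.group,
                    "sex": o.sex,
                    "task": o.task,
                    "reached_criterion": int(o.reached_criterion),
                    "trials_to_criterion": o.trials_to_criterion,
                    "n_trials_run": o.n_trials_run,
                }
                for o in outcomes
            ]
            import pandas as pd

            pd.DataFrame(outcome_rows).to_csv(out_dir / "cognition_outcomes.csv", index=False)

            selected = outcomes
            if config.cognition_females_only:
                selected = [o for o in outcomes if o.sex == "F"]
            matrix, exclusions = build_cognitive_space(selected)
            exclusions.write_csv(out_dir / "cognition_exclusions.csv")
            space_report = _analyse_space(matrix, "cognition", config, out_dir)
            space_report["n_excluded"] = len(exclusions.exclusions)
            # via to_json so missing percentages serialize as null, not NaN
            space_report["success_rates"] = json.loads(rates.to_json(orient="records"))
            report["spaces"]["cognition"] = space_report
            log_lines.append(
                f"cognition: n={matrix.n} excluded={len(exclusions.exclusions)} "
                f"ensemble_seed={space_report['ensemble']['seed']}"
            )
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("cognition", exc) from exc

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
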