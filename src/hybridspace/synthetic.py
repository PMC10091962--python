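"""Synthetic study generator with known ground truth.

Emulates a two-species crossing design at the phenotypic level: the two
parental species are distinct multivariate normals, F1 hybrids sit at the
midparent mean (optionally shifted by a heterosis vector and by a mismatch
component injected orthogonal to the inter-parental axis) with covariance
(Σ₁+Σ₂)/4 — the variance of a midparent of independent parental draws — and
F2 hybrids share the F1 mean minus heterosis with covariance inflated by a
scalar segregation factor.  A stated fraction of hybrids can additionally
be displaced by a fixed vector to inject known transgressives.  Trial logs
are generated from per-fish Bernoulli learning curves with a logistic
success probability rising over trials.

Every generator is a pure function of its config (including the seed), so
identical configs yield bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_tables import (
    DIMS,
    GROUPS,
    HYBRID_GROUPS,
    REGIONS,
    IndividualRecord,
    TrialLog,
)
from .trait_space import TraitMatrix

__all__ = [
    "TraitGenConfig",
    "TrialGenConfig",
    "generate_trait_cohort",
    "generate_trial_log",
    "generate_morphometric_cohort",
]


def _as_cov(matrix, d: int, name: str) -> np.ndarray:
    cov = np.asarray(matrix, dtype=float)
    if cov.shape != (d, d):
        raise ValueError(f"{name} must be {d}×{d}")
    if not np.allclose(cov, cov.T):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(f"{name} must be positive definite") from None
    return cov


@dataclass
class TraitGenConfig:
    """Ground-truth parameters for a synthetic trait cohort.

    Defaults describe a moderately diverged species pair: unit covariances,
    parental means 2 SD apart along the first axis, 40 fish per crossing
    group, and no heterosis, mismatch, segregation inflation, or injected
    transgression — an additive null cross.
    """

    d: int = 3
    mu_p1: np.ndarray | None = None
    mu_p2: np.ndarray | None = None
    sigma_p1: np.ndarray | None = None
    sigma_p2: np.ndarray | None = None
    n_per_group: int = 40
    heterosis: np.ndarray | None = None
    mismatch: np.ndarray | None = None
    segregation_factor: float = 1.0
    transgression_fraction: float = 0.0
    transgression_displacement: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.d
        self.mu_p1 = np.zeros(d) if self.mu_p1 is None else np.asarray(self.mu_p1, float)
        default_mu2 = np.zeros(d)
        default_mu2[0] = 2.0
        self.mu_p2 = default_mu2 if self.mu_p2 is None else np.asarray(self.mu_p2, float)
        self.sigma_p1 = np.eye(d) if self.sigma_p1 is None else _as_cov(self.sigma_p1, d, "sigma_p1")
        self.sigma_p2 = np.eye(d) if self.sigma_p2 is None else _as_cov(self.sigma_p2, d, "sigma_p2")
        self.heterosis = np.zeros(d) if self.heterosis is None else np.asarray(self.heterosis, float)
        self.mismatch = np.zeros(d) if self.mismatch is None else np.asarray(self.mismatch, float)
        self.transgression_displacement = (
            np.zeros(d)
            if self.transgression_displacement is None
            else np.asarray(self.transgression_displacement, float)
        )
        for name in ("mu_p1", "mu_p2", "heterosis", "mismatch", "transgression_displacement"):
            if getattr(self, name).shape != (d,):
                raise ValueError(f"{name} must be a {d}-vector")
        if self.segregation_factor < 0:
            raise ValueError("segregation_factor must be >= 0")
        if not (0.0 <= self.transgression_fraction <= 1.0):
            raise ValueError("transgression_fraction must lie in [0, 1]")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def _orthogonal_component(vector: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Part of `vector` perpendicular to `axis` (zero if axis degenerate)."""
    norm = np.linalg.norm(axis)
    if norm == 0:
        return vector.copy()
    u = axis / norm
    return vector - (vector @ u) * u


def generate_trait_cohort(config: TraitGenConfig) -> tuple[TraitMatrix, dict]:
    """Sample a six-group trait cohort and return it with its ground truth.

    The injected mismatch vector is first projected orthogonal to the true
    inter-parental axis, so the ground-truth mismatch magnitude reported in
    the sidecar is exact.  Transgression injection displaces a Bernoulli-
    selected fraction of hybrid individuals by the configured vector.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    midparent = (cfg.mu_p1 + cfg.mu_p2) / 2.0
    mismatch_perp = _orthogonal_component(cfg.mismatch, cfg.mu_p2 - cfg.mu_p1)
    cov_f1 = (cfg.sigma_p1 + cfg.sigma_p2) / 4.0
    cov_f2 = cov_f1 * cfg.segregation_factor

    group_params = {
        "P1": (cfg.mu_p1, cfg.sigma_p1),
        "P2": (cfg.mu_p2, cfg.sigma_p2),
        "F1_P1xP2": (midparent + cfg.heterosis + mismatch_perp, cov_f1),
        "F1_P2xP1": (midparent + cfg.heterosis + mismatch_perp, cov_f1),
        "F2_P1xP2": (midparent + mismatch_perp, cov_f2),
        "F2_P2xP1": (midparent + mismatch_perp, cov_f2),
    }

    values: list[np.ndarray] = []
    ids: list[str] = []
    groups: list[str] = []
    displaced: dict[str, list[str]] = {g: [] for g in HYBRID_GROUPS}
    for group in GROUPS:
        mean, cov = group_params[group]
        sample = rng.multivariate_normal(mean, cov, size=cfg.n_per_group)
        group_ids = [f"{group}_{i + 1:03d}" for i in range(cfg.n_per_group)]
        if group in HYBRID_GROUPS and cfg.transgression_fraction > 0:
            picks = rng.random(cfg.n_per_group) < cfg.transgression_fraction
            sample[picks] += cfg.transgression_displacement
            displaced[group] = [gid for gid, p in zip(group_ids, picks) if p]
        values.append(sample)
        ids.extend(group_ids)
        groups.extend([group] * cfg.n_per_group)

    matrix = TraitMatrix(
        values=np.vstack(values),
        trait_names=tuple(f"axis{j + 1}" for j in range(cfg.d)),
        individual_ids=tuple(ids),
        groups=tuple(groups),
    )
    ground_truth = {
        "true_means": {g: group_params[g][0].tolist() for g in GROUPS},
        "midparent": midparent.tolist(),
        "heterosis": cfg.heterosis.tolist(),
        "mismatch_injected": mismatch_perp.tolist(),
        "mismatch_magnitude": float(np.linalg.norm(mismatch_perp)),
        "segregation_factor": cfg.segregation_factor,
        "transgression_fraction": cfg.transgression_fraction,
        "displaced_ids": displaced,
        "seed": cfg.seed,
    }
    return matrix, ground_truth


@dataclass
class TrialGenConfig:
    """Bernoulli learning-curve parameters for a synthetic trial log.

    ``n_fish`` fish per crossing group; fish ``i`` succeeds at trial ``t``
    with probability logistic(a + uᵢ + b·t), uᵢ ~ Normal(0, individual_sd²).
    Defaults give curves rising from near-chance to near-certain success
    within the associative 40-trial window, matching the high success rates
    typical of these assays.
    """

    n_fish: int = 25
    intercept: float = 0.0
    slope: float = 0.12
    individual_sd: float = 0.5
    max_trials: dict[str, int] = field(
        default_factory=lambda: {"associative": 40, "reversal": 60}
    )
    run_length: int = 7
    groups: tuple[str, ...] = GROUPS
    sex: str = "F"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.individual_sd < 0:
            raise ValueError("individual_sd must be >= 0")
        for task, maximum in self.max_trials.items():
            if maximum < self.run_length:
                raise ValueError(f"max_trials[{task!r}] must be >= run_length")
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_trial_log(config: TrialGenConfig) -> tuple[TrialLog, dict]:
    """Simulate per-trial outcomes for every fish on both tasks.

    Trials are generated until the criterion run completes or the task
    maximum is hit; the reversal task only runs for fish that reached
    criterion in the associative task, as in the assay protocol.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sequences: dict[tuple[str, str], list[int]] = {}
    meta: dict[str, tuple[str, str]] = {}
    abilities: dict[str, float] = {}

    for group in cfg.groups:
        for i in range(cfg.n_fish):
            fish = f"{group}_fish{i + 1:03d}"
            meta[fish] = (group, cfg.sex)
            u = rng.normal(0.0, cfg.individual_sd)
            abilities[fish] = u
            reached_associative = False
            for task in ("associative", "reversal"):
                if task == "reversal" and not reached_associative:
                    break
                maximum = cfg.max_trials[task]
                seq: list[int] = []
                run = 0
                for t in range(1, maximum + 1):
                    p = _logistic(cfg.intercept + u + cfg.slope * t)
                    correct = int(rng.random() < p)
                    seq.append(correct)
                    run = run + 1 if correct else 0
                    if run >= cfg.run_length:
                        break
                sequences[(fish, task)] = seq
                if task == "associative":
                    reached_associative = run >= cfg.run_length

    ground_truth = {
        "intercept": cfg.intercept,
        "slope": cfg.slope,
        "individual_sd": cfg.individual_sd,
        "abilities": abilities,
        "seed": cfg.seed,
    }
    return TrialLog(sequences=sequences, meta=meta), ground_truth


# Raw-morphometrics generator: log-scale allometries with per-group offsets,
# so the downstream residual morphospace has known group structure.
_REGION_BASE_MM = {
    "telencephalon": (1.1, 0.9, 0.7),
    "optic_tectum": (1.4, 1.2, 0.9),
    "cerebellum": (1.0, 0.8, 0.7),
    "dorsal_medulla": (0.8, 0.6, 0.5),
    "hypothalamus": (0.7, 0.6, 0.5),
    "olfactory_bulbs": (0.4, 0.35, 0.3),
}


def generate_morphometric_cohort(
    n_per_group: int = 20,
    seed: int = 0,
    brain_weight_offsets: dict[str, float] | None = None,
    noise_sd: float = 0.03,
) -> list[IndividualRecord]:
    """Simulate raw morphometric records (body, brain weight, region dims).

    Body length is log-normal around 25 mm; brain weight follows a log-log
    allometry on body length with slope 1.2 plus an optional per-group
    offset (in log10 units) and lognormal noise; region dimensions scale
    isometrically with brain size with independent noise per dimension.
    """
    rng = np.random.default_rng(seed)
    offsets = brain_weight_offsets or {}
    records: list[IndividualRecord] = []
    for group in GROUPS:
        for i in range(n_per_group):
            body = float(np.exp(rng.normal(math.log(25.0), 0.08)))
            log_weight = (
                -0.9
                + 1.2 * math.log10(body)
                + offsets.get(group, 0.0)
                + rng.normal(0.0, noise_sd)
            )
            weight = 10.0 ** log_weight
            scale = (body / 25.0) ** 0.9
            region_dims = {}
            for region, base in _REGION_BASE_MM.items():
                region_dims[region] = tuple(
                    float(b * scale * np.exp(rng.normal(0.0, noise_sd))) for b in base
                )
            records.append(
                IndividualRecord(
                    individual_id=f"{group}_{i + 1:03d}",
                    group=group,
                    sex="F" if i % 2 == 0 else "M",
                    body_length_mm=body,
                    brain_weight_mg=weight,
                    region_dims=region_dims,
                )
            )
    return records
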