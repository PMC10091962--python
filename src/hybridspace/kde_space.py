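"""Kernel density estimation of group trait clouds and 95% hypervolumes.

Each group's trait cloud is smoothed with a Gaussian product kernel with a
diagonal (axis-aligned) bandwidth.  The per-axis bandwidth is

    h_j = c* · sigma_j · n^(-1/(d+4)),

where sigma_j is the per-axis sample standard deviation and the single scale
factor c* is chosen by least-squares cross-validation over a fixed
logarithmic grid.  Phenotypic dispersion is the hypervolume of the density
superlevel set that contains 95% of the group's own individuals: the
threshold is the 5% quantile of the **leave-one-out** densities at the
training points, and the volume is counted on a rectangular evaluation
grid.  Leaving each point's own kernel out of its density removes the
optimism of self-smoothing, so the 95% region is calibrated for fresh draws
from the group's distribution — which is what makes "5% transgressive by
chance" hold when test points share the parental distribution.  Membership
queries ("is this hybrid inside the parental 95% region?") evaluate the
kernel sum exactly rather than interpolating from the grid.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CoverageError",
    "DegenerateAxisError",
    "KdeModel",
    "select_bandwidth",
    "fit_kde",
    "contour_threshold",
    "hypervolume",
    "contains",
]

BANDWIDTH_FACTORS = np.geomspace(0.25, 4.0, 25)
DEFAULT_GRID_POINTS = {2: 151, 3: 101}  # per-axis resolution by dimension
DEFAULT_PAD_BANDWIDTHS = 4.0
_CHUNK = 65536


class CoverageError(ValueError):
    """The evaluation grid does not cover the padded data range."""


class DegenerateAxisError(ValueError):
    """An axis has zero sample variance; no bandwidth can be selected."""


class InsufficientDataError(ValueError):
    pass


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2:
        raise ValueError("points must be an n×d matrix")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts


def select_bandwidth(
    points: np.ndarray,
    factors: Sequence[float] | None = None,
) -> np.ndarray:
    """Least-squares cross-validation over a scalar bandwidth factor.

    Evaluates the closed-form LSCV criterion for the Gaussian product kernel

        LSCV(h) = ∫ fhat² − (2/n) Σ_i fhat_{−i}(x_i)

    on the factor grid and returns ``c* · sigma · n^(−1/(d+4))`` per axis.
    Deterministic for fixed input; ties break toward the smaller factor.
    """
    pts = _as_points(points)
    n, d = pts.shape
    if n < d + 2:
        raise InsufficientDataError(f"bandwidth selection needs n >= d + 2, got n={n}, d={d}")
    sigma = pts.std(axis=0, ddof=1)
    if np.any(sigma == 0):
        bad = [j for j in range(d) if sigma[j] == 0]
        raise DegenerateAxisError(f"zero sample variance on axis/axes {bad}")
    if factors is None:
        factors = BANDWIDTH_FACTORS
    base = sigma * n ** (-1.0 / (d + 4))

    # Pairwise Mahalanobis-like squared distances under the base bandwidth;
    # scaling by c only rescales the exponent, so compute them once.
    scaled = pts / base
    sq = np.zeros((n, n))
    for j in range(d):
        diff = scaled[:, j][:, None] - scaled[:, j][None, :]
        sq += diff * diff

    best_factor = None
    best_score = np.inf
    for c in factors:
        h = c * base
        norm = float(np.prod(np.sqrt(2.0 * math.pi) * h))
        kernel = np.exp(-sq / (2.0 * c * c)) / norm          # K_h(x_i - x_j)
        kernel2 = np.exp(-sq / (4.0 * c * c)) / (norm * 2.0 ** (d / 2.0))  # K_{√2·h}
        integral_sq = kernel2.sum() / (n * n)
        loo_mean = (kernel.sum() - n * (1.0 / norm)) / (n * (n - 1))
        score = integral_sq - 2.0 * loo_mean
        if score < best_score - 1e-15:
            best_score = score
            best_factor = c
    return best_factor * base


def _kernel_density(points: np.ndarray, bandwidth: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Exact Gaussian product-kernel density of `points` evaluated at `x`."""
    n, d = points.shape
    norm = n * float(np.prod(np.sqrt(2.0 * math.pi) * bandwidth))
    out = np.empty(x.shape[0])
    for start in range(0, x.shape[0], _CHUNK):
        chunk = x[start : start + _CHUNK]
        sq = np.zeros((chunk.shape[0], n))
        for j in range(d):
            diff = (chunk[:, j][:, None] - points[:, j][None, :]) / bandwidth[j]
            sq += diff * diff
        out[start : start + chunk.shape[0]] = np.exp(-0.5 * sq).sum(axis=1) / norm
    return out


class KdeModel:
    """A fitted Gaussian product-kernel density with its 95% contour level.

    Parameters
    ----------
    points
        Training points, n×d.
    bandwidth
        Per-axis kernel standard deviations; selected by LSCV when omitted.
    grid_spec
        Per-axis ``(min, max, n_steps)``; must cover the data range padded by
        at least :data:`DEFAULT_PAD_BANDWIDTHS` bandwidths.  Built
        automatically when omitted.
    level
        Fraction of training individuals the contour region must contain.
    """

    def __init__(
        self,
        points: np.ndarray,
        bandwidth: np.ndarray | None = None,
        grid_spec: Sequence[tuple[float, float, int]] | None = None,
        level: float = 0.95,
        grid_points_per_axis: int | None = None,
    ) -> None:
        self.points = _as_points(points)
        n, d = self.points.shape
        if not (0.0 < level < 1.0):
            raise ValueError("level must be in (0, 1)")
        self.level = float(level)
        if bandwidth is None:
            bandwidth = select_bandwidth(self.points)
        self.bandwidth = np.asarray(bandwidth, dtype=float).reshape(-1)
        if self.bandwidth.shape != (d,) or np.any(self.bandwidth <= 0):
            raise ValueError("bandwidth must be d positive reals")

        if grid_spec is None:
            n_steps = grid_points_per_axis or DEFAULT_GRID_POINTS.get(d, 101)
            pad = DEFAULT_PAD_BANDWIDTHS * self.bandwidth
            grid_spec = [
                (float(self.points[:, j].min() - pad[j]),
                 float(self.points[:, j].max() + pad[j]),
                 int(n_steps))
                for j in range(d)
            ]
        else:
            grid_spec = [(float(lo), float(hi), int(k)) for lo, hi, k in grid_spec]
            for j, (lo, hi, _k) in enumerate(grid_spec):
                pad = DEFAULT_PAD_BANDWIDTHS * self.bandwidth[j]
                if lo > self.points[:, j].min() - pad or hi < self.points[:, j].max() + pad:
                    raise CoverageError(
                        f"grid axis {j} does not cover the data range padded by "
                        f"{DEFAULT_PAD_BANDWIDTHS} bandwidths"
                    )
        self.grid_spec = grid_spec

        self.train_density = _kernel_density(self.points, self.bandwidth, self.points)
        if n > 1:
            # leave-one-out: strip each point's own kernel from its density
            self_kernel = 1.0 / float(np.prod(np.sqrt(2.0 * math.pi) * self.bandwidth))
            self.train_density_loo = np.maximum(
                (n * self.train_density - self_kernel) / (n - 1), 0.0
            )
        else:
            self.train_density_loo = self.train_density.copy()
        self.threshold_95 = contour_threshold(self, self.level)
        self._grid_density: np.ndarray | None = None

    # -- density machinery ------------------------------------------------

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def density(self, x: np.ndarray) -> np.ndarray:
        """Exact kernel-sum density at arbitrary query points."""
        q = np.asarray(x, dtype=float)
        single = q.ndim == 1
        if single:
            q = q[None, :]
        if q.shape[1] != self.d:
            raise ValueError(f"query dimension {q.shape[1]} != model dimension {self.d}")
        if not np.all(np.isfinite(q)):
            raise ValueError("query points must be finite")
        out = _kernel_density(self.points, self.bandwidth, q)
        return out[0] if single else out

    def contains(self, x: np.ndarray) -> bool | np.ndarray:
        """True where the density at x reaches the contour threshold."""
        dens = self.density(x)
        return dens >= self.threshold_95

    # -- grid machinery ----------------------------------------------------

    def grid_axes(self) -> list[np.ndarray]:
        return [np.linspace(lo, hi, k) for lo, hi, k in self.grid_spec]

    @property
    def cell_volume(self) -> float:
        vol = 1.0
        for lo, hi, k in self.grid_spec:
            if k < 2:
                raise ValueError("grid needs at least 2 points per axis")
            vol *= (hi - lo) / (k - 1)
        return vol

    @property
    def grid_density(self) -> np.ndarray:
        """Density on the evaluation grid (computed on first access)."""
        if self._grid_density is None:
            axes = self.grid_axes()
            mesh = np.meshgrid(*axes, indexing="ij")
            flat = np.column_stack([m.ravel() for m in mesh])
            dens = _kernel_density(self.points, self.bandwidth, flat)
            self._grid_density = dens.reshape([len(a) for a in axes])
        return self._grid_density

    def grid_integral(self) -> float:
        """Riemann integral of the grid density; ~1 for compliant grids."""
        return float(self.grid_density.sum() * self.cell_volume)

    def hypervolume(self) -> float:
        """Volume of the superlevel set {x : fhat(x) >= threshold}."""
        count = int(np.count_nonzero(self.grid_density >= self.threshold_95))
        if count == 0:
            warnings.warn("empty superlevel set; hypervolume is zero", stacklevel=2)
        return count * self.cell_volume

    # -- serialization -----------------------------------------------------

    def to_dict(self, include_points: bool = True) -> dict:
        payload = {
            "bandwidth": self.bandwidth.tolist(),
            "grid_spec": [list(spec) for spec in self.grid_spec],
            "level": self.level,
            "threshold_95": float(self.threshold_95),
        }
        if include_points:
            payload["points"] = self.points.tolist()
        return payload

    def to_json(self, path: str | Path, include_points: bool = True) -> None:
        Path(path).write_text(json.dumps(self.to_dict(include_points), indent=2))


def fit_kde(
    points: np.ndarray,
    bandwidth: np.ndarray | None = None,
    grid_spec: Sequence[tuple[float, float, int]] | None = None,
    level: float = 0.95,
    grid_points_per_axis: int | None = None,
) -> KdeModel:
    """Fit a :class:`KdeModel`; see the class for parameter semantics."""
    return KdeModel(points, bandwidth, grid_spec, level, grid_points_per_axis)


def contour_threshold(model: KdeModel, level: float = 0.95) -> float:
    """Density level whose superlevel set contains `level` of the group.

    Computed as the (1 − level) empirical quantile — linear interpolation
    between order statistics — of the leave-one-out densities at the model's
    own training points.  The leave-one-out evaluation makes the region's
    coverage hold for fresh draws, not just the points that shaped the
    estimate.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    return float(np.quantile(model.train_density_loo, 1.0 - level, method="linear"))


def hypervolume(model: KdeModel) -> float:
    return model.hypervolume()


def contains(model: KdeModel, x: np.ndarray):
    return model.contains(x)
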