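"""Analytical geometry of mean phenotypes: parental bias and mismatch.

Let m1 and m2 be the parental group mean phenotypes, M = (m1 + m2)/2 their
midpoint and u the unit vector from m1 toward m2.  A hybrid group's mean h
decomposes orthogonally relative to the inter-parental axis:

* **parental bias** — |(h − M)·u|, the deviation from the midpoint *along*
  the axis, i.e. toward one parent or the other;
* **phenotypic mismatch** — ‖(h − M) − ((h − M)·u)u‖, the perpendicular
  distance of h from the infinite line through the parental means.

The two satisfy bias² + mismatch² = ‖h − M‖² exactly.  Bias is reported as
an unsigned magnitude plus a categorical direction; mismatch uses the
infinite line (not the segment) so that hybrids beyond a parent still
separate the along-axis and off-axis components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UndefinedAxisError",
    "GeometryResult",
    "hybrid_geometry",
    "parental_bias",
    "phenotypic_mismatch",
]

_DIRECTION_TOL = 1e-12


class UndefinedAxisError(ValueError):
    """The parental means coincide; the inter-parental axis is undefined."""


@dataclass
class GeometryResult:
    hybrid_mean: np.ndarray
    midpoint: np.ndarray
    axis_unit: np.ndarray
    parental_bias: float
    bias_direction: str  # toward_P1 | toward_P2 | none
    phenotypic_mismatch: float
    interparental_distance: float

    def to_dict(self) -> dict:
        return {
            "hybrid_mean": self.hybrid_mean.tolist(),
            "midpoint": self.midpoint.tolist(),
            "axis_unit": self.axis_unit.tolist(),
            "parental_bias": self.parental_bias,
            "bias_direction": self.bias_direction,
            "phenotypic_mismatch": self.phenotypic_mismatch,
            "interparental_distance": self.interparental_distance,
        }


def hybrid_geometry(
    hybrid_mean: np.ndarray,
    mean_p1: np.ndarray,
    mean_p2: np.ndarray,
) -> GeometryResult:
    """Decompose a hybrid mean phenotype relative to the parental axis."""
    h = np.asarray(hybrid_mean, dtype=float)
    m1 = np.asarray(mean_p1, dtype=float)
    m2 = np.asarray(mean_p2, dtype=float)
    if not (h.shape == m1.shape == m2.shape) or h.ndim != 1:
        raise ValueError("hybrid_mean, mean_p1, mean_p2 must be d-vectors of equal length")
    axis = m2 - m1
    distance = float(np.linalg.norm(axis))
    if distance == 0.0:
        raise UndefinedAxisError("parental means coincide; no inter-parental axis")
    u = axis / distance
    midpoint = (m1 + m2) / 2.0
    offset = h - midpoint
    projection = float(offset @ u)
    perpendicular = offset - projection * u
    if projection > _DIRECTION_TOL:
        direction = "toward_P2"
    elif projection < -_DIRECTION_TOL:
        direction = "toward_P1"
    else:
        direction = "none"
    return GeometryResult(
        hybrid_mean=h,
        midpoint=midpoint,
        axis_unit=u,
        parental_bias=abs(projection),
        bias_direction=direction,
        phenotypic_mismatch=float(np.linalg.norm(perpendicular)),
        interparental_distance=distance,
    )


def parental_bias(
    hybrid_mean: np.ndarray, mean_p1: np.ndarray, mean_p2: np.ndarray
) -> tuple[float, str]:
    """Unsigned along-axis deviation from the midparent, with direction."""
    result = hybrid_geometry(hybrid_mean, mean_p1, mean_p2)
    return result.parental_bias, result.bias_direction


def phenotypic_mismatch(
    hybrid_mean: np.ndarray, mean_p1: np.ndarray, mean_p2: np.ndarray
) -> float:
    """Perpendicular distance from the line through the parental means."""
    return hybrid_geometry(hybrid_mean, mean_p1, mean_p2).phenotypic_mismatch
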