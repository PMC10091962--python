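import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridspace.io_tables import REGIONS, IndividualRecord, ValidationError
from hybridspace.learning_metrics import LearningOutcome
from hybridspace.synthetic import generate_morphometric_cohort
from hybridspace.trait_space import (
    InsufficientDataError,
    allometric_residuals,
    build_brain_morphospace,
    build_cognitive_space,
    ellipsoid_volume,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestEllipsoidVolume:
    @pytest.mark.parametrize(
        "dims, expected",
        [
            ((1, 1, 1), math.pi / 6),
            ((2, 1, 1), math.pi / 3),
            ((1.2, 0.9, 0.8), 0.864 * math.pi / 6),  # = 0.45239
        ],
    )
    def test_known_values(self, dims, expected):
        assert ellipsoid_volume(*dims) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValidationError):
            ellipsoid_volume(1.0, 0.0, 1.0)
        with pytest.raises(ValidationError):
            ellipsoid_volume(-1.0, 1.0, 1.0)

    @given(length=positive, width=positive, height=positive,
           scale=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=100, derandomize=True)
    def test_degree_three_homogeneity(self, length, width, height, scale):
        base = ellipsoid_volume(length, width, height)
        scaled = ellipsoid_volume(scale * length, scale * width, scale * height)
        assert scaled == pytest.approx(scale**3 * base, rel=1e-9)


class TestAllometricResiduals:
    def test_exact_power_law_has_zero_residuals(self, rng):
        x = rng.uniform(10, 40, size=30)
        fit = allometric_residuals(x**1.17, x)
        assert fit.slope == pytest.approx(1.17, abs=1e-10)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_residuals_sum_to_zero_and_orthogonal_to_covariate(self, rng):
        x = rng.uniform(5, 50, size=40)
        y = x**1.2 * 10 ** rng.normal(0, 0.05, size=40)
        fit = allometric_residuals(y, x)
        assert abs(fit.residuals.sum()) < 1e-9
        assert abs(fit.residuals @ np.log10(x)) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        """Slope/intercept agree with the closed-form OLS solution."""
        x = rng.uniform(5, 50, size=50)
        y = x**0.8 * 10 ** rng.normal(0, 0.1, size=50)
        lx, ly = np.log10(x), np.log10(y)
        slope = ((lx - lx.mean()) * (ly - ly.mean())).sum() / ((lx - lx.mean()) ** 2).sum()
        intercept = ly.mean() - slope * lx.mean()
        fit = allometric_residuals(y, x)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_response_rescaling_shifts_only_the_intercept(self, rng):
        x = rng.uniform(5, 50, size=25)
        y = x**1.1 * 10 ** rng.normal(0, 0.05, size=25)
        fit1 = allometric_residuals(y, x)
        fit2 = allometric_residuals(3.7 * y, x)
        assert np.allclose(fit1.residuals, fit2.residuals, atol=1e-10)
        assert fit2.slope == pytest.approx(fit1.slope, abs=1e-10)

    def test_zero_variance_covariate_is_degenerate(self):
        with pytest.raises(ValidationError, match="degenerate"):
            allometric_residuals([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            allometric_residuals([1.0, 2.0], [1.0, 2.0])


class TestBrainMorphospace:
    def test_pooled_residual_axes_have_zero_mean(self):
        records = generate_morphometric_cohort(n_per_group=15, seed=11)
        matrix, report = build_brain_morphospace(records)
        assert matrix.d == 3
        assert matrix.n == 90
        assert np.all(np.abs(matrix.values.mean(axis=0)) < 1e-9)
        assert report.exclusions == []

    def test_missing_region_excluded_with_reason(self):
        records = generate_morphometric_cohort(n_per_group=5, seed=2)
        del records[0].region_dims["optic_tectum"]
        records[1].brain_weight_mg = None
        matrix, report = build_brain_morphospace(records)
        assert matrix.n == len(records) - 2
        reasons = dict(report.exclusions)
        assert "optic_tectum" in reasons[records[0].individual_id]
        assert "brain weight" in reasons[records[1].individual_id]

    def test_group_offsets_recovered_in_first_axis(self):
        """Injected log10 brain-weight offsets reappear as axis-1 group means."""
        offset = 0.06
        records = generate_morphometric_cohort(
            n_per_group=120, seed=5, brain_weight_offsets={"F1_P1xP2": offset}, noise_sd=0.02
        )
        matrix, _ = build_brain_morphospace(records)
        shifted = matrix.group_values("F1_P1xP2")[:, 0].mean()
        others = np.concatenate(
            [matrix.group_values(g)[:, 0] for g in ("P1", "P2", "F2_P1xP2")]
        ).mean()
        se = 0.02 / math.sqrt(120)
        assert shifted - others == pytest.approx(offset, abs=4 * se)

    def test_insufficient_data(self):
        records = generate_morphometric_cohort(n_per_group=5, seed=2)[:2]
        with pytest.raises(InsufficientDataError):
            build_brain_morphospace(records)


def _outcome(fish, task, trials, group="P1"):
    return LearningOutcome(fish, task, trials is not None, trials,
                           40 if task == "associative" else 60,
                           40 if task == "associative" else 60, group=group, sex="F")


class TestCognitiveSpace:
    def test_log10_scores(self):
        outcomes = [_outcome("f1", "associative", 10), _outcome("f1", "reversal", 20)]
        matrix, report = build_cognitive_space(outcomes)
        assert matrix.values[0] == pytest.approx([1.0, math.log10(20)])
        assert matrix.values[0, 1] == pytest.approx(1.30103, abs=1e-5)
        assert report.exclusions == []

    def test_minimal_run_score(self):
        outcomes = [_outcome("f1", "associative", 7), _outcome("f1", "reversal", 7)]
        matrix, _ = build_cognitive_space(outcomes)
        assert matrix.values[0, 0] == pytest.approx(math.log10(7), abs=1e-12)
        assert matrix.values[0, 0] == pytest.approx(0.84510, abs=1e-5)

    def test_failures_excluded_with_reason(self):
        outcomes = [
            _outcome("ok", "associative", 12), _outcome("ok", "reversal", 25),
            _outcome("failA", "associative", None),
            _outcome("failR", "associative", 9), _outcome("failR", "reversal", None),
        ]
        matrix, report = build_cognitive_space(outcomes)
        assert matrix.individual_ids == ("ok",)
        reasons = dict(report.exclusions)
        assert "associative" in reasons["failA"]
        assert "reversal" in reasons["failR"]

    def test_no_qualifiers_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            build_cognitive_space([_outcome("f1", "associative", None)])
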