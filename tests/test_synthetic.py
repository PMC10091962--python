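import math

import numpy as np
import pytest

from hybridspace.geometry import phenotypic_mismatch
from hybridspace.learning_metrics import score_trial_log
from hybridspace.synthetic import (
    TraitGenConfig,
    TrialGenConfig,
    generate_trait_cohort,
    generate_trial_log,
)


def run_probability_dp(p, run_length, n_trials):
    """DP oracle: P(a run of `run_length` successes occurs within n_trials)."""
    # state = current streak length (absorbing at run_length)
    state = np.zeros(run_length + 1)
    state[0] = 1.0
    for _ in range(n_trials):
        new = np.zeros_like(state)
        new[run_length] = state[run_length]
        for s in range(run_length):
            new[min(s + 1, run_length)] += state[s] * p
            new[0] += state[s] * (1 - p)
        state = new
    return state[run_length]


class TestTraitCohort:
    def test_bitwise_determinism(self):
        cfg = TraitGenConfig(seed=42)
        a, truth_a = generate_trait_cohort(cfg)
        b, truth_b = generate_trait_cohort(TraitGenConfig(seed=42))
        assert np.array_equal(a.values, b.values)
        assert truth_a == truth_b

    def test_group_sizes_exact_and_values_finite(self):
        matrix, _ = generate_trait_cohort(TraitGenConfig(n_per_group=17, seed=1))
        assert matrix.n == 6 * 17
        for group in set(matrix.groups):
            assert matrix.group_values(group).shape[0] == 17
        assert np.all(np.isfinite(matrix.values))

    def test_additive_null_f1_mean_near_midparent(self):
        cfg = TraitGenConfig(n_per_group=400, seed=3)
        matrix, truth = generate_trait_cohort(cfg)
        midparent = np.asarray(truth["midparent"])
        f1 = matrix.group_values("F1_P1xP2")
        # F1 covariance is (Σ1+Σ2)/4 = I/2 here
        se = np.sqrt(0.5 / 400)
        assert np.all(np.abs(f1.mean(axis=0) - midparent) < 3.5 * se)

    def test_heterosis_shifts_f1_but_not_f2(self):
        shift = np.array([0.0, 0.8, 0.0])
        cfg = TraitGenConfig(n_per_group=600, heterosis=shift, seed=8)
        matrix, truth = generate_trait_cohort(cfg)
        mid = np.asarray(truth["midparent"])
        se = math.sqrt(0.5 / 600)
        assert matrix.group_mean("F1_P2xP1")[1] - mid[1] == pytest.approx(0.8, abs=4 * se)
        assert matrix.group_mean("F2_P2xP1")[1] - mid[1] == pytest.approx(0.0, abs=4 * se)

    def test_injected_mismatch_magnitude_is_exact_in_ground_truth(self):
        # vector with a component along the parental axis: only the
        # orthogonal part must be injected and reported
        cfg = TraitGenConfig(mismatch=np.array([1.0, 2.0, 0.0]), seed=0)
        _, truth = generate_trait_cohort(cfg)
        assert truth["mismatch_magnitude"] == pytest.approx(2.0, rel=1e-12)
        assert np.asarray(truth["mismatch_injected"]) @ np.array([1.0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_pipeline_recovers_injected_mismatch(self):
        """Estimated F1 mismatch tracks the injected orthogonal magnitude."""
        magnitude = 1.0
        estimates = []
        for seed in range(60):
            cfg = TraitGenConfig(
                n_per_group=50, mismatch=np.array([0.0, magnitude, 0.0]), seed=seed
            )
            matrix, _ = generate_trait_cohort(cfg)
            estimates.append(
                phenotypic_mismatch(
                    matrix.group_mean("F1_P1xP2"),
                    matrix.group_mean("P1"),
                    matrix.group_mean("P2"),
                )
            )
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(estimates.mean() - magnitude) < 3 * mc_se

    def test_segregation_factor_inflates_f2_variance(self):
        cfg = TraitGenConfig(n_per_group=800, segregation_factor=3.0, seed=5)
        matrix, _ = generate_trait_cohort(cfg)
        var_f1 = matrix.group_values("F1_P1xP2").var(axis=0).mean()
        var_f2 = matrix.group_values("F2_P1xP2").var(axis=0).mean()
        assert var_f2 / var_f1 == pytest.approx(3.0, rel=0.25)

    def test_transgression_injection_displaces_listed_ids(self):
        cfg = TraitGenConfig(
            n_per_group=50,
            transgression_fraction=0.3,
            transgression_displacement=np.array([0.0, 0.0, 30.0]),
            seed=2,
        )
        matrix, truth = generate_trait_cohort(cfg)
        displaced = truth["displaced_ids"]["F2_P1xP2"]
        values = {i: v for i, v in zip(matrix.individual_ids, matrix.values)}
        assert displaced, "with fraction 0.3 and n=50 some fish must be displaced"
        for fish in displaced:
            assert values[fish][2] > 20

    def test_non_positive_definite_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            TraitGenConfig(d=2, sigma_p1=bad)


class TestTrialLog:
    def test_bitwise_determinism(self):
        a, _ = generate_trial_log(TrialGenConfig(seed=11))
        b, _ = generate_trial_log(TrialGenConfig(seed=11))
        assert a.sequences == b.sequences

    def test_saturating_learner_reaches_criterion_immediately(self):
        log, _ = generate_trial_log(TrialGenConfig(n_fish=20, slope=10.0, seed=0))
        outcomes = score_trial_log(log)
        associative = [o for o in outcomes if o.task == "associative"]
        assert all(o.reached_criterion for o in associative)
        assert all(o.trials_to_criterion <= 8 for o in associative)

    def test_coin_flip_learner_matches_run_occurrence_dp(self):
        """a=b=0, no individual spread: criterion rate equals the DP probability."""
        cfg = TrialGenConfig(n_fish=150, intercept=0.0, slope=0.0,
                             individual_sd=0.0, seed=21)
        log, _ = generate_trial_log(cfg)
        outcomes = [o for o in score_trial_log(log) if o.task == "associative"]
        observed = np.mean([o.reached_criterion for o in outcomes])
        expected = run_probability_dp(0.5, 7, 40)
        n = len(outcomes)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_reversal_only_for_associative_passers(self):
        log, _ = generate_trial_log(TrialGenConfig(n_fish=40, intercept=-1.0,
                                                   slope=0.02, seed=6))
        outcomes = score_trial_log(log)
        passed_assoc = {
            o.individual_id for o in outcomes
            if o.task == "associative" and o.reached_criterion
        }
        ran_reversal = {o.individual_id for o in outcomes if o.task == "reversal"}
        assert ran_reversal == passed_assoc
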