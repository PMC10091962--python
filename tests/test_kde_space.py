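import math

import numpy as np
import pytest

from hybridspace.kde_space import (
    CoverageError,
    DegenerateAxisError,
    KdeModel,
    contour_threshold,
    fit_kde,
    select_bandwidth,
)


def brute_force_density(points, bandwidth, queries):
    """Independent double-loop Gaussian product-kernel sum."""
    n, d = points.shape
    out = []
    for x in queries:
        total = 0.0
        for p in points:
            prod = 1.0
            for j in range(d):
                z = (x[j] - p[j]) / bandwidth[j]
                prod *= math.exp(-0.5 * z * z) / (math.sqrt(2 * math.pi) * bandwidth[j])
            total += prod
        out.append(total / n)
    return np.array(out)


class TestSelectBandwidth:
    def test_scale_equivariance(self, rng):
        pts = rng.standard_normal((80, 2))
        h = select_bandwidth(pts)
        scale = np.array([3.0, 0.5])
        h_scaled = select_bandwidth(pts * scale)
        assert np.allclose(h_scaled, h * scale, rtol=1e-12)

    def test_deterministic(self, rng):
        pts = rng.standard_normal((60, 2))
        assert np.array_equal(select_bandwidth(pts), select_bandwidth(pts.copy()))

    def test_within_factor_two_of_silverman_reference(self, rng):
        """1-D standard-normal sample: LSCV lands near 1.06·σ·n^(−1/5)."""
        pts = rng.standard_normal((500, 1))
        h = select_bandwidth(pts)[0]
        silverman = 1.06 * pts.std(ddof=1) * 500 ** (-1 / 5)
        assert silverman / 2 < h < silverman * 2

    def test_degenerate_axis_error(self):
        pts = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(DegenerateAxisError):
            select_bandwidth(pts)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            select_bandwidth(np.random.default_rng(0).standard_normal((3, 2)))


class TestFitKde:
    def test_density_matches_brute_force(self, rng):
        pts = rng.standard_normal((50, 2))
        model = fit_kde(pts)
        queries = rng.uniform(-3, 3, size=(100, 2))
        expected = brute_force_density(pts, model.bandwidth, queries)
        assert np.max(np.abs(model.density(queries) - expected)) < 1e-12

    def test_single_point_maximal_at_point_and_integrates_to_one(self):
        model = fit_kde(np.array([[0.5, -0.2]]), bandwidth=np.array([0.3, 0.4]))
        at_point = model.density(np.array([0.5, -0.2]))
        nearby = model.density(np.array([[0.6, -0.2], [0.5, 0.1], [1.0, 1.0]]))
        assert np.all(at_point > nearby)
        assert model.grid_integral() == pytest.approx(1.0, abs=0.02)

    def test_two_point_symmetry(self):
        pts = np.array([[-1.0], [1.0]])
        model = fit_kde(pts, bandwidth=np.array([0.5]),
                        grid_spec=[(-6.0, 6.0, 241)])
        dens = model.grid_density
        assert np.max(np.abs(dens - dens[::-1])) < 1e-9

    def test_grid_integral_within_band(self, rng):
        pts = rng.standard_normal((200, 2))
        model = fit_kde(pts)
        assert 0.98 <= model.grid_integral() <= 1.02

    def test_grid_not_covering_data_is_an_error(self, rng):
        pts = rng.standard_normal((50, 1))
        with pytest.raises(CoverageError):
            fit_kde(pts, bandwidth=np.array([0.3]), grid_spec=[(-1.0, 1.0, 101)])


class TestContourThreshold:
    def test_equal_density_configuration(self):
        # four corners of a square: identical leave-one-out densities
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        model = fit_kde(pts, bandwidth=np.array([0.5, 0.5]))
        assert np.allclose(model.train_density_loo, model.train_density_loo[0])
        assert model.threshold_95 == pytest.approx(model.train_density_loo[0], rel=1e-12)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        pts = rng.standard_normal((20, 2))
        model = fit_kde(pts)
        dens = np.sort(model.train_density_loo)
        # (1-0.95) quantile of 20 values: linear interpolation at rank 0.95
        rank = 0.05 * 19
        lo, frac = int(rank), rank - int(rank)
        expected = dens[lo] * (1 - frac) + dens[lo + 1] * frac
        assert contour_threshold(model, 0.95) == pytest.approx(expected, rel=1e-12)

    def test_threshold_decreases_with_level_toward_minimum_density(self, rng):
        pts = rng.standard_normal((40, 2))
        model = fit_kde(pts)
        # larger coverage -> lower threshold; at level -> 1 it hits the
        # smallest training-point density
        assert contour_threshold(model, 0.99) <= contour_threshold(model, 0.95)
        assert contour_threshold(model, 1 - 1e-12) == pytest.approx(
            model.train_density_loo.min(), rel=1e-9
        )

    def test_training_point_coverage(self, rng):
        """The 95% region contains ~95% of the group (and >= 95% by contains)."""
        pts = rng.standard_normal((100, 2))
        model = fit_kde(pts)
        n = 100
        frac_loo = np.mean(model.train_density_loo >= model.threshold_95)
        assert 0.95 - 1 / n <= frac_loo <= 0.95 + 1 / n
        # full-density membership can only add points relative to leave-one-out
        assert np.mean(model.contains(pts)) >= 0.95 - 1 / n


class TestHypervolume:
    def test_translation_invariance(self, rng):
        pts = rng.standard_normal((150, 2))
        m1 = fit_kde(pts)
        m2 = fit_kde(pts + np.array([100.0, -40.0]), bandwidth=m1.bandwidth)
        assert m2.hypervolume() == pytest.approx(m1.hypervolume(), rel=1e-9)

    def test_riemann_convergence_under_refinement(self, rng):
        pts = rng.standard_normal((200, 2))
        m1 = fit_kde(pts, grid_points_per_axis=101)
        m2 = fit_kde(pts, bandwidth=m1.bandwidth, grid_points_per_axis=201)
        assert abs(m2.hypervolume() - m1.hypervolume()) / m1.hypervolume() < 0.05

    def test_monotone_in_level(self, rng):
        pts = rng.standard_normal((100, 2))
        m95 = fit_kde(pts, level=0.95)
        m50 = fit_kde(pts, bandwidth=m95.bandwidth, level=0.5)
        assert m50.hypervolume() <= m95.hypervolume()

    def test_empty_superlevel_warns_and_returns_zero(self, rng):
        pts = rng.standard_normal((30, 1))
        model = fit_kde(pts)
        model.threshold_95 = model.grid_density.max() * 2
        with pytest.warns(UserWarning, match="empty superlevel"):
            assert model.hypervolume() == 0.0


class TestContains:
    def test_high_density_point_inside(self, rng):
        pts = rng.standard_normal((80, 3))
        model = fit_kde(pts)
        assert bool(model.contains(pts.mean(axis=0)))

    def test_far_tail_outside(self, rng):
        pts = rng.standard_normal((80, 3))
        model = fit_kde(pts)
        assert not bool(model.contains(pts.mean(axis=0) + 10 * pts.std(axis=0)))

    def test_dimension_mismatch(self, rng):
        model = fit_kde(rng.standard_normal((30, 2)))
        with pytest.raises(ValueError, match="dimension"):
            model.contains(np.zeros(3))


def test_json_round_trip_fields(tmp_path, rng):
    model = fit_kde(rng.standard_normal((30, 2)))
    path = tmp_path / "kde.json"
    model.to_json(path, include_points=False)
    import json

    payload = json.loads(path.read_text())
    assert payload["bandwidth"] == model.bandwidth.tolist()
    assert payload["threshold_95"] == model.threshold_95
    assert "points" not in payload
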