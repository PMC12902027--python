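"""Inversion building blocks: model curve, prior, objective, grids, refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accesshist import (
    AccessibilityGrid,
    DoseResponseSeries,
    FitConfig,
    equivalent_epitopes,
    fit_histogram,
    histogram_density,
    initial_grid,
    model_curve,
    objective,
    refine_step,
    smoothness_prior,
)
from accesshist.inversion import HistogramFit


def _uniform_log_grid(lo_exp, hi_exp, n_points):
    return AccessibilityGrid(np.logspace(lo_exp, hi_exp, n_points))


class TestModelCurve:
    def test_zero_dilution_gives_zero(self):
        grid = _uniform_log_grid(-6, -2, 5)
        assert model_curve(0.0, grid, np.ones(4)) == 0.0

    def test_single_interval_at_midpoint(self):
        grid = AccessibilityGrid(np.array([1e-4, 3e-4]))
        # arithmetic midpoint 2e-4; evaluating there gives 1 - 1/e
        assert model_curve(2e-4, grid, np.array([1.0])) == pytest.approx(1.0 - np.exp(-1.0), rel=1e-12)

    def test_linearity_in_lambda(self):
        grid = _uniform_log_grid(-6, -2, 6)
        lam = np.array([0.1, 0.4, 0.0, 0.7, 0.2])
        d = np.geomspace(1e-7, 1e-1, 9)
        assert np.allclose(model_curve(d, grid, 3.5 * lam), 3.5 * model_curve(d, grid, lam), rtol=1e-13)

    def test_negative_dilution_rejected(self):
        grid = _uniform_log_grid(-6, -2, 4)
        with pytest.raises(ValueError):
            model_curve(-1.0, grid, np.ones(3))


class TestSmoothnessPrior:
    def test_flat_histogram_has_zero_penalty(self):
        grid = _uniform_log_grid(-6, -2, 5)
        assert smoothness_prior(np.full(4, 0.7), grid, alpha=500.0) == pytest.approx(0.0, abs=1e-20)

    def test_zero_alpha(self):
        grid = _uniform_log_grid(-6, -2, 5)
        assert smoothness_prior(np.array([0.0, 1.0, 0.5, 2.0]), grid, alpha=0.0) == 0.0

    def test_hand_evaluated_quadratic_form(self):
        # 3 intervals of unit log-width, lambda = (0, 1, 0), alpha = m^2 = 16:
        # penalty = (1/1 - 0)^2 + (0 - 1/1)^2 = 2
        grid = _uniform_log_grid(0, 3, 4)
        assert smoothness_prior(np.array([0.0, 1.0, 0.0]), grid, alpha=16.0) == pytest.approx(2.0)


class TestObjective:
    def _series(self):
        d = np.geomspace(1e-5, 1e-2, 7)
        rng = np.random.default_rng(11)
        return DoseResponseSeries(d, rng.uniform(0.1, 1.0, 7), rng.uniform(0.02, 0.1, 7))

    def test_interpolating_lambda_with_zero_alpha_is_zero(self):
        grid = _uniform_log_grid(-5, -2, 4)
        lam = np.array([0.2, 0.5, 0.3])
        d = np.geomspace(1e-5, 1e-2, 5)
        series = DoseResponseSeries(d, model_curve(d, grid, lam), np.full(5, 0.05))
        assert objective(lam, grid, series, alpha=0.0) == pytest.approx(0.0, abs=1e-22)

    def test_doubling_uncertainties_quarters_data_term(self):
        grid = _uniform_log_grid(-5, -2, 4)
        lam = np.array([0.1, 0.2, 0.3])
        s = self._series()
        loose = DoseResponseSeries(s.d, s.r, 2.0 * s.dr)
        assert objective(lam, grid, loose, 0.0) == pytest.approx(objective(lam, grid, s, 0.0) / 4.0, rel=1e-12)

    def test_matches_explicit_quadratic_assembly(self):
        """Independent oracle: assemble the quadratic form from the design
        matrix and difference operator and compare term by term."""
        grid = _uniform_log_grid(-5.3, -1.7, 6)
        s = self._series()
        alpha = 137.0
        rng = np.random.default_rng(5)
        lam = rng.uniform(0, 1, grid.n_intervals)

        A = 1.0 - np.exp(-s.d[:, None] / grid.midpoints[None, :])
        w = grid.log_widths
        D = np.zeros((grid.n_intervals - 1, grid.n_intervals))
        for j in range(grid.n_intervals - 1):
            D[j, j] = -1.0 / w[j]
            D[j, j + 1] = 1.0 / w[j + 1]
        expected = alpha / grid.m**2 * np.sum((D @ lam) ** 2) + np.sum(((s.r - A @ lam) / (2 * s.dr)) ** 2)
        assert objective(lam, grid, s, alpha) == pytest.approx(expected, rel=1e-10)

    def test_zero_uncertainty_rejected_with_flooring_hint(self):
        grid = _uniform_log_grid(-5, -2, 4)
        s = self._series()
        bad = DoseResponseSeries(s.d, s.r, np.where(np.arange(7) == 0, 0.0, s.dr))
        with pytest.raises(ValueError, match="floor"):
            objective(np.ones(3), grid, bad, 500.0)


class TestInitialGrid:
    def test_log_midpoint_construction(self):
        series = DoseResponseSeries(np.array([1e-6, 1e-4, 1e-2]), np.ones(3), np.full(3, 0.01))
        grid = initial_grid(series)
        assert np.allclose(grid.points, [1e-6, 1e-4, 1e-2])

    def test_spans_full_measured_range(self):
        d = np.array([1 / 204800, 1 / 6400, 1 / 400, 1 / 100])
        series = DoseResponseSeries(d, np.ones(4), np.full(4, 0.01))
        grid = initial_grid(series)
        assert grid.points[0] == pytest.approx(1 / 204800)
        assert grid.points[-1] == pytest.approx(1 / 100)
        assert grid.points[1] == pytest.approx(np.sqrt(grid.points[0] * grid.points[-1]), rel=1e-12)


class TestRefineStep:
    def test_loaded_interval_split_with_equal_halves(self):
        grid = _uniform_log_grid(-6, -2, 3)
        new_grid, new_lam = refine_step(grid, np.array([1.0, 0.0]))
        assert np.allclose(new_lam, [0.5, 0.5, 0.0])
        assert new_grid.points[1] == pytest.approx(np.sqrt(grid.points[0] * grid.points[1]), rel=1e-12)

    def test_all_equal_contributions_split_lowest_index(self):
        grid = _uniform_log_grid(-6, -2, 5)
        new_grid, new_lam = refine_step(grid, np.full(4, 0.3))
        assert new_grid.n_intervals == 5
        assert np.allclose(new_lam, [0.15, 0.15, 0.3, 0.3, 0.3])

    @given(st.lists(st.floats(0.0, 5.0), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_total_amount_conserved_exactly(self, lam):
        grid = _uniform_log_grid(-6, -2, 5)
        lam = np.asarray(lam)
        new_grid, new_lam = refine_step(grid, lam)
        j = int(np.flatnonzero(~np.isin(new_grid.points, grid.points))[0]) - 1
        # the two halves recombine to the parent amount without rounding loss
        assert new_lam[j] + new_lam[j + 1] == lam[j]
        assert np.array_equal(np.delete(new_lam, (j, j + 1)), np.delete(lam, j))


class TestHistogramOutputs:
    def _fit(self, lam, lo=-6, hi=-2):
        grid = _uniform_log_grid(lo, hi, len(lam) + 1)
        return HistogramFit(grid, np.asarray(lam, dtype=float), 0.0, FitConfig())

    def test_density_heights_per_log_width(self):
        fit = self._fit([1.0], 0, 1)  # one-decade interval
        assert histogram_density(fit).heights[0] == pytest.approx(1.0)
        fit2 = self._fit([1.0], 0, 0.5)  # half-decade interval
        assert histogram_density(fit2).heights[0] == pytest.approx(2.0)

    def test_area_identity(self):
        rng = np.random.default_rng(3)
        fit = self._fit(rng.uniform(0, 2, 6))
        assert histogram_density(fit).area == pytest.approx(fit.total_mass, rel=1e-12)

    def test_equivalent_epitopes_full_and_disjoint_ranges(self):
        fit = self._fit([0.2, 0.3, 0.5])
        assert equivalent_epitopes(fit, 1e-7, 1.0) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            assert equivalent_epitopes(fit, 1.0, 10.0) == 0.0


class TestFitHistogram:
    def test_zero_responses_give_empty_histogram(self):
        d = np.geomspace(1e-5, 1e-2, 8)
        series = DoseResponseSeries(d, np.zeros(8), np.full(8, 0.01))
        fit = fit_histogram(series, FitConfig(refinement_cycles=5, nm_iterations=100))
        assert fit.total_mass <= 1e-6 * 0.01

    def test_noise_free_single_class_recovery(self, single_class, fourfold_ladder):
        from accesshist import NoiseSpec, generate_series

        series = generate_series(single_class, fourfold_ladder, NoiseSpec(replicates=2, cv=0.0, seed=0)).series
        fit = fit_histogram(series)
        assert 0.9 <= fit.total_mass <= 1.1
        near = equivalent_epitopes(fit, 10**-4.5, 10**-3.5)
        assert near >= 0.9 * fit.total_mass

    def test_determinism(self, noisy_single_series):
        cfg = FitConfig(refinement_cycles=8, nm_iterations=200)
        f1 = fit_histogram(noisy_single_series, cfg)
        f2 = fit_histogram(noisy_single_series, cfg)
        assert np.array_equal(f1.lambdas, f2.lambdas)
        assert np.array_equal(f1.grid.points, f2.grid.points)
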