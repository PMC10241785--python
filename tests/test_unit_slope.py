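"""Unit-level averaging slopes: recovery, oracles, invariances, attenuation."""

import numpy as np
import pytest

from pairavg import (
    GeneratorConfig,
    condition_means,
    constant_coefficient,
    generate_dataset,
    normal_coefficient,
    per_unit_slopes,
    population_slope,
    responsive_unit_mask,
)
from pairavg.design import constituent_indices
from pairavg.synth import expected_abscissa_reliability


def ols_oracle(x, y):
    """Normal-equations fit, independent of the implementation under test."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[1], beta[0]


class TestConditionMeans:
    def test_run_free_identity(self):
        ds = generate_dataset(GeneratorConfig(n_units=6, n_runs=0, noise_sd=0.0))
        np.testing.assert_array_equal(condition_means(ds), ds.values)

    def test_mean_over_runs(self, table4):
        from pairavg import ResponseDataset

        v = np.zeros((1, 20, 2))
        v[0, 0] = [1.0, 3.0]
        ds = ResponseDataset(values=v, table=table4)
        assert condition_means(ds)[0, 0] == 2.0

    def test_noise_free_recovers_generator_truth(self):
        config = GeneratorConfig(n_units=15, n_runs=4, noise_sd=0.0, seed=3)
        ds, truth = generate_dataset(config, 0, return_truth=True)
        np.testing.assert_allclose(condition_means(ds), truth.condition_means, atol=1e-14)


class TestResponsiveMask:
    def test_planted_dead_units_excluded_exactly(self, table4, rng):
        means = rng.lognormal(size=(50, 20))
        dead = rng.choice(50, size=5, replace=False)
        top_cols = [table4.index(c.id) for c in table4.singles if c.top_category]
        means[np.ix_(dead, top_cols)] = 2.0  # constant across top singles
        mask = responsive_unit_mask(means, table4)
        assert set(np.flatnonzero(~mask)) == set(dead)

    def test_variable_units_pass(self, table4, rng):
        means = rng.lognormal(size=(10, 20))
        assert responsive_unit_mask(means, table4).all()


class TestPopulationSlope:
    @pytest.mark.parametrize("c", [0.25, 0.5, 0.55, 0.75, 1.0])
    def test_noise_free_recovery_exact(self, c, table4):
        config = GeneratorConfig(
            n_units=200, n_runs=2, noise_sd=0.0, coefficient=constant_coefficient(c), seed=31
        )
        ds = generate_dataset(config)
        res = population_slope(condition_means(ds), table4)
        assert res.population_slope == pytest.approx(c, abs=1e-12)
        assert res.population_intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, table4, rng):
        means = rng.lognormal(size=(18, 20))
        res = population_slope(means, table4)
        pair_idx, top_idx, bottom_idx = constituent_indices(table4)
        x = (means[:, top_idx] + means[:, bottom_idx]).mean(axis=1)
        y = means[:, pair_idx].mean(axis=1)
        slope, intercept = ols_oracle(x, y)
        assert res.population_slope == pytest.approx(slope, abs=1e-10)
        assert res.population_intercept == pytest.approx(intercept, abs=1e-10)

    def test_invariant_to_unit_permutation_and_rescaling(self, table4, rng):
        means = rng.lognormal(size=(30, 20))
        base = population_slope(means, table4).population_slope
        perm = rng.permutation(30)
        assert population_slope(means[perm], table4).population_slope == pytest.approx(
            base, abs=1e-12
        )
        assert population_slope(3.7 * means, table4).population_slope == pytest.approx(
            base, abs=1e-12
        )

    def test_mask_restricts_units(self, table4, rng):
        means = rng.lognormal(size=(20, 20))
        mask = np.zeros(20, dtype=bool)
        mask[:8] = True
        res = population_slope(means, table4, mask)
        direct = population_slope(means[:8], table4)
        assert res.n_units_used == 8
        assert res.population_slope == pytest.approx(direct.population_slope, abs=1e-12)

    def test_degenerate_abscissae_rejected(self, table4):
        means = np.ones((5, 20))
        with pytest.raises(ValueError):
            population_slope(means, table4)

    def test_errors_in_variables_attenuation_matches_closed_form(self):
        # mean measured slope over many noisy subjects ~ c * reliability of
        # the summed-single abscissa
        noise_sd, n_runs, c = 1.2, 10, 0.5
        config = GeneratorConfig(
            n_units=300, n_runs=n_runs, noise_sd=noise_sd,
            coefficient=constant_coefficient(c), seed=37,
        )
        slopes = []
        for i in range(200):
            ds = generate_dataset(config, i)
            slopes.append(population_slope(condition_means(ds), ds.table).population_slope)
        rho = expected_abscissa_reliability(config.tuning.variance(), noise_sd, n_runs)
        assert rho < 0.8  # the regime actually attenuates
        assert np.mean(slopes) == pytest.approx(c * rho, abs=0.02)


class TestPerUnitSlopes:
    def test_exact_half_sum_gives_half(self, table4):
        config = GeneratorConfig(
            n_units=40, n_runs=2, noise_sd=0.0, coefficient=constant_coefficient(0.5), seed=41
        )
        ds = generate_dataset(config)
        slopes = per_unit_slopes(condition_means(ds), table4)
        np.testing.assert_allclose(slopes, 0.5, atol=1e-12)

    def test_max_rule_matches_ols_oracle(self, table4):
        config = GeneratorConfig(
            n_units=25, n_runs=2, noise_sd=0.0, combination_rule="max", seed=43
        )
        ds = generate_dataset(config)
        means = condition_means(ds)
        slopes = per_unit_slopes(means, table4)
        pair_idx, top_idx, bottom_idx = constituent_indices(table4)
        for u in range(25):
            x = means[u, top_idx] + means[u, bottom_idx]
            y = means[u, pair_idx]
            assert slopes[u] == pytest.approx(ols_oracle(x, y)[0], abs=1e-10)

    def test_heterogeneous_coefficients_recovered(self, table4):
        config = GeneratorConfig(
            n_units=100, n_runs=2, noise_sd=0.0,
            coefficient=normal_coefficient(0.5, 0.1), seed=47,
        )
        ds, truth = generate_dataset(config, 0, return_truth=True)
        slopes = per_unit_slopes(condition_means(ds), table4)
        np.testing.assert_allclose(slopes, truth.coefficients, atol=1e-10)

    def test_degenerate_unit_gets_nan(self, table4, rng):
        means = rng.lognormal(size=(4, 20))
        means[2] = 1.0  # every pair sums to the same abscissa
        slopes = per_unit_slopes(means, table4)
        assert np.isnan(slopes[2]) and not np.isnan(slopes[[0, 1, 3]]).any()
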