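"""Pattern-level statistics: z-normalization, split-half ratios, sweeps."""

import numpy as np
import pytest
from scipy import stats

from pairavg import (
    GeneratorConfig,
    ResponseDataset,
    condition_means,
    constant_coefficient,
    generate_dataset,
    noiseless_pattern_averaging,
    normal_coefficient,
    pattern_correlation,
    split_half_pattern_ratio,
    weight_sweep,
    znormalize,
)
from pairavg.design import constituent_indices


class TestZnormalize:
    def test_every_slice_standardized(self, averaging_dataset):
        z = znormalize(averaging_dataset)
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_idempotent(self, averaging_dataset):
        z1 = znormalize(averaging_dataset)
        z2 = znormalize(z1)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-12)

    def test_three_unit_slice_hand_value(self, table4):
        # sample-SD convention: (1,2,3) -> (-1, 0, 1)
        v = np.tile(np.array([1.0, 2.0, 3.0])[:, None], (1, 20))
        z = znormalize(ResponseDataset(values=v, table=table4))
        np.testing.assert_allclose(z.values[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_slice_error_names_condition(self, table4, rng):
        v = rng.normal(size=(5, 20, 2))
        v[:, 3, 1] = 7.0
        with pytest.raises(ValueError, match="run 2"):
            znormalize(ResponseDataset(values=v, table=table4))


class TestPatternCorrelation:
    def test_self_and_negated(self, rng):
        p = rng.normal(size=50)
        assert pattern_correlation(p, p) == pytest.approx(1.0)
        assert pattern_correlation(p, -p) == pytest.approx(-1.0)

    def test_matches_scipy(self):
        p = np.array([1.0, 2.0, 3.0, 4.0])
        q = np.array([1.0, 2.0, 3.0, 5.0])
        assert pattern_correlation(p, q) == pytest.approx(
            stats.pearsonr(p, q).statistic, abs=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            pattern_correlation(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            pattern_correlation(np.arange(2.0), np.arange(2.0))


class TestSplitHalfRatio:
    def test_noise_free_averaging_actual_is_one_averaged_slightly_below(
        self, averaging_dataset
    ):
        # the ceiling is exact; the averaged-pair correlation is capped just
        # below 1 because the constituents are averaged after per-condition
        # z-scoring (see docs/methods.md)
        res = split_half_pattern_ratio(averaging_dataset)
        np.testing.assert_allclose(res.actual_r, 1.0, atol=1e-12)
        assert np.all(res.averaged_r <= 1.0 + 1e-12)
        assert np.all(res.averaged_r > 0.95)
        assert 0.97 < res.mean_ratio <= 1.0 + 1e-12

    def test_ratio_exact_when_averaging_precedes_normalization(self, averaging_dataset):
        # without the z-scoring step the noise-free ratio is exactly 1
        res = split_half_pattern_ratio(averaging_dataset, normalize=False)
        np.testing.assert_allclose(res.ratio, 1.0, atol=1e-12)

    def test_degenerate_weights_on_top_only_pairs(self, table4):
        # pair pattern equals the top constituent -> weights (1, 0) are exact
        config = GeneratorConfig(
            n_units=60, n_runs=4, noise_sd=0.0,
            combination_rule="weighted_average", coefficient=constant_coefficient(1.0),
            seed=53,
        )
        ds = generate_dataset(config)
        res = split_half_pattern_ratio(ds, weights=(1.0, 0.0))
        np.testing.assert_allclose(res.ratio, 1.0, atol=1e-12)

    def test_max_rule_ratio_below_one(self):
        config = GeneratorConfig(n_units=50, n_runs=4, noise_sd=0.0,
                                 combination_rule="max", seed=59)
        ds = generate_dataset(config)
        res = split_half_pattern_ratio(ds)
        assert res.mean_ratio < 0.99

    def test_matches_direct_pearson_computation(self, noisy_averaging_config):
        ds = generate_dataset(noisy_averaging_config, 0)
        res = split_half_pattern_ratio(ds)
        z = znormalize(ds)
        odd = z.values[:, :, 0::2].mean(axis=2)
        even = z.values[:, :, 1::2].mean(axis=2)
        pair_idx, top_idx, bottom_idx = constituent_indices(ds.table)
        for k in range(12):
            actual = stats.pearsonr(odd[:, pair_idx[k]], even[:, pair_idx[k]]).statistic
            r1 = stats.pearsonr(
                odd[:, pair_idx[k]], 0.5 * (even[:, top_idx[k]] + even[:, bottom_idx[k]])
            ).statistic
            r2 = stats.pearsonr(
                even[:, pair_idx[k]], 0.5 * (odd[:, top_idx[k]] + odd[:, bottom_idx[k]])
            ).statistic
            assert res.actual_r[k] == pytest.approx(actual, abs=1e-12)
            assert res.averaged_r[k] == pytest.approx(0.5 * (r1 + r2), abs=1e-12)

    def test_low_ceiling_pairs_excluded_from_mean(self, averaging_dataset):
        v = averaging_dataset.values.copy()
        pair_idx, _, _ = constituent_indices(averaging_dataset.table)
        # flip the first pair's even runs so its split-half ceiling is -1
        v[:, pair_idx[0], 1::2] *= -1.0
        ds = ResponseDataset(values=v, table=averaging_dataset.table)
        res = split_half_pattern_ratio(ds)
        assert res.actual_r[0] == pytest.approx(-1.0, abs=1e-6)
        assert np.isnan(res.ratio[0])
        assert np.isfinite(res.mean_ratio)

    def test_under_noise_mean_ratio_at_least_one(self, noisy_averaging_config):
        # averaging two single patterns halves the noise variance, so the
        # averaged-pair correlation exceeds the actual-pair ceiling on average
        import dataclasses

        ratios = []
        for i in range(100):
            ds = generate_dataset(noisy_averaging_config, i)
            ratios.append(split_half_pattern_ratio(ds).mean_ratio)
        assert np.mean(ratios) >= 1.0

    def test_fisher_z_close_to_arithmetic_for_moderate_r(self, noisy_averaging_config):
        ds = generate_dataset(noisy_averaging_config, 1)
        a = split_half_pattern_ratio(ds)
        f = split_half_pattern_ratio(ds, fisher_z=True)
        assert f.mean_ratio == pytest.approx(a.mean_ratio, abs=0.05)


class TestNoiseless:
    @pytest.mark.parametrize("c", [0.3, 0.5, 1.0, 2.0])
    def test_constant_coefficient_gives_r_one(self, c, table4):
        config = GeneratorConfig(
            n_units=80, n_runs=0, noise_sd=0.0, coefficient=constant_coefficient(c), seed=61
        )
        means = generate_dataset(config).values
        res = noiseless_pattern_averaging(means, table4)
        np.testing.assert_allclose(res.averaged_r, 1.0, atol=1e-12)

    def test_affine_transform_invariance(self, table4, rng):
        means = rng.lognormal(size=(40, 20))
        base = noiseless_pattern_averaging(means, table4)
        moved = noiseless_pattern_averaging(2.5 * means + 1.0, table4)
        np.testing.assert_allclose(base.averaged_r, moved.averaged_r, atol=1e-12)

    def test_degradation_monotone_in_coefficient_spread(self, table4):
        scores = []
        for sd in (0.05, 0.15, 0.3):
            per_seed = []
            for i in range(30):
                config = GeneratorConfig(
                    n_units=500, n_runs=0, noise_sd=0.0,
                    coefficient=normal_coefficient(0.5, sd), seed=67,
                )
                per_seed.append(
                    noiseless_pattern_averaging(
                        generate_dataset(config, i).values, table4
                    ).mean_averaged_r
                )
            scores.append(np.mean(per_seed))
        assert scores[0] > scores[1] > scores[2]

    def test_matches_direct_computation(self, table4, rng):
        means = rng.lognormal(size=(60, 20))
        res = noiseless_pattern_averaging(means, table4, weights=(0.3, 0.7))
        pair_idx, top_idx, bottom_idx = constituent_indices(table4)
        for k in range(12):
            pred = 0.3 * means[:, top_idx[k]] + 0.7 * means[:, bottom_idx[k]]
            assert res.averaged_r[k] == pytest.approx(
                stats.pearsonr(means[:, pair_idx[k]], pred).statistic, abs=1e-12
            )


class TestWeightSweep:
    def test_equal_weight_data_argmax_half_split_half(self, averaging_dataset):
        res = weight_sweep(averaging_dataset, mode="split_half")
        assert res.argmax_weight == 0.5
        assert res.weights.shape == (11,)

    @pytest.mark.parametrize("w", [0.2, 0.5, 0.8])
    def test_generator_weight_recovered_noiseless(self, w, table4):
        config = GeneratorConfig(
            n_units=300, n_runs=0, noise_sd=0.0,
            combination_rule="weighted_average", coefficient=constant_coefficient(w),
            seed=71,
        )
        means = generate_dataset(config).values
        res = weight_sweep(means, table4, mode="noiseless")
        assert res.argmax_weight == pytest.approx(w)

    def test_curve_symmetric_for_equal_weight_exchangeable_tuning(self, table4):
        config = GeneratorConfig(
            n_units=400, n_runs=0, noise_sd=0.0, coefficient=constant_coefficient(0.5),
            seed=73,
        )
        curves = []
        for i in range(50):
            means = generate_dataset(config, i).values
            curves.append(weight_sweep(means, table4, mode="noiseless").scores)
        mean_curve = np.mean(curves, axis=0)
        np.testing.assert_allclose(mean_curve, mean_curve[::-1], atol=0.02)

    def test_bad_step_rejected(self, averaging_dataset):
        with pytest.raises(ValueError):
            weight_sweep(averaging_dataset, mode="split_half", step=0.3)
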