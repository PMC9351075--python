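import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from profilemix import (
    IndicatorMatrix,
    ModelSpec,
    ParameterSet,
    aic,
    back_transform,
    bic,
    compare_models,
    fit_em,
    fit_report,
    high_posterior_fraction,
    relative_entropy,
    residual_variance_fractions,
    sensitivity_grid,
    standardize,
    track_class_evolution,
    two_reference_spec,
)
from profilemix.evaluation import sweep_classes
from profilemix.lpa import FittedModel


class TestInformationCriteria:
    def test_aic_trivial_zero(self):
        assert aic(0.0, 0) == 0.0

    def test_bic_n_one_log_vanishes(self):
        assert bic(0.0, 1, 1) == 0.0

    def test_aic_bic_from_fit_statistics(self):
        # five-class model with two fully specified reference classes:
        # LL = −1072.99, k = 32, n = 120
        assert abs(aic(-1072.99, 32) - 2209.973) < 0.02
        assert abs(bic(-1072.99, 32, 120) - 2299.172) < 0.02


class TestRelativeEntropy:
    def test_one_hot_is_one(self):
        tau = np.eye(4)[[0, 1, 2, 3, 0, 1]]
        assert relative_entropy(tau) == 1.0

    def test_uniform_is_zero(self):
        tau = np.full((10, 5), 0.2)
        assert abs(relative_entropy(tau)) < 1e-12

    def test_single_class_undefined(self):
        assert math.isnan(relative_entropy(np.ones((10, 1))))

    def test_matches_direct_double_sum(self, rng):
        tau = rng.dirichlet(np.ones(3), size=10)
        direct = 0.0
        for i in range(10):
            for c in range(3):
                direct += -tau[i, c] * math.log(tau[i, c])
        expected = 1.0 - direct / (10 * math.log(3))
        assert abs(relative_entropy(tau) - expected) < 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_sharpening_rows_never_decreases_entropy(self, seed):
        rng = np.random.default_rng(seed)
        tau = rng.dirichlet(np.ones(3), size=8)
        power = tau ** 2
        sharper = power / power.sum(axis=1, keepdims=True)
        assert relative_entropy(sharper) >= relative_entropy(tau) - 1e-12


class TestHighPosteriorFraction:
    def test_one_hot_rows(self):
        assert high_posterior_fraction(np.eye(3)[[0, 1, 2]]) == 1.0

    def test_uniform_rows(self):
        assert high_posterior_fraction(np.full((5, 2), 0.5)) == 0.0

    def test_constructed_seven_of_ten(self):
        rows = [[0.9, 0.1]] * 7 + [[0.6, 0.4]] * 3
        assert high_posterior_fraction(np.array(rows)) == 0.7

    def test_threshold_outside_informative_range_warns(self):
        with pytest.warns(UserWarning):
            high_posterior_fraction(np.full((4, 2), 0.5), threshold=0.3)


class TestResidualVarianceFractions:
    def test_one_class_model_explains_nothing(self, random_data):
        spec = ModelSpec(n_classes=1)
        init = ParameterSet([1.0], np.zeros((1, 3)), np.ones(3))
        fit = fit_em(random_data, spec, init)
        frac = residual_variance_fractions(fit, random_data)
        # sigma^2 uses denominator n, the ratio n−1: off by (n−1)/n
        assert np.allclose(frac, 19 / 20, atol=1e-10)

    def test_perfectly_separated_classes_explain_everything(self):
        y = np.array([[-2.0]] * 10 + [[2.0]] * 10)
        y += np.linspace(-1e-3, 1e-3, 20)[:, None]  # break exact degeneracy
        data = IndicatorMatrix(y, [f"s{i}" for i in range(20)], ["y"])
        init = ParameterSet([0.5, 0.5], np.array([[-2.0], [2.0]]), [0.1])
        fit = fit_em(data, ModelSpec(n_classes=2), init)
        assert residual_variance_fractions(fit, data)[0] < 0.01


class TestFitReportAndComparison:
    def test_report_consistent_with_recomputation(self, default_sim):
        data = default_sim.primary
        spec = two_reference_spec(5, 7)
        from profilemix import run_multistart

        ms = run_multistart(data, spec, n_starts=40, seed=2)
        rep = fit_report(ms.best, data, ms)
        assert rep.k == 32
        assert abs(rep.aic - aic(rep.loglik, rep.k)) < 1e-9
        assert abs(rep.bic - bic(rep.loglik, rep.k, data.n)) < 1e-9
        assert abs(rep.class_proportions.sum() - 1.0) < 1e-10

    def test_sweep_parameter_column(self, default_sim):
        reports, _ = sweep_classes(default_sim.primary, range(1, 4),
                                   n_starts=8, seed=0)
        df = compare_models(reports)
        assert list(df.k) == [14, 22, 30]

    def test_comparison_invariant_to_input_order(self, default_sim):
        reports, _ = sweep_classes(default_sim.primary, range(1, 4),
                                   n_starts=8, seed=0)
        a = compare_models(reports)
        b = compare_models(reports[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_mixed_sample_sizes_rejected(self, default_sim, random_data):
        r1, _ = sweep_classes(default_sim.primary, [1], n_starts=2, seed=0)
        r2, _ = sweep_classes(random_data, [1], n_starts=2, seed=0)
        with pytest.raises(ValueError):
            compare_models(r1 + r2)


class TestSensitivityGrid:
    def test_true_reference_level_dominates_extreme_levels(self, default_sim):
        data = default_sim.primary
        base = two_reference_spec(5, 7)
        levels = [(-0.5, 0.5), (-2.0, 2.0)]
        df = sensitivity_grid(data, base, levels, n_starts=30, seed=1)
        assert len(df) == 2
        good = df[(df.low == -0.5)].iloc[0]
        bad = df[(df.low == -2.0)].iloc[0]
        assert good.aic < bad.aic and good.bic < bad.bic

    def test_empty_level_list(self, default_sim):
        base = two_reference_spec(5, 7)
        df = sensitivity_grid(default_sim.primary, base, [], n_starts=4, seed=0)
        assert len(df) == 0

    def test_requires_two_fixed_classes(self, default_sim):
        with pytest.raises(ValueError):
            sensitivity_grid(default_sim.primary, ModelSpec(n_classes=3),
                             [(-0.5, 0.5)])


class TestTrackClassEvolution:
    def _fit(self, data, C, seed):
        from profilemix import run_multistart

        return run_multistart(data, ModelSpec(n_classes=C),
                              n_starts=30, seed=seed).best

    def test_identical_models_match_with_zero_distance(self, default_sim):
        m = self._fit(default_sim.primary, 2, 0)
        smap = track_class_evolution([m, m])
        assert np.allclose(smap.matches.distance, 0.0)
        assert (smap.matches.class_small == smap.matches.class_large).all()

    def test_shared_classes_matched_across_sizes(self, default_sim):
        m2 = self._fit(default_sim.primary, 2, 0)
        m3 = self._fit(default_sim.primary, 3, 1)
        smap = track_class_evolution([m2, m3])
        assert len(smap.matches) == 2  # each small class matched once
        assert smap.matches.class_large.nunique() == 2

    def test_proportion_trajectory_table_shape(self, default_sim):
        models = [self._fit(default_sim.primary, C, C) for C in (2, 3, 4)]
        smap = track_class_evolution(models)
        assert list(smap.proportions.n_classes) == [2, 3, 4]


class TestBackTransform:
    def test_zero_z_maps_to_raw_mean_and_median_percentile(self, small_raw_data):
        z = standardize(small_raw_data)
        params = ParameterSet([1.0], np.zeros((1, 2)), np.ones(2))
        table = back_transform(params, z)
        assert np.allclose(table.raw_mean, z.raw_means)
        assert np.allclose(table.percentile, 50.0)

    def test_half_sd_below_on_iq_scale(self):
        values = np.column_stack([
            100 + 15 * np.array([-1.2, -0.3, 0.4, 1.1, 0.0, -0.8, 0.8]),
        ])
        data = IndicatorMatrix(values, [f"s{i}" for i in range(7)], ["fsiq"])
        z = standardize(data)
        # force known raw moments for the check
        z.raw_means[:] = 100.0
        z.raw_sds[:] = 15.0
        params = ParameterSet([1.0], np.array([[-0.5]]), np.ones(1))
        row = back_transform(params, z).iloc[0]
        assert np.isclose(row.raw_mean, 92.5)
        assert abs(row.percentile - 30.9) < 0.1

    def test_high_z_hits_top_percentiles(self, small_raw_data):
        z = standardize(small_raw_data)
        params = ParameterSet([1.0], np.full((1, 2), 2.05), np.ones(2))
        table = back_transform(params, z)
        assert np.all(np.abs(table.percentile - 98.0) < 0.1)

    def test_missing_raw_moments_rejected(self, random_data):
        params = ParameterSet([1.0], np.zeros((1, 3)), np.ones(3))
        with pytest.raises(ValueError):
            back_transform(params, random_data)
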