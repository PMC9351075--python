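import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from profilemix import (
    EMError,
    IndicatorMatrix,
    ModelSpec,
    ParameterSet,
    count_parameters,
    e_step,
    fit_em,
    loglik,
    m_step,
    two_reference_spec,
)


def naive_loglik(y, pi, mu, var):
    """Independent oracle: direct density summation, no log-sum-exp."""
    total = 0.0
    for i in range(y.shape[0]):
        dens = 0.0
        for c in range(len(pi)):
            f = 1.0
            for j in range(y.shape[1]):
                f *= math.exp(-0.5 * (y[i, j] - mu[c, j]) ** 2 / var[j]) / \
                    math.sqrt(2 * math.pi * var[j])
            dens += pi[c] * f
        total += math.log(dens)
    return total


class TestLoglik:
    def test_standard_normal_at_zero(self):
        data = IndicatorMatrix(np.array([[0.0]]), ["s"], ["y"])
        params = ParameterSet([1.0], [[0.0]], [1.0])
        assert np.isclose(loglik(data, params), math.log(1 / math.sqrt(2 * math.pi)))

    def test_mixture_of_identical_classes_collapses(self, random_data):
        mu = np.zeros((1, 3))
        one = ParameterSet([1.0], mu, np.ones(3))
        two = ParameterSet([0.5, 0.5], np.zeros((2, 3)), np.ones(3))
        assert np.isclose(loglik(random_data, one), loglik(random_data, two),
                          atol=1e-10)

    def test_matches_naive_summation(self, rng):
        y = rng.standard_normal((5, 3))
        data = IndicatorMatrix(y, list("abcde"), ["x", "y", "z"])
        params = ParameterSet(
            [0.4, 0.6], rng.standard_normal((2, 3)), [0.5, 1.0, 2.0])
        expected = naive_loglik(y, params.proportions, params.means,
                                params.variances)
        assert np.isclose(loglik(data, params), expected, atol=1e-8)

    def test_permutation_invariance(self, random_data, random_params):
        swapped = random_params.permuted([1, 0])
        assert np.isclose(loglik(random_data, random_params),
                          loglik(random_data, swapped), atol=1e-10)


class TestEStep:
    def test_identical_classes_give_uniform_posteriors(self, random_data):
        params = ParameterSet([0.5, 0.5], np.zeros((2, 3)), np.ones(3))
        tau = e_step(random_data, params)
        assert np.allclose(tau, 0.5)

    def test_zero_proportion_rejected(self, random_data):
        params = ParameterSet([1.0, 0.0], np.zeros((2, 3)), np.ones(3))
        with pytest.raises(EMError):
            e_step(random_data, params)

    def test_matches_direct_bayes_calculation(self):
        y = np.array([[-1.0], [0.0], [1.0], [2.0]])
        data = IndicatorMatrix(y, list("abcd"), ["y"])
        pi = np.array([0.3, 0.7])
        mu = np.array([[0.0], [1.0]])
        var = np.array([1.0])
        params = ParameterSet(pi, mu, var)
        tau = e_step(data, params)
        # spreadsheet-style direct calculation per row
        for i in range(4):
            f = pi * np.exp(-0.5 * (y[i, 0] - mu[:, 0]) ** 2) / np.sqrt(2 * np.pi)
            assert np.allclose(tau[i], f / f.sum(), atol=1e-10)

    def test_rows_sum_to_one(self, random_data, random_params):
        tau = e_step(random_data, random_params)
        assert np.allclose(tau.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_hard_posteriors_reduce_to_subgroup_means(self, random_data):
        tau = np.zeros((20, 2))
        tau[:10, 0] = 1.0
        tau[10:, 1] = 1.0
        spec = ModelSpec(n_classes=2)
        params = m_step(random_data, tau, spec)
        assert np.allclose(params.means[0], random_data.values[:10].mean(axis=0))
        assert np.allclose(params.means[1], random_data.values[10:].mean(axis=0))
        assert np.allclose(params.proportions, [0.5, 0.5])

    def test_fixed_class_row_is_exact(self, random_data, rng):
        spec = ModelSpec(n_classes=2, fixed_classes=((0, (-0.5,) * 3),))
        tau = rng.dirichlet(np.ones(2), size=20)
        params = m_step(random_data, tau, spec)
        assert np.array_equal(params.means[0], np.full(3, -0.5))

    def test_equality_group_pools_weighted_mean(self, rng):
        y = rng.standard_normal((6, 3))
        data = IndicatorMatrix(y, [f"s{i}" for i in range(6)], list("abc"))
        tau = rng.dirichlet(np.ones(4), size=6)
        spec = ModelSpec(n_classes=4, equality_groups=((2, (1, 3)),))
        params = m_step(data, tau, spec)
        # hand-computed pooled weighted mean over classes {1, 3}, indicator 2
        num = (tau[:, 1] * y[:, 2]).sum() + (tau[:, 3] * y[:, 2]).sum()
        den = tau[:, 1].sum() + tau[:, 3].sum()
        assert np.isclose(params.means[1, 2], num / den, atol=1e-12)
        assert params.means[1, 2] == params.means[3, 2]

    def test_pooled_variance_formula(self, random_data, rng):
        tau = rng.dirichlet(np.ones(2), size=20)
        spec = ModelSpec(n_classes=2)
        params = m_step(random_data, tau, spec)
        y = random_data.values
        expected = np.zeros(3)
        for c in range(2):
            expected += (tau[:, c][:, None] * (y - params.means[c]) ** 2).sum(axis=0)
        assert np.allclose(params.variances, expected / 20, atol=1e-12)


class TestFitEM:
    def test_one_class_closed_form(self, random_data):
        spec = ModelSpec(n_classes=1)
        init = ParameterSet([1.0], np.zeros((1, 3)), np.ones(3))
        fit = fit_em(random_data, spec, init)
        y = random_data.values
        assert np.allclose(fit.params.means[0], y.mean(axis=0), atol=1e-12)
        assert np.allclose(fit.params.variances, y.var(axis=0, ddof=0), atol=1e-12)
        assert fit.converged and fit.n_iter == 1

    def test_recovers_well_separated_two_class_mixture(self, two_class_sim):
        data, z = two_class_sim
        spec = ModelSpec(n_classes=2)
        best = None
        rng = np.random.default_rng(5)
        for _ in range(10):
            rows = rng.choice(200, 2, replace=False)
            init = ParameterSet([0.5, 0.5], data.values[rows], np.ones(1))
            fit = fit_em(data, spec, init)
            if best is None or fit.loglik > best.loglik:
                best = fit
        mus = np.sort(best.params.means[:, 0])
        assert abs(mus[0] - (-2.0)) < 0.15 and abs(mus[1] - 2.0) < 0.15

    def test_restrictions_hold_exactly_in_result(self, default_sim):
        spec = two_reference_spec(5, 7)
        rng = np.random.default_rng(3)
        rows = rng.choice(120, 5, replace=False)
        means = default_sim.primary.values[rows].copy()
        means[0, :] = -0.5
        means[1, :] = 0.5
        init = ParameterSet(np.full(5, 0.2), means,
                            default_sim.primary.values.var(axis=0))
        fit = fit_em(default_sim.primary, spec, init)
        assert np.array_equal(fit.params.means[0], np.full(7, -0.5))
        assert np.array_equal(fit.params.means[1], np.full(7, 0.5))

    def test_final_loglik_consistent_with_params(self, two_class_sim):
        data, _ = two_class_sim
        init = ParameterSet([0.4, 0.6], np.array([[-1.0], [1.0]]), np.ones(1))
        fit = fit_em(data, ModelSpec(n_classes=2), init)
        assert np.isclose(fit.loglik, loglik(data, fit.params), atol=1e-8)
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-10)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_em_loglik_monotone_on_random_instances(seed):
    """EM never decreases the loglikelihood, whatever the start."""
    rng = np.random.default_rng(seed)
    n, C, J = 15, 3, 2
    y = rng.standard_normal((n, J)) * rng.uniform(0.5, 2) + rng.normal(0, 1, J)
    data = IndicatorMatrix(y, [f"s{i}" for i in range(n)],
                           [f"y{j}" for j in range(J)])
    rows = rng.choice(n, C, replace=False)
    init = ParameterSet(rng.dirichlet(np.ones(C)) * 0.98 + 0.02 / C,
                        y[rows], y.var(axis=0) + 0.1)
    # fit_em itself raises EMError on any interior decrease beyond 1e-9
    fit = fit_em(data, ModelSpec(n_classes=C), init, max_iter=300)
    assert np.isfinite(fit.loglik)


def grid_search_oracle(data, resolution=0.1):
    """Coarse exhaustive search for the best 2-class, 1-indicator mixture.

    Scans proportions, both class means, and a small variance grid; its
    maximum is a lower bound on the attainable loglikelihood.
    """
    y = data.values
    lo, hi = y.min() - 0.5, y.max() + 0.5
    mu_grid = np.arange(lo, hi + resolution, resolution)
    pi_grid = np.arange(0.1, 0.95, 0.1)
    var_grid = data.values.var() * np.array([0.25, 0.5, 1.0, 2.0])
    best = -np.inf
    for v in var_grid:
        # vectorized over the mean grid
        d1 = np.exp(-0.5 * (y[:, 0][:, None] - mu_grid[None, :]) ** 2 / v) \
            / np.sqrt(2 * np.pi * v)   # (n, M)
        for p in pi_grid:
            mix = p * d1[:, :, None] + (1 - p) * d1[:, None, :]
            ll = np.log(mix).sum(axis=0).max()
            best = max(best, ll)
    return best


def test_multistart_em_beats_grid_search_oracle(rng):
    data = IndicatorMatrix(rng.standard_normal((8, 1)) + rng.choice([-1.5, 1.5], 8)[:, None],
                           [f"s{i}" for i in range(8)], ["y"])
    oracle = grid_search_oracle(data)
    spec = ModelSpec(n_classes=2)
    best_ll = -np.inf
    for s in range(200):
        srng = np.random.default_rng(s)
        rows = srng.choice(8, 2, replace=False)
        pi = srng.dirichlet([1, 1]) * 0.9 + 0.05
        init = ParameterSet(pi / pi.sum(), data.values[rows],
                            [data.values.var()])
        try:
            fit = fit_em(data, spec, init)
        except EMError:
            continue
        best_ll = max(best_ll, fit.loglik)
    assert best_ll >= oracle - 1e-6


class TestCountParameters:
    @pytest.mark.parametrize("C, expected", [
        (1, 14), (2, 22), (3, 30), (4, 38), (5, 46), (6, 54), (7, 62), (8, 70),
    ])
    def test_unrestricted_seven_indicators(self, C, expected):
        assert count_parameters(ModelSpec(n_classes=C), 7) == expected

    @pytest.mark.parametrize("C, expected", [
        (2, 8), (3, 16), (4, 24), (5, 32), (6, 40), (7, 48),
    ])
    def test_two_fixed_reference_classes(self, C, expected):
        assert count_parameters(two_reference_spec(C, 7), 7) == expected

    def test_equality_group_saves_size_minus_one(self):
        spec = ModelSpec(n_classes=3, equality_groups=((0, (0, 1, 2)), (1, (0, 2))))
        # 3*2 means − (3−1) − (2−1) + 2 variances + 2 proportions
        assert count_parameters(spec, 2) == 6 - 2 - 1 + 2 + 2

    def test_spec_validation_rejects_overlap(self):
        with pytest.raises(ValueError):
            ModelSpec(n_classes=3, fixed_classes=((0, (0.0,)),),
                      equality_groups=((0, (0, 1)),))
        with pytest.raises(ValueError):
            ModelSpec(n_classes=2, fixed_classes=((5, (0.0,)),))
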