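from fractions import Fraction

import numpy as np
import pytest

from hane import (
    BernoulliDesign,
    ClusterRandomizedDesign,
    CompletelyRandomizedDesign,
    HANEModel,
    SaturationDesign,
    bias_baseline_adjusted,
    bias_tte_hat,
    check_unbiasedness,
    conditional_odds_rho,
    exhaustive_moments,
    influence,
    make_estimator,
    variance_cluster,
    variance_crd,
    variance_general,
    variance_saturation,
)

F = Fraction


# ---------------------------------------------------------------- influence
def test_influence_without_edges_is_beta():
    m = HANEModel([0.0] * 3, [1.0, 2.0, 3.0], {})
    iv = influence(m, CompletelyRandomizedDesign(3, 1))
    assert list(iv.L) == [1.0, 2.0, 3.0]


def test_influence_row_sums_and_mean_under_equal_marginals():
    m = HANEModel([F(0)] * 2, [F(1), F(0)], {(0, 1): F(2)})
    iv = influence(m, CompletelyRandomizedDesign(2, 1))
    assert iv.L == [F(3), F(0)]
    assert iv.mean() == m.total_treatment_effect() == F(3, 2)


def test_influence_with_unequal_marginals_hand_ratio():
    # individual 0 treated with probability 1/2, individual 1 with 1/4
    d = SaturationDesign([0, 1, 1, 1, 1, 0], [F(1, 2), F(1, 4)])
    m6 = HANEModel([F(0)] * 6, [F(1), F(0)] + [F(0)] * 4, {(0, 1): F(2)})
    iv = influence(m6, d)
    assert iv.L[0] == F(1) + F(1, 2) * F(2) / F(1, 4) == F(5)


def test_influence_requires_positive_marginals():
    m = HANEModel([0.0] * 2, [1.0, 1.0], {(0, 1): 1.0})
    d = SaturationDesign([0, 1], [0, 1])
    with pytest.raises(ValueError, match="positive"):
        influence(m, d)


# ---------------------------------------------------------------- biases
def test_ht_bias_zero_when_edges_inside_clusters():
    m = HANEModel([F(0)] * 4, [F(1)] * 4, {(0, 1): F(3), (2, 3): F(-2)})
    d = ClusterRandomizedDesign([0, 0, 1, 1], 1)
    assert bias_tte_hat(m, d) == 0


def test_ht_bias_under_independence_is_minus_mean_gamma():
    m = HANEModel([F(0)] * 3, [F(0)] * 3, {(0, 1): F(2), (1, 2): F(1, 2)})
    d = BernoulliDesign(3, F(1, 3))
    assert bias_tte_hat(m, d) == -F(5, 2) / 3


def test_ht_bias_crd_single_edge_hand_value():
    m = HANEModel([F(0)] * 4, [F(0)] * 4, {(0, 1): F(1)})
    d = CompletelyRandomizedDesign(4, 2)
    assert bias_tte_hat(m, d) == F(-1, 3)


def test_baseline_adjusted_bias_zero_under_equal_marginals():
    m = HANEModel([F(0)] * 4, [F(1)] * 4, {(0, 2): F(5), (3, 1): F(-1)})
    assert bias_baseline_adjusted(m, CompletelyRandomizedDesign(4, 2)) == 0


def test_baseline_adjusted_bias_hand_value():
    m = HANEModel([F(0)] * 2, [F(0)] * 2, {(0, 1): F(1)})

    class TwoMarginals(BernoulliDesign):
        def marginal(self, i):
            return [F(1, 2), F(1, 4)][i]

    d = TwoMarginals(2, F(1, 2))
    assert bias_baseline_adjusted(m, d) == F(1, 2)


def test_baseline_adjusted_bias_matches_enumeration_on_varying_saturation():
    labels = [0, 0, 0, 1, 1, 1]
    d = SaturationDesign(labels, [F(1, 3), F(2, 3)])
    m = HANEModel(
        [F(1), F(-1), F(2), F(0), F(1), F(3)],
        [F(1)] * 6,
        {(0, 4): F(2), (5, 1): F(-3, 2), (1, 2): F(1, 2)},
    )
    est = make_estimator("baseline_adjusted", d.marginals(), alpha_hat=m.alpha)
    mean, _ = exhaustive_moments(m, d, est)
    assert mean - m.total_treatment_effect() == bias_baseline_adjusted(m, d)


# ---------------------------------------------------------------- variances
def test_variance_bernoulli_diagonal_form(exact_model_factory):
    rng = np.random.default_rng(2)
    m = exact_model_factory(rng, n=5)
    p = F(1, 3)
    d = BernoulliDesign(5, p)
    iv = influence(m, d)
    expected = sum(l * l for l in iv.L) * (1 - p) / p / 25
    assert variance_general(m, d) == expected


def test_variance_crd_zero_for_constant_influence():
    m = HANEModel([F(0)] * 4, [F(2)] * 4, {})
    assert variance_crd(m, F(1, 2)) == 0


def test_variance_crd_two_point_hand_value():
    m = HANEModel([F(0)] * 2, [F(0), F(2)], {})
    assert variance_crd(m, F(1, 2)) == 1


def test_variance_crd_equals_general(exact_model_factory):
    rng = np.random.default_rng(21)
    m = exact_model_factory(rng, n=8)
    assert variance_crd(m, F(1, 2)) == variance_general(
        m, CompletelyRandomizedDesign(8, 4)
    )


def test_variance_cluster_hand_and_general(exact_model_factory):
    rng = np.random.default_rng(22)
    m = exact_model_factory(rng, n=8)
    labels = [0, 0, 1, 1, 2, 2, 3, 3]
    assert variance_cluster(m, labels, F(1, 2)) == variance_general(
        m, ClusterRandomizedDesign(labels, 2)
    )
    m2 = HANEModel([F(0)] * 4, [F(0), F(0), F(2), F(2)], {})
    assert variance_cluster(m2, [0, 0, 1, 1], F(1, 2)) == 1


def test_variance_cluster_rejects_non_uniform_sizes():
    m = HANEModel([F(0)] * 5, [F(1)] * 5, {})
    with pytest.raises(ValueError, match="uniform"):
        variance_cluster(m, [0, 0, 0, 1, 1], F(1, 2))


def test_variance_saturation_pair_hand_value():
    m = HANEModel([F(0)] * 2, [F(0), F(2)], {})
    assert variance_saturation(m, [0, 0], F(1, 2)) == 1


def test_variance_saturation_zero_for_cluster_constant_influence():
    m = HANEModel([F(0)] * 4, [F(1), F(1), F(5), F(5)], {})
    assert variance_saturation(m, [0, 0, 1, 1], F(1, 2)) == 0


def test_uniform_saturation_is_special_case_of_varying():
    rng = np.random.default_rng(23)
    from conftest import random_exact_model

    m = random_exact_model(rng, n=6)
    labels = [0, 0, 0, 1, 1, 1]
    uniform = variance_saturation(m, labels, F(1, 3))
    varying = variance_saturation(m, labels, [F(1, 3), F(1, 3)])
    assert uniform == varying


def test_cluster_design_with_singleton_clusters_is_crd():
    rng = np.random.default_rng(24)
    from conftest import random_exact_model

    m = random_exact_model(rng, n=6)
    singleton = variance_general(m, ClusterRandomizedDesign(list(range(6)), 3))
    assert singleton == variance_crd(m, F(1, 2))


def test_variance_bound_from_effect_and_outdegree():
    """popvar(L) <= B^2 (1 + d_max)^2 so the variance inherits that bound."""
    rng = np.random.default_rng(25)
    from conftest import random_exact_model

    for _ in range(5):
        m = random_exact_model(rng, n=8)
        bound_b = max(
            [abs(b) for b in m.beta.tolist()] + [abs(g) for g in m.gamma.values()]
        )
        p = F(1, 2)
        cap = (1 - p) / (p * 7) * bound_b**2 * (1 + m.max_outdegree()) ** 2
        assert variance_crd(m, p) <= cap


def test_variance_crd_scaling_with_population_size():
    """Duplicating the influence population halves the variance up to (n-1)."""
    beta = [F(0), F(1), F(3), F(-2)]
    m1 = HANEModel([F(0)] * 4, beta, {})
    m2 = HANEModel([F(0)] * 8, beta + beta, {})
    v1 = variance_crd(m1, F(1, 2))
    v2 = variance_crd(m2, F(1, 2))
    assert v2 / v1 == F(3, 7)  # (n-1)/(2n-1) at n=4


# ---------------------------------------------------------------- conditions
def test_conditions_cluster_design_contains_edges():
    d = ClusterRandomizedDesign([0, 0, 1, 1], 1)
    rep = check_unbiasedness(d, [(0, 1), (2, 3)])
    assert rep.same_treatment and rep.equal_marginals and rep.common_odds_ratio


def test_conditions_crd_cross_pairs():
    d = CompletelyRandomizedDesign(4, 2)
    rep = check_unbiasedness(d, [(0, 1), (2, 3)])
    assert not rep.same_treatment
    assert rep.same_treatment_violations == [(0, 1), (2, 3)]
    assert rep.equal_marginals
    assert rep.common_odds_ratio


def test_conditions_varying_saturation_cross_cluster_edge():
    d = SaturationDesign([0, 0, 0, 1, 1, 1], [F(1, 3), F(2, 3)])
    rep = check_unbiasedness(d, [(0, 3)])
    assert not rep.equal_marginals
    assert rep.equal_marginals_violations == [(0, 3)]


def test_conditions_detect_inconsistent_odds_ratio():
    # target 1 has one in-edge inside its pair (anti-correlated, ratio 1) and
    # one from a cluster at a different saturation level (ratio 2): no single
    # rho_1 exists, so the common-odds-ratio condition fails at that target
    d = SaturationDesign([0, 0, 1, 1, 1], [F(1, 2), F(1, 3)])
    rep = check_unbiasedness(d, [(0, 1), (2, 1)])
    assert rep.common_odds_ratio_violations == [1]


def test_conditional_odds_rho_bernoulli():
    d = BernoulliDesign(3, F(1, 3))
    assert conditional_odds_rho(d, 0, 1) == (1 - F(1, 3)) / F(1, 3)


# ---------------------------------------------------------------- oracle
def test_exhaustive_single_edge_bernoulli_half_hand_value():
    """Four assignments by hand: the HT form misses gamma/n under independence."""
    m = HANEModel([F(0)] * 2, [F(0)] * 2, {(0, 1): F(3)})
    d = BernoulliDesign(2, F(1, 2))
    mean, _ = exhaustive_moments(m, d, make_estimator("ht", d.marginals()))
    assert mean - m.total_treatment_effect() == -F(3, 2)
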