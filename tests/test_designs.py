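import warnings
from fractions import Fraction

import numpy as np
import pytest

from hane import (
    BernoulliDesign,
    ClusterRandomizedDesign,
    CompletelyRandomizedDesign,
    SaturationDesign,
    SupportTooLargeError,
    design_from_config,
    matched_pair_design,
    moment_tables,
)


def _enumerated_moments(design):
    """First/second moments by direct enumeration (the design oracle)."""
    n = design.n
    m1 = [Fraction(0)] * n
    m2 = {}
    total = Fraction(0)
    for z, prob in design.enumerate_support():
        total += prob
        for i in range(n):
            if z[i]:
                m1[i] += prob
        for i in range(n):
            for j in range(n):
                if z[i] and z[j]:
                    m2[(i, j)] = m2.get((i, j), Fraction(0)) + prob
    assert total == 1
    return m1, m2


DESIGNS = [
    BernoulliDesign(4, Fraction(1, 3)),
    CompletelyRandomizedDesign(6, 2),
    ClusterRandomizedDesign([0, 0, 1, 1, 2, 2], 1),
    ClusterRandomizedDesign([0, 0, 0, 1, 1], 1),  # non-uniform clusters
    SaturationDesign([0, 0, 0, 1, 1, 1], [Fraction(1, 3), Fraction(2, 3)]),
    SaturationDesign([0, 0, 1, 1, 2], [Fraction(1, 2), Fraction(1, 2), 1]),
]


@pytest.mark.parametrize("design", DESIGNS, ids=lambda d: d.kind + str(d.n))
def test_closed_form_moments_equal_enumeration_exactly(design):
    m1, m2 = _enumerated_moments(design)
    for i in range(design.n):
        assert design.marginal(i) == m1[i]
        for j in range(design.n):
            assert design.second_moment(i, j) == m2.get((i, j), Fraction(0))
            assert design.covariance(i, j) == m2.get((i, j), Fraction(0)) - m1[i] * m1[j]


@pytest.mark.parametrize("design", DESIGNS, ids=lambda d: d.kind + str(d.n))
def test_quadratic_form_matches_dense_double_sum(design):
    rng = np.random.default_rng(0)
    u = [Fraction(int(x), 3) for x in rng.integers(-5, 6, design.n)]
    dense = sum(
        u[i] * u[j] * design.covariance(i, j)
        for i in range(design.n)
        for j in range(design.n)
    )
    assert design.covariance_quadratic_form(u) == dense


@pytest.mark.parametrize(
    "design, per_draw_check",
    [
        (CompletelyRandomizedDesign(10, 4), lambda z: z.sum() == 4),
        (
            ClusterRandomizedDesign([0, 0, 1, 1, 2, 2], 2),
            lambda z: z.sum() == 4,
        ),
        (
            SaturationDesign([0] * 3 + [1] * 3, [Fraction(1, 3), Fraction(2, 3)]),
            lambda z: z[:3].sum() == 1 and z[3:].sum() == 2,
        ),
    ],
    ids=["crd", "cluster", "saturation"],
)
def test_fixed_counts_hold_on_every_draw(design, per_draw_check):
    rng = np.random.default_rng(123)
    for _ in range(200):
        assert per_draw_check(design.sample(rng))


@pytest.mark.parametrize(
    "design",
    [
        CompletelyRandomizedDesign(6, 2),
        ClusterRandomizedDesign([0, 0, 1, 1, 2, 2], 1),
        SaturationDesign([0, 0, 0, 1, 1, 1], [Fraction(1, 3), Fraction(2, 3)]),
        BernoulliDesign(6, 0.3),
    ],
    ids=lambda d: d.kind,
)
def test_empirical_moments_within_4se(design):
    reps = 50_000
    rng = np.random.default_rng(99)
    count1 = np.zeros(design.n)
    count01 = 0.0
    i, j = 0, design.n - 1
    for _ in range(reps):
        z = design.sample(rng)
        count1 += z
        count01 += z[i] * z[j]
    for k in range(design.n):
        p = float(design.marginal(k))
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(count1[k] / reps - p) <= 4 * se + 1e-12
    pij = float(design.second_moment(i, j))
    se = np.sqrt(pij * (1 - pij) / reps)
    assert abs(count01 / reps - pij) <= 4 * se + 1e-12


def test_sampling_deterministic_given_seed():
    d = CompletelyRandomizedDesign(20, 7)
    assert np.array_equal(d.sample(5), d.sample(5))


@pytest.mark.parametrize(
    "design, i, j, expected",
    [
        (CompletelyRandomizedDesign(4, 2), 0, 1, Fraction(-1, 12)),
        (ClusterRandomizedDesign([0, 0, 1, 1], 1), 0, 1, Fraction(1, 4)),
        (BernoulliDesign(4, 0.5), 0, 1, 0.0),
    ],
    ids=["crd", "cluster_same", "bernoulli"],
)
def test_hand_computed_covariances(design, i, j, expected):
    assert design.covariance(i, j) == expected


def test_moment_tables_accessor():
    d = CompletelyRandomizedDesign(4, 2)
    marg, cov = moment_tables(d)
    assert marg == [Fraction(1, 2)] * 4
    assert cov(0, 1) == Fraction(-1, 12)


def test_crd_requires_integer_treated_count():
    with pytest.raises(ValueError):
        CompletelyRandomizedDesign(4, 5)
    assert CompletelyRandomizedDesign(4, 1).p == Fraction(1, 4)


def test_saturation_rejects_noninteger_counts():
    with pytest.raises(ValueError, match="integer treated count"):
        SaturationDesign([0, 0, 0], [Fraction(1, 2)])


def test_saturation_budget_mismatch_warns_not_errors():
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        SaturationDesign([0, 0, 1, 1], [Fraction(1, 2), Fraction(1, 2)], budget_p=0.75)
    assert any("budget" in str(w.message) for w in caught)


def test_singleton_cluster_saturation_is_degenerate_but_valid():
    d = SaturationDesign([0, 0, 1], [Fraction(1, 2), 1])
    assert d.marginal(2) == 1
    assert d.covariance(2, 2) == 0


def test_matched_pair_design():
    d = matched_pair_design([0, 0, 1, 1])
    assert all(m == Fraction(1, 2) for m in d.marginals())
    with pytest.raises(ValueError, match="pair"):
        matched_pair_design([0, 0, 0, 1])


def test_support_cap_raises():
    with pytest.raises(SupportTooLargeError):
        list(BernoulliDesign(30, 0.5).enumerate_support(cap=1000))


def test_design_from_config_round_trip():
    d = design_from_config({"kind": "completely_randomized", "n": 10, "m": 5})
    assert d.kind == "completely_randomized" and d.m == 5
    d = design_from_config(
        {"kind": "saturation", "clusters": [0, 0, 0, 1, 1, 1],
         "saturations": ["1/3", "2/3"]}
    )
    assert d.saturations == [Fraction(1, 3), Fraction(2, 3)]
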