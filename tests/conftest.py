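from fractions import Fraction

import numpy as np
import pytest

from hane import HANEModel


def random_exact_model(rng, n=8, edge_prob=0.3, max_num=4, max_den=3):
    """Random model with small-denominator rational parameters.

    Rational parameters make 'equals exactly' literal in the enumeration
    oracle checks: no tolerance is involved anywhere downstream.
    """
    alpha = np.empty(n, dtype=object)
    beta = np.empty(n, dtype=object)
    alpha[:] = [
        Fraction(int(rng.integers(-max_num, max_num + 1)), int(rng.integers(1, max_den + 1)))
        for _ in range(n)
    ]
    beta[:] = [
        Fraction(int(rng.integers(-max_num, max_num + 1)), int(rng.integers(1, max_den + 1)))
        for _ in range(n)
    ]
    gamma = {}
    for s in range(n):
        for t in range(n):
            if s != t and rng.random() < edge_prob:
                num = int(rng.integers(-max_num, max_num + 1))
                if num:
                    gamma[(s, t)] = Fraction(num, int(rng.integers(1, max_den + 1)))
    return HANEModel(alpha, beta, gamma)


def random_float_model(rng, n=20, edge_prob=0.2, gamma_scale=0.5):
    alpha = rng.normal(0.0, 1.0, n)
    beta = rng.normal(1.0, 0.5, n)
    gamma = {}
    for s in range(n):
        for t in range(n):
            if s != t and rng.random() < edge_prob:
                gamma[(s, t)] = float(rng.uniform(-gamma_scale, gamma_scale))
    return HANEModel(alpha, beta, gamma)


@pytest.fixture
def exact_model_factory():
    return random_exact_model


@pytest.fixture
def float_model_factory():
    return random_float_model
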