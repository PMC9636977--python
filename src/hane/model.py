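"""Heterogeneous additive network effects (HANE) potential-outcomes model.

The model describes a finite population of ``n`` individuals whose outcomes
respond additively to treatment: individual ``i`` has a baseline outcome
``alpha_i`` (its outcome under the all-control assignment), a direct effect
``beta_i`` (the shift when ``i`` itself is treated), and edge-specific
interference effects ``gamma[(k, i)]`` (the shift in ``i``'s outcome when
``k`` is treated).  The potential outcome under a binary treatment vector
``z`` is

    Y_i(z) = alpha_i + beta_i * z_i + sum_{(k, i) in E} gamma_ki * z_k,

where the edge set ``E`` is exactly the support of ``gamma``.  Every causal
estimand of interest here is a deterministic function of these parameters;
the randomness in an experiment comes only from the design that draws ``z``.

Parameters may be floats or :class:`fractions.Fraction`.  When any parameter
is a ``Fraction`` the model switches to exact rational arithmetic, which is
what the enumeration oracles in :mod:`hane.theory` rely on for literal
(not approximate) equality checks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

Edge = tuple[int, int]

#: Above this population size a dense n-by-n interference matrix is never
#: materialized; the sparse edge map is the only representation used.
DENSE_LIMIT = 2048


class DimensionError(ValueError):
    """A vector's length does not match the population size."""


def check_treatment_vector(z, n: int) -> np.ndarray:
    """Validate and return a binary treatment vector of length ``n``."""
    arr = np.asarray(z)
    if arr.shape != (n,):
        raise DimensionError(
            f"treatment vector has shape {arr.shape}, expected ({n},)"
        )
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"treatment vector entries must be 0/1, got {vals}")
    return arr.astype(np.int64)


def _param_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise DimensionError(f"{name} must be one-dimensional")
    if arr.dtype == object:
        return arr.copy()
    return arr.astype(float)


@dataclass
class HANEModel:
    """All potential outcomes of a population under additive network effects.

    Parameters
    ----------
    alpha : array-like of shape (n,)
        Baseline outcome of each individual, ``Y_i(0)``.
    beta : array-like of shape (n,)
        Direct effect of each individual, ``Y_i(e_i) - Y_i(0)``.
    gamma : mapping ``(k, i) -> value``
        Interference effect of treating ``k`` on ``i``'s outcome.  Self-pairs
        are rejected (the direct effect lives only in ``beta``); entries equal
        to zero are dropped so the support is exactly the edge set.
    B : float, optional
        A stated bound on ``|beta_i|`` and ``|gamma_ki|``, used only by
        variance-bound diagnostics.
    ids : sequence of str, optional
        External identifiers; internally individuals are always the
        contiguous indices ``0..n-1``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: dict[Edge, object]
    B: float | None = None
    ids: Sequence[str] | None = None
    _gamma_t_csr: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.alpha = _param_array(self.alpha, "alpha")
        self.beta = _param_array(self.beta, "beta")
        n = len(self.alpha)
        if len(self.beta) != n:
            raise DimensionError("alpha and beta have different lengths")
        if self.ids is not None and len(self.ids) != n:
            raise DimensionError("ids length does not match population size")
        clean: dict[Edge, object] = {}
        for (k, i), g in dict(self.gamma).items():
            k = int(k)
            i = int(i)
            if k == i:
                raise ValueError(
                    f"gamma contains the self-loop ({k}, {k}); direct effects "
                    "belong in beta, not gamma — a self-loop here would corrupt "
                    "outdegrees and every bias formula"
                )
            if not (0 <= k < n and 0 <= i < n):
                raise IndexError(f"gamma edge ({k}, {i}) out of range for n={n}")
            if g != 0:
                clean[(k, i)] = g
        self.gamma = clean
        self._exact = (
            self.alpha.dtype == object
            or self.beta.dtype == object
            or any(isinstance(g, Fraction) for g in self.gamma.values())
        )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.alpha)

    @property
    def edges(self) -> list[Edge]:
        """Edge set E, as (source, target) pairs: treating source shifts target."""
        return list(self.gamma.keys())

    @property
    def is_exact(self) -> bool:
        """True when parameters are rationals and arithmetic stays exact."""
        return self._exact

    # ------------------------------------------------------------------
    def evaluate_outcomes(self, z) -> np.ndarray:
        """Potential outcomes ``Y(z)``; a pure function of (model, z)."""
        z = check_treatment_vector(z, self.n)
        if self._exact:
            y = [self.alpha[i] + self.beta[i] * int(z[i]) for i in range(self.n)]
            for (k, i), g in self.gamma.items():
                if z[k]:
                    y[i] = y[i] + g
            out = np.empty(self.n, dtype=object)
            out[:] = y
            return out
        zf = z.astype(float)
        y = self.alpha + self.beta * zf
        gt = self._gamma_transpose()
        if gt is not None:
            y = y + gt @ zf
        return y

    def _gamma_transpose(self):
        """Cached sparse matrix G^T with ``G^T[i, k] = gamma_ki`` (float path)."""
        if not self.gamma:
            return None
        if self._gamma_t_csr is None:
            src = np.fromiter((k for k, _ in self.gamma), dtype=np.int64)
            dst = np.fromiter((i for _, i in self.gamma), dtype=np.int64)
            val = np.fromiter((float(g) for g in self.gamma.values()), dtype=float)
            self._gamma_t_csr = sparse.csr_array(
                (val, (dst, src)), shape=(self.n, self.n)
            )
        return self._gamma_t_csr

    def total_treatment_effect(self):
        """TTE = (1/n)(sum_i beta_i + sum_{(k,i) in E} gamma_ki).

        Equals the average of ``Y_i(1) - Y_i(0)`` over the population.
        """
        total = sum(self.beta.tolist()) + sum(self.gamma.values())
        return total / self.n

    def direct_effect_part(self):
        """Mean direct effect, the SUTVA component of the TTE."""
        return sum(self.beta.tolist()) / self.n

    def interference_part(self):
        """Mean interference contribution, ``(1/n) * sum(gamma)``."""
        return sum(self.gamma.values()) / self.n if self.gamma else 0

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for k, _ in self.gamma:
            deg[k] += 1
        return deg

    def max_outdegree(self) -> int:
        """Maximum number of individuals any one treatment can affect."""
        if not self.gamma:
            return 0
        return int(Counter(k for k, _ in self.gamma).most_common(1)[0][1])

    # ------------------------------------------------------------------
    def as_exact(self) -> "HANEModel":
        """Copy of the model with every parameter coerced to ``Fraction``."""
        a = np.empty(self.n, dtype=object)
        b = np.empty(self.n, dtype=object)
        a[:] = [Fraction(x) for x in self.alpha.tolist()]
        b[:] = [Fraction(x) for x in self.beta.tolist()]
        g = {e: Fraction(v) for e, v in self.gamma.items()}
        return HANEModel(a, b, g, B=self.B, ids=self.ids)

    def as_float(self) -> "HANEModel":
        """Copy with every parameter cast to double precision."""
        return HANEModel(
            np.asarray([float(x) for x in self.alpha.tolist()]),
            np.asarray([float(x) for x in self.beta.tolist()]),
            {e: float(v) for e, v in self.gamma.items()},
            B=self.B,
            ids=self.ids,
        )


# Module-level aliases matching the operation vocabulary used elsewhere.
def evaluate_outcomes(model: HANEModel, z) -> np.ndarray:
    return model.evaluate_outcomes(z)


def total_treatment_effect(model: HANEModel):
    return model.total_treatment_effect()


def max_outdegree(model: HANEModel) -> int:
    return model.max_outdegree()
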