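"""Linear contagion (peer-effects) models and their additive-network reduction.

Under linear contagion an individual's outcome responds to the *outcomes* of
its peers rather than directly to their treatments:

    Y_i(z) = a_i + b_i z_i + sum_k c_ki Y_k(z).

When the peer-weight matrix is a contraction (spectral radius < 1) this
system has a unique fixed point for every treatment vector, and the map
``z -> Y(z)`` is affine.  Its linear part, read off column by column, is an
additive network effects model whose interference support is generally dense:
multihop paths ``l -> k -> j -> i`` all contribute to the effect of treating
``l`` on ``i``.  :func:`contagion_to_hane` performs this reduction by direct
linear solves (never by truncating the Neumann series), and
:func:`simulate_contagion_fixed_point` provides the iterative oracle the
conversion is verified against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import DimensionError, HANEModel, check_treatment_vector

Edge = tuple[int, int]


class NonContractiveError(ValueError):
    """The peer-weight matrix has spectral radius >= 1; no fixed point."""


class ConvergenceError(RuntimeError):
    """Fixed-point iteration did not reach tolerance within max_iter."""


@dataclass
class ContagionModel:
    """Linear contagion model ``Y_i = a_i + b_i z_i + sum_k c_ki Y_k``.

    Parameters
    ----------
    a : array-like of shape (n,)
        Intrinsic outcome levels.
    b : array-like of shape (n,)
        Intrinsic treatment responses.
    c : mapping ``(k, i) -> weight``
        Peer weight: the effect of ``k``'s outcome on ``i``'s outcome.
        Self-weights are rejected, and the spectral radius of the weight
        matrix must be strictly below 1 for the equilibrium to exist.
    """

    a: np.ndarray
    b: np.ndarray
    c: dict[Edge, float]

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.ndim != 1 or self.a.shape != self.b.shape:
            raise DimensionError("a and b must be 1-d vectors of equal length")
        n = len(self.a)
        clean: dict[Edge, float] = {}
        for (k, i), w in dict(self.c).items():
            k, i = int(k), int(i)
            if k == i:
                raise ValueError(f"self-weight c[({k}, {k})] is not allowed")
            if not (0 <= k < n and 0 <= i < n):
                raise IndexError(f"peer edge ({k}, {i}) out of range for n={n}")
            if w != 0:
                clean[(k, i)] = float(w)
        self.c = clean
        rho = self.spectral_radius()
        if rho >= 1:
            raise NonContractiveError(
                f"peer-weight matrix has spectral radius {rho:.6g} >= 1; "
                "the contagion equilibrium does not exist"
            )

    @property
    def n(self) -> int:
        return len(self.a)

    def peer_matrix_t(self) -> np.ndarray:
        """Dense C^T so that ``(C^T Y)_i = sum_k c_ki Y_k``."""
        ct = np.zeros((self.n, self.n))
        for (k, i), w in self.c.items():
            ct[i, k] = w
        return ct

    def spectral_radius(self) -> float:
        if not self.c:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(self.peer_matrix_t()))))


def simulate_contagion_fixed_point(
    cm: ContagionModel, z, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Equilibrium outcomes by fixed-point iteration from ``Y = a``.

    Iterates ``Y <- a + diag(b) z + C^T Y`` until the sup-norm change drops
    below ``tol``.  Convergence is guaranteed because the model validates
    spectral radius < 1 at construction.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    z = check_treatment_vector(z, cm.n)
    base = cm.a + cm.b * z.astype(float)
    ct = cm.peer_matrix_t()
    y = cm.a.copy()
    for _ in range(max_iter):
        y_new = base + ct @ y
        if np.max(np.abs(y_new - y)) < tol:
            return y_new
        y = y_new
    resid = float(np.max(np.abs(base + ct @ y - y)))
    raise ConvergenceError(
        f"fixed point not reached in {max_iter} iterations (residual {resid:.3g})"
    )


def contagion_to_hane(cm: ContagionModel, drop_tol: float = 1e-12) -> HANEModel:
    """Exact additive-network representation of a contagion model.

    Solves ``(I - C^T) alpha = a`` for the no-treatment equilibrium and
    ``(I - C^T) M = diag(b)`` for the linear response ``M`` of equilibrium
    outcomes to treatments.  The diagonal of ``M`` becomes the direct effects
    and off-diagonal entries become interference effects ``gamma[(l, i)] =
    M[i, l]`` (treating ``l`` shifts ``i``).  Entries below ``drop_tol`` in
    magnitude are dropped to keep the support meaningful.
    """
    n = cm.n
    a_mat = np.eye(n) - cm.peer_matrix_t()
    alpha = np.linalg.solve(a_mat, cm.a)
    m = np.linalg.solve(a_mat, np.diag(cm.b))
    beta = np.diag(m).copy()
    gamma: dict[Edge, float] = {}
    for i in range(n):
        for l in range(n):
            if i != l and abs(m[i, l]) > drop_tol:
                gamma[(l, i)] = float(m[i, l])
    return HANEModel(alpha, beta, gamma)
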