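"""Randomized treatment designs with exact first and second moments.

Every bias and variance formula in :mod:`hane.theory` is a function of the
design only through ``E[z_i]`` and ``E[z_i z_j]``.  Each design here exposes

* ``sample(seed)`` — one draw of the treatment vector,
* ``marginal(i)`` / ``second_moment(i, j)`` / ``covariance(i, j)`` — exact
  closed-form moments (``Fraction``-valued for the count-based designs, so
  downstream identities can be checked literally),
* ``enumerate_support()`` — the full support with exact probabilities, the
  enumeration oracle used to certify every closed form on small instances,
* ``covariance_quadratic_form(u)`` — ``sum_{i,j} u_i u_j Cov(z_i, z_j)``
  evaluated through the design's block covariance structure in O(n), never
  via a dense n-by-n covariance matrix.

Designs implemented: Bernoulli (independent coin flips), completely
randomized (exactly ``m`` treated), cluster-randomized (whole clusters
jointly treated), and saturation-randomized (a fixed treated fraction drawn
within each cluster; the matched-pair design is the special case of clusters
of size two at saturation 1/2).
"""

from __future__ import annotations

import abc
import itertools
import math
import warnings
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

import numpy as np


class SupportTooLargeError(ValueError):
    """Design support exceeds the enumeration cap; use Monte Carlo instead."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_index(i: int, n: int):
    if not (0 <= i < n):
        raise IndexError(f"individual index {i} out of range for n={n}")


class Design(abc.ABC):
    """A distribution over binary treatment vectors of length ``n``."""

    kind: str
    n: int

    # -- sampling -----------------------------------------------------
    @abc.abstractmethod
    def sample(self, seed) -> np.ndarray:
        """One draw; deterministic given an integer seed or Generator."""

    # -- exact moments -------------------------------------------------
    @abc.abstractmethod
    def marginal(self, i: int):
        """Exact ``E[z_i]``."""

    def marginals(self) -> list:
        return [self.marginal(i) for i in range(self.n)]

    @abc.abstractmethod
    def second_moment(self, i: int, j: int):
        """Exact ``E[z_i z_j]`` (equals the marginal when ``i == j``)."""

    def covariance(self, i: int, j: int):
        """Exact ``Cov(z_i, z_j)``; uses ``z_i^2 = z_i`` on the diagonal."""
        return self.second_moment(i, j) - self.marginal(i) * self.marginal(j)

    # -- enumeration ---------------------------------------------------
    @abc.abstractmethod
    def support_size(self) -> int:
        """Number of assignments with positive probability."""

    @abc.abstractmethod
    def _iter_support(self) -> Iterator[tuple[np.ndarray, Fraction]]:
        ...

    def enumerate_support(self, cap: int = 1_000_000):
        """Yield ``(z, probability)`` over the whole support.

        Probabilities are exact ``Fraction`` values for count-based designs
        (and for a Bernoulli design constructed with a ``Fraction`` p).
        """
        size = self.support_size()
        if size > cap:
            raise SupportTooLargeError(
                f"support size {size} exceeds cap {cap}; "
                "use the Monte Carlo harness in hane.simulate instead"
            )
        return self._iter_support()

    # -- block quadratic form -------------------------------------------
    @abc.abstractmethod
    def covariance_quadratic_form(self, u: Sequence):
        """``sum_{i,j} u_i u_j Cov(z_i, z_j)`` via block structure, O(n)."""


def moment_tables(design: Design):
    """Marginal vector plus a pairwise-covariance accessor for a design."""
    return design.marginals(), design.covariance


# ----------------------------------------------------------------------
class BernoulliDesign(Design):
    """Independent treatment with probability ``p`` per individual."""

    kind = "bernoulli"

    def __init__(self, n: int, p):
        if not 0 <= p <= 1:
            raise ValueError("p must lie in [0, 1]")
        self.n = int(n)
        self.p = p

    def sample(self, seed) -> np.ndarray:
        rng = _as_rng(seed)
        return (rng.random(self.n) < float(self.p)).astype(np.int64)

    def marginal(self, i: int):
        _check_index(i, self.n)
        return self.p

    def second_moment(self, i: int, j: int):
        _check_index(i, self.n)
        _check_index(j, self.n)
        if i == j:
            return self.p
        return self.p * self.p

    def support_size(self) -> int:
        return 2**self.n

    def _iter_support(self):
        p = self.p
        q = 1 - p
        for bits in itertools.product((0, 1), repeat=self.n):
            z = np.array(bits, dtype=np.int64)
            t = int(z.sum())
            yield z, p**t * q ** (self.n - t)

    def covariance_quadratic_form(self, u):
        pq = self.p * (1 - self.p)
        return sum(ui * ui for ui in u) * pq


# ----------------------------------------------------------------------
class CompletelyRandomizedDesign(Design):
    """Exactly ``m`` of ``n`` individuals treated, uniformly at random.

    The constructor takes the integer treated count ``m`` rather than a
    fraction: silent rounding of ``p*n`` would change every moment.  The
    implied budget is reported as ``p = m/n`` (a ``Fraction``).
    """

    kind = "completely_randomized"

    def __init__(self, n: int, m: int):
        n, m = int(n), int(m)
        if not 0 <= m <= n:
            raise ValueError(f"treated count m={m} must lie in [0, {n}]")
        self.n = n
        self.m = m

    @property
    def p(self) -> Fraction:
        return Fraction(self.m, self.n)

    def sample(self, seed) -> np.ndarray:
        rng = _as_rng(seed)
        z = np.zeros(self.n, dtype=np.int64)
        z[rng.choice(self.n, size=self.m, replace=False)] = 1
        return z

    def marginal(self, i: int) -> Fraction:
        _check_index(i, self.n)
        return self.p

    def second_moment(self, i: int, j: int) -> Fraction:
        _check_index(i, self.n)
        _check_index(j, self.n)
        if i == j:
            return self.p
        return Fraction(self.m * (self.m - 1), self.n * (self.n - 1))

    def support_size(self) -> int:
        return math.comb(self.n, self.m)

    def _iter_support(self):
        prob = Fraction(1, self.support_size())
        for treated in itertools.combinations(range(self.n), self.m):
            z = np.zeros(self.n, dtype=np.int64)
            z[list(treated)] = 1
            yield z, prob

    def covariance_quadratic_form(self, u):
        # Cov is p(1-p) on the diagonal and -p(1-p)/(n-1) off it.
        p = self.p
        pq = p * (1 - p)
        if pq == 0:
            return 0 * pq
        q2 = sum(ui * ui for ui in u)
        s = sum(u)
        if self.n == 1:
            return pq * q2
        return pq * (q2 - (s * s - q2) / (self.n - 1))


# ----------------------------------------------------------------------
def _normalize_clusters(cluster_map: Sequence) -> tuple[np.ndarray, list[np.ndarray], list]:
    """Map arbitrary cluster labels to 0..T-1 and collect member indices."""
    labels = list(cluster_map)
    if len(labels) == 0:
        raise ValueError("cluster map is empty")
    ids = sorted(set(labels), key=lambda x: (str(type(x)), x))
    index = {c: t for t, c in enumerate(ids)}
    assign = np.array([index[c] for c in labels], dtype=np.int64)
    members = [np.flatnonzero(assign == t) for t in range(len(ids))]
    return assign, members, ids


class ClusterRandomizedDesign(Design):
    """``k`` of ``T`` clusters jointly treated, uniformly at random.

    All members of a treated cluster receive treatment together, so
    within-cluster treatments are perfectly correlated.
    """

    kind = "cluster_randomized"

    def __init__(self, cluster_map: Sequence, treated_clusters: int):
        self.assign, self.members, self.cluster_ids = _normalize_clusters(cluster_map)
        self.n = len(self.assign)
        self.T = len(self.members)
        k = int(treated_clusters)
        if not 0 <= k <= self.T:
            raise ValueError(f"treated_clusters={k} must lie in [0, {self.T}]")
        self.k = k

    @property
    def p(self) -> Fraction:
        return Fraction(self.k, self.T)

    def cluster_sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=np.int64)

    def sample(self, seed) -> np.ndarray:
        rng = _as_rng(seed)
        treated = rng.choice(self.T, size=self.k, replace=False)
        z = np.zeros(self.n, dtype=np.int64)
        for t in treated:
            z[self.members[t]] = 1
        return z

    def marginal(self, i: int) -> Fraction:
        _check_index(i, self.n)
        return self.p

    def second_moment(self, i: int, j: int) -> Fraction:
        _check_index(i, self.n)
        _check_index(j, self.n)
        if i == j or self.assign[i] == self.assign[j]:
            return self.p
        if self.T == 1:
            return self.p
        return Fraction(self.k * (self.k - 1), self.T * (self.T - 1))

    def support_size(self) -> int:
        return math.comb(self.T, self.k)

    def _iter_support(self):
        prob = Fraction(1, self.support_size())
        for treated in itertools.combinations(range(self.T), self.k):
            z = np.zeros(self.n, dtype=np.int64)
            for t in treated:
                z[self.members[t]] = 1
            yield z, prob

    def covariance_quadratic_form(self, u):
        # Within a cluster z_i are identical, so the form collapses onto the
        # per-cluster sums S_t exactly as the CRD form collapses onto units.
        p = self.p
        pq = p * (1 - p)
        if pq == 0:
            return 0 * pq
        sums = [sum(u[i] for i in mem) for mem in self.members]
        q2 = sum(s * s for s in sums)
        s = sum(sums)
        if self.T == 1:
            return pq * q2
        return pq * (q2 - (s * s - q2) / (self.T - 1))


# ----------------------------------------------------------------------
class SaturationDesign(Design):
    """Each cluster treats a fixed fraction of its members independently.

    ``saturations`` gives the treated fraction ``p_t`` per cluster (aligned
    with the sorted unique cluster labels, or a dict keyed by label, or a
    single value applied to all clusters — the *uniform* saturation design).
    Each ``p_t * n_t`` must be an integer count; the exact ``Fraction``
    ``m_t / n_t`` is stored so all moments are exact.  Treatments are drawn
    as an independent completely randomized design inside every cluster.

    When a budget fraction ``p`` is supplied, the constraint
    ``sum_t n_t p_t = n p`` is checked and a mismatch raises a warning, not
    an error: every moment formula is well defined without it.
    """

    kind = "saturation"

    def __init__(self, cluster_map: Sequence, saturations, budget_p=None):
        self.assign, self.members, self.cluster_ids = _normalize_clusters(cluster_map)
        self.n = len(self.assign)
        self.T = len(self.members)
        if isinstance(saturations, dict):
            sats = [saturations[c] for c in self.cluster_ids]
        elif np.isscalar(saturations) or isinstance(saturations, Fraction):
            sats = [saturations] * self.T
        else:
            sats = list(saturations)
            if len(sats) != self.T:
                raise ValueError(
                    f"{len(sats)} saturation levels given for {self.T} clusters"
                )
        self.m_per_cluster: list[int] = []
        self.saturations: list[Fraction] = []
        for t, s in enumerate(sats):
            n_t = len(self.members[t])
            m_t = float(s) * n_t
            if abs(m_t - round(m_t)) > 1e-9:
                raise ValueError(
                    f"saturation {s} on cluster {self.cluster_ids[t]} of size "
                    f"{n_t} does not give an integer treated count"
                )
            m_t = int(round(m_t))
            if not 0 <= m_t <= n_t:
                raise ValueError("saturation levels must lie in [0, 1]")
            self.m_per_cluster.append(m_t)
            self.saturations.append(Fraction(m_t, n_t))
        if budget_p is not None:
            total = sum(self.m_per_cluster)
            expected = float(budget_p) * self.n
            if abs(total - expected) > 1e-9:
                warnings.warn(
                    f"saturation levels treat {total} individuals but the "
                    f"budget p={budget_p} implies {expected:g}",
                    stacklevel=2,
                )

    @property
    def p(self) -> Fraction:
        """Overall treated fraction implied by the per-cluster counts."""
        return Fraction(sum(self.m_per_cluster), self.n)

    def cluster_sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=np.int64)

    def sample(self, seed) -> np.ndarray:
        rng = _as_rng(seed)
        z = np.zeros(self.n, dtype=np.int64)
        for mem, m_t in zip(self.members, self.m_per_cluster):
            if m_t:
                z[rng.choice(mem, size=m_t, replace=False)] = 1
        return z

    def marginal(self, i: int) -> Fraction:
        _check_index(i, self.n)
        return self.saturations[self.assign[i]]

    def second_moment(self, i: int, j: int) -> Fraction:
        _check_index(i, self.n)
        _check_index(j, self.n)
        if i == j:
            return self.marginal(i)
        ti, tj = self.assign[i], self.assign[j]
        if ti != tj:
            return self.saturations[ti] * self.saturations[tj]
        n_t = len(self.members[ti])
        m_t = self.m_per_cluster[ti]
        # within-cluster CRD: m(m-1)/(n(n-1)); n_t == 1 has no distinct pairs
        return Fraction(m_t * (m_t - 1), n_t * (n_t - 1))

    def support_size(self) -> int:
        size = 1
        for mem, m_t in zip(self.members, self.m_per_cluster):
            size *= math.comb(len(mem), m_t)
        return size

    def _iter_support(self):
        prob = Fraction(1, self.support_size())
        per_cluster = [
            list(itertools.combinations(mem.tolist(), m_t))
            for mem, m_t in zip(self.members, self.m_per_cluster)
        ]
        for combo in itertools.product(*per_cluster):
            z = np.zeros(self.n, dtype=np.int64)
            for treated in combo:
                z[list(treated)] = 1
            yield z, prob

    def covariance_quadratic_form(self, u):
        # Clusters are independent; each contributes a CRD-shaped block.
        total = 0
        for t, mem in enumerate(self.members):
            p_t = self.saturations[t]
            pq = p_t * (1 - p_t)
            if pq == 0:
                continue
            vals = [u[i] for i in mem]
            q2 = sum(v * v for v in vals)
            n_t = len(mem)
            if n_t == 1:
                total = total + pq * q2
            else:
                s = sum(vals)
                total = total + pq * (q2 - (s * s - q2) / (n_t - 1))
        return total


def matched_pair_design(cluster_map: Sequence) -> SaturationDesign:
    """Matched-pair randomization: clusters of size two, saturation 1/2."""
    _, members, _ = _normalize_clusters(cluster_map)
    if any(len(m) != 2 for m in members):
        raise ValueError("matched-pair design requires every cluster to be a pair")
    return SaturationDesign(cluster_map, Fraction(1, 2))


# ----------------------------------------------------------------------
def design_from_config(cfg: dict) -> Design:
    """Build a design from a plain config mapping.

    Expected keys by kind::

        {"kind": "bernoulli", "n": 100, "p": 0.3}
        {"kind": "completely_randomized", "n": 100, "m": 50}
        {"kind": "cluster_randomized", "clusters": [...], "treated_clusters": 5}
        {"kind": "saturation", "clusters": [...], "saturations": [...],
         "budget_p": 0.5}          # budget_p optional

    Saturation levels may be strings like ``"1/3"``; they are parsed as
    exact fractions.
    """
    cfg = dict(cfg)
    kind = cfg.pop("kind")
    if kind == "bernoulli":
        return BernoulliDesign(cfg["n"], cfg["p"])
    if kind == "completely_randomized":
        return CompletelyRandomizedDesign(cfg["n"], cfg["m"])
    if kind == "cluster_randomized":
        return ClusterRandomizedDesign(cfg["clusters"], cfg["treated_clusters"])
    if kind == "saturation":
        sats = cfg["saturations"]
        if isinstance(sats, (list, tuple)):
            sats = [Fraction(s) if isinstance(s, str) else s for s in sats]
        elif isinstance(sats, str):
            sats = Fraction(sats)
        return SaturationDesign(cfg["clusters"], sats, budget_p=cfg.get("budget_p"))
    raise ValueError(f"unknown design kind {kind!r}")
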