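"""Design-based bias and variance theory for TTE estimation, with oracles.

Everything here is a closed form in the model parameters and the design's
exact treatment moments, plus the exhaustive-enumeration oracle
(:func:`exhaustive_moments`) that certifies each closed form on small
instances by brute force.

The central object is the *influence* of individual ``i``,

    L_i = beta_i + sum_{(i, k) in E} E[z_i] * gamma_ik / E[z_k],

the total contribution i makes to the baseline-adjusted estimator when
treated (its own direct effect plus all its outgoing interference effects,
reweighted by marginals).  The baseline-adjusted estimator is exactly the
inverse-propensity-weighted sample mean ``(1/n) sum_i L_i z_i / E[z_i]``,
so TTE estimation reduces to estimating the population mean of L — and its
variance under any design follows from the covariance of the treatment
vector alone.

Direction conventions: the model stores an edge ``(k, i)`` as "treating the
*source* k shifts the *target* i".  Influence sums over the *outgoing*
edges of an individual, so ``L_s`` accumulates every stored edge with
source ``s``.  Outdegree (``d_max``) likewise counts outgoing edges — the
number of individuals one treatment can reach — never in-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np

from .designs import Design, SaturationDesign, SupportTooLargeError
from .model import HANEModel

Edge = tuple[int, int]


def _mean(values: Sequence):
    return sum(values) / len(values)


def _population_variance(values: Sequence):
    """``mean(x^2) - mean(x)^2``; exact for Fraction inputs."""
    m = _mean(values)
    return sum(v * v for v in values) / len(values) - m * m


# ----------------------------------------------------------------------
@dataclass
class InfluenceVector:
    """Per-individual influence terms under a given design's marginals."""

    L: list
    marginals: list

    @property
    def n(self) -> int:
        return len(self.L)

    def mean(self):
        """Equals the TTE whenever marginals are equal across all edges."""
        return _mean(self.L)

    def population_variance(self):
        return _population_variance(self.L)

    def as_array(self) -> np.ndarray:
        return np.asarray([float(x) for x in self.L])


def influence(model: HANEModel, design: Design) -> InfluenceVector:
    """Influence ``L_i = beta_i + sum_k E[z_i] gamma_ik / E[z_k]``.

    The interference sum runs over i's outgoing edges.  With equal marginals
    it reduces to the row sum ``beta_i + sum_k gamma_ik`` and ``mean(L)``
    equals the total treatment effect.
    """
    marg = design.marginals()
    for i, m in enumerate(marg):
        if m <= 0:
            raise ValueError(
                f"individual {i} has marginal E[z_i]={m}; influence requires "
                "strictly positive treatment probabilities"
            )
    L = list(model.beta.tolist())
    for (s, t), g in model.gamma.items():
        L[s] = L[s] + marg[s] * g / marg[t]
    return InfluenceVector(L, marg)


def _row_sum_influence(model: HANEModel) -> list:
    """Influence under any equal-marginal design: plain row sums."""
    L = list(model.beta.tolist())
    for (s, _), g in model.gamma.items():
        L[s] = L[s] + g
    return L


# ----------------------------------------------------------------------
def bias_tte_hat(model: HANEModel, design: Design):
    """Bias of the Horvitz–Thompson-form estimator without baselines.

        E[TTE_hat] - TTE = (1/n) sum_{(k,i) in E} (Cov[z_i,z_k]/Var[z_i] - 1) gamma_ki

    Zero exactly when the design treats both endpoints of every edge
    identically (``P(z_k = z_i) = 1``); equal to ``-(1/n) sum(gamma)`` when
    treatments are independent across every edge, in which case the
    estimator recovers only the direct effects.
    """
    total = 0
    for (s, t), g in model.gamma.items():
        var_t = design.covariance(t, t)
        if var_t == 0:
            raise ValueError(
                f"individual {t} has a degenerate marginal under this design; "
                "the bias formula divides by Var[z_i]"
            )
        total = total + (design.covariance(t, s) / var_t - 1) * g
    return total / model.n


def bias_baseline_adjusted(model: HANEModel, design: Design):
    """Bias of the baseline-adjusted estimator.

        E[TTE_hat_-alpha] - TTE = (1/n) sum_{(i,k) in E} (E[z_i]/E[z_k] - 1) gamma_ik

    where the ratio is source marginal over target marginal; the bias
    vanishes whenever marginals are equal across every edge.
    """
    total = 0
    for (s, t), g in model.gamma.items():
        m_s = design.marginal(s)
        m_t = design.marginal(t)
        if m_t == 0:
            raise ValueError(f"individual {t} has zero marginal; bias undefined")
        total = total + (m_s / m_t - 1) * g
    return total / model.n


# ----------------------------------------------------------------------
def variance_general(model: HANEModel, design: Design):
    """Design-based variance of the baseline-adjusted estimator.

        Var = sum_{i,j} L_i L_j Cov(z_i, z_j) / (n^2 E[z_i] E[z_j])

    evaluated through the design's block covariance structure (O(n) for
    Bernoulli, completely randomized, cluster, and saturation designs).
    """
    ivec = influence(model, design)
    n = model.n
    u = [ivec.L[i] / (n * ivec.marginals[i]) for i in range(n)]
    return design.covariance_quadratic_form(u)


def variance_crd(model: HANEModel, p):
    """Variance under a completely randomized design with budget ``p``.

        Var = (1-p)/(p(n-1)) * popvar(L)

    where ``popvar(L)`` is the population variance of the influence terms
    (which do not depend on the marginals here, since they are all equal).
    ``p * n`` must be an integer treated count.
    """
    n = model.n
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    if n < 2:
        raise ValueError("variance under CRD requires n >= 2")
    m = p * n
    if abs(float(m) - round(float(m))) > 1e-9:
        raise ValueError(f"p={p} does not give an integer treated count for n={n}")
    L = _row_sum_influence(model)
    return (1 - p) / (p * (n - 1)) * _population_variance(L)


def variance_cluster(model: HANEModel, cluster_map: Sequence, p):
    """Variance under cluster randomization with uniform cluster sizes.

        Var = (1-p)/(p(T-1)) * popvar(L'_tau),   L'_tau = (T/n) sum_{i in tau} L_i

    This display assumes clusters of equal size n/T; non-uniform clusters
    raise an error (``variance_general`` with a
    :class:`~hane.designs.ClusterRandomizedDesign` covers that case).
    ``p * T`` must be an integer number of treated clusters.
    """
    from .designs import _normalize_clusters

    assign, members, _ = _normalize_clusters(cluster_map)
    n = model.n
    if len(assign) != n:
        raise ValueError("cluster map length does not match population size")
    T = len(members)
    sizes = {len(mem) for mem in members}
    if len(sizes) != 1:
        raise ValueError(
            "the cluster variance formula assumes uniform cluster sizes n/T; "
            "got sizes {} — use variance_general for non-uniform clusters".format(
                sorted(len(m) for m in members)
            )
        )
    if T < 2:
        raise ValueError("cluster variance requires at least two clusters")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    k = p * T
    if abs(float(k) - round(float(k))) > 1e-9:
        raise ValueError(f"p={p} does not give an integer treated-cluster count")
    L = _row_sum_influence(model)
    # Fraction(T, n) keeps rational inputs exact and degrades to float
    # automatically when the influence terms are floats.
    cluster_means = [Fraction(T, n) * sum(L[i] for i in mem) for mem in members]
    return (1 - p) / (p * (T - 1)) * _population_variance(cluster_means)


def variance_saturation(model: HANEModel, cluster_map: Sequence, saturations):
    """Variance under a saturation design (uniform or varying levels).

        Var = sum_tau (1 - p_tau) n_tau^2 / (p_tau n^2 (n_tau - 1)) * V_tau

    with ``V_tau`` the within-cluster population variance of the influence
    terms (computed under the design's own marginals — with varying levels
    the influence itself is marginal-dependent).  At a common level
    ``p_tau = p`` this reduces to ``(1-p)/(pn) sum_tau n_tau^2/(n(n_tau-1)) V_tau``.
    Size-one clusters carry ``V_tau = 0`` and contribute nothing (there is
    no within-cluster randomness to divide by ``n_tau - 1`` for).
    """
    design = SaturationDesign(cluster_map, saturations)
    if model.n != design.n:
        raise ValueError("cluster map length does not match population size")
    ivec = influence(model, design)
    n = model.n
    total = 0
    for t, mem in enumerate(design.members):
        n_t = len(mem)
        if n_t == 1:
            continue
        p_t = design.saturations[t]
        if p_t == 0 or p_t == 1:
            continue
        v_t = _population_variance([ivec.L[i] for i in mem])
        total = total + (1 - p_t) * n_t * n_t / (p_t * n * n * (n_t - 1)) * v_t
    return total


# ----------------------------------------------------------------------
def conditional_odds_rho(design: Design, k: int, i: int):
    """``P(z_k = 0 | z_i = 1) / P(z_k = 1 | z_i = 0)`` from exact moments."""
    m_i = design.marginal(i)
    m_k = design.marginal(k)
    a = design.second_moment(i, k)
    num = (m_i - a) * (1 - m_i)
    den = m_i * (m_k - a)
    if den == 0:
        return None
    return num / den


@dataclass
class UnbiasednessReport:
    """Which sufficient conditions a design satisfies on a given edge set.

    * ``same_treatment`` — every edge's endpoints are treated identically
      almost surely (the only route to unbiasedness *without* baselines);
    * ``common_odds_ratio`` — the conditional odds ratio is constant over
      each individual's in-edges (unbiasedness of the generalized
      baseline-adjusted estimator); ``rho`` holds the per-target ratios
      where consistent, omitting targets whose in-edges are all degenerate;
    * ``equal_marginals`` — marginals match across every edge (unbiasedness
      of the plain baseline-adjusted estimator).
    """

    same_treatment: bool
    same_treatment_violations: list[Edge]
    common_odds_ratio: bool
    rho: dict[int, object]
    common_odds_ratio_violations: list[int]
    equal_marginals: bool
    equal_marginals_violations: list[Edge]

    def to_dict(self) -> dict:
        return {
            "same_treatment": {
                "satisfied": self.same_treatment,
                "violating_edges": [list(e) for e in self.same_treatment_violations],
            },
            "common_odds_ratio": {
                "satisfied": self.common_odds_ratio,
                "rho": {str(i): float(r) for i, r in self.rho.items()},
                "violating_targets": list(self.common_odds_ratio_violations),
            },
            "equal_marginals": {
                "satisfied": self.equal_marginals,
                "violating_edges": [list(e) for e in self.equal_marginals_violations],
            },
        }


def _close(x, y) -> bool:
    if isinstance(x, Fraction) and isinstance(y, Fraction):
        return x == y
    return abs(float(x) - float(y)) <= 1e-12 * max(1.0, abs(float(x)))


def check_unbiasedness(design: Design, edges: Iterable[Edge]) -> UnbiasednessReport:
    """Evaluate the three sufficient unbiasedness conditions edge by edge."""
    edges = list(edges)
    same_viol: list[Edge] = []
    marg_viol: list[Edge] = []
    by_target: dict[int, list[int]] = {}
    for k, i in edges:
        m_i = design.marginal(i)
        m_k = design.marginal(k)
        a = design.second_moment(i, k)
        # z_i = z_k a.s.  <=>  E[(z_i - z_k)^2] = m_i + m_k - 2 E[z_i z_k] = 0
        if not _close(m_i + m_k - 2 * a, 0):
            same_viol.append((k, i))
        if not _close(m_i, m_k):
            marg_viol.append((k, i))
        by_target.setdefault(i, []).append(k)
    rho: dict[int, object] = {}
    ratio_viol: list[int] = []
    for i, sources in by_target.items():
        ratios = []
        broken = False
        for k in sources:
            m_i = design.marginal(i)
            m_k = design.marginal(k)
            a = design.second_moment(i, k)
            if _close(m_i + m_k - 2 * a, 0):
                continue  # degenerate edge: the constraint holds automatically
            r = conditional_odds_rho(design, k, i)
            if r is None:
                broken = True
                break
            ratios.append(r)
        if broken or (
            ratios and any(not _close(r, ratios[0]) for r in ratios[1:])
        ):
            ratio_viol.append(i)
        elif ratios:
            rho[i] = ratios[0]
    return UnbiasednessReport(
        same_treatment=not same_viol,
        same_treatment_violations=same_viol,
        common_odds_ratio=not ratio_viol,
        rho=rho,
        common_odds_ratio_violations=sorted(ratio_viol),
        equal_marginals=not marg_viol,
        equal_marginals_violations=marg_viol,
    )


# ----------------------------------------------------------------------
def exhaustive_moments(
    model: HANEModel,
    design: Design,
    estimator: Callable,
    cap: int = 1_000_000,
):
    """Exact expectation and variance of an estimator by full enumeration.

    Walks every assignment in the design's support with its exact
    probability, evaluates ``estimator(z, Y(z))`` on the model's potential
    outcomes, and accumulates first and second moments.  With a rational
    model and a count-based design the result is exact (``Fraction``); this
    is the certification oracle behind every closed form in this module.

    Raises :class:`~hane.designs.SupportTooLargeError` when the support
    exceeds ``cap``.
    """
    mean = 0
    mean_sq = 0
    for z, prob in design.enumerate_support(cap=cap):
        val = estimator(z, model.evaluate_outcomes(z))
        mean = mean + prob * val
        mean_sq = mean_sq + prob * val * val
    return mean, mean_sq - mean * mean
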