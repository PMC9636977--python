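"""Individually weighted linear estimators of the total treatment effect.

The estimator class is ``sum_i (w_i z_i + v_i (1 - z_i)) Y_i`` with weights
that are deterministic — functions of the design's moments only, never of
the realized treatment vector.  That restriction is what makes the class
usable when the interference network is unknown: the weight on individual
``i``'s outcome may depend on whether *i* is treated but not on the
treatment of i's (unobserved) neighbors.

Three members matter here:

* the Horvitz–Thompson form ``(1/n) sum_i (z_i/E[z_i] - (1-z_i)/E[1-z_i]) Y_i``,
  the unique candidate for unbiasedness without baseline information;
* the baseline-adjusted estimator ``(1/n) sum_i (Y_i - alpha_i)/E[z_i]``,
  unbiased for the TTE under any design whose marginals are equal across
  interference edges, and computable from the *population-average* baseline
  alone when all marginals equal a common p;
* the generalized baseline-adjusted estimator with per-individual control
  weights ``rho_i``, unbiased whenever the design's conditional odds ratio
  ``P(z_k=0 | z_i=1) / P(z_k=1 | z_i=0)`` is constant over i's in-edges.

All arithmetic is carried out with plain Python sums so that ``Fraction``
inputs stay exact end to end; these estimators are O(n) and never the
bottleneck of a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .model import DimensionError, check_treatment_vector


def _is_constant(values: Sequence) -> bool:
    first = values[0]
    if isinstance(first, Fraction):
        return all(v == first for v in values)
    return max(float(v) for v in values) - min(float(v) for v in values) < 1e-12


@dataclass
class LinearEstimatorWeights:
    """The (w, v) pair of treated / control weights, one per individual."""

    w: Sequence
    v: Sequence

    def __post_init__(self):
        if len(self.w) != len(self.v):
            raise DimensionError("w and v must have equal length")

    @property
    def n(self) -> int:
        return len(self.w)


@dataclass
class ExperimentRecord:
    """One realized experiment: treatments, outcomes, and baseline estimates.

    ``alpha_hat`` is either a vector of per-individual baseline estimates or
    a single scalar population-average baseline; the two modes are distinct
    input states and the estimators enforce which designs each is valid for.
    ``marginals`` are the exact treatment probabilities ``E[z_i]`` of the
    design that produced ``z``.
    """

    z: np.ndarray
    Y: Sequence
    alpha_hat: object
    marginals: Sequence

    def __post_init__(self):
        n = len(self.Y)
        self.z = check_treatment_vector(self.z, n)
        if len(self.marginals) != n:
            raise DimensionError("marginals length does not match outcomes")
        for i, m in enumerate(self.marginals):
            if not 0 < m < 1:
                raise ValueError(
                    f"marginal treatment probability of individual {i} is {m}; "
                    "estimation requires 0 < E[z_i] < 1"
                )
        if not self.baseline_is_scalar and len(self.alpha_hat) != n:
            raise DimensionError("alpha_hat length does not match outcomes")

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def baseline_is_scalar(self) -> bool:
        return np.isscalar(self.alpha_hat) or isinstance(self.alpha_hat, Fraction)


def evaluate_linear(weights: LinearEstimatorWeights, rec: ExperimentRecord):
    """``sum_i (w_i z_i + v_i (1 - z_i)) Y_i`` for one realized experiment."""
    if weights.n != rec.n:
        raise DimensionError("weights and record have different lengths")
    total = 0
    for i in range(rec.n):
        zi = int(rec.z[i])
        total = total + (weights.w[i] * zi + weights.v[i] * (1 - zi)) * rec.Y[i]
    return total


def ht_weights(marginals: Sequence) -> LinearEstimatorWeights:
    """Horvitz–Thompson weights ``w_i = 1/(n E[z_i])``, ``v_i = -1/(n E[1-z_i])``.

    This is the only weight choice compatible with unbiasedness for the TTE
    within the individually weighted class (whether the design then delivers
    unbiasedness is a separate condition on treatment correlations across
    interference edges; see :func:`hane.theory.check_unbiasedness`).
    """
    n = len(marginals)
    w, v = [], []
    for i, m in enumerate(marginals):
        if not 0 < m < 1:
            raise ValueError(
                f"individual {i} has degenerate marginal E[z_i]={m}; "
                "Horvitz–Thompson weights require 0 < E[z_i] < 1"
            )
        w.append(1 / (n * m))
        v.append(-1 / (n * (1 - m)))
    return LinearEstimatorWeights(w, v)


def ht_estimate(rec: ExperimentRecord):
    """The Horvitz–Thompson-form TTE estimate on one realized experiment."""
    return evaluate_linear(ht_weights(rec.marginals), rec)


def baseline_adjusted_estimate(rec: ExperimentRecord):
    """Baseline-adjusted estimate ``(1/n) sum_i (Y_i - alpha_i) / E[z_i]``.

    With per-individual baselines this is the general form.  With a scalar
    (population-average) baseline the simplification
    ``(1/p)(mean(Y) - alpha_bar)`` is only derived for designs whose
    marginals all equal a common ``p``; supplying an average baseline under
    heterogeneous marginals is a contract error, not a silent approximation.
    """
    n = rec.n
    if rec.baseline_is_scalar:
        if not _is_constant(rec.marginals):
            raise ValueError(
                "a population-average baseline is only valid when every "
                "individual has the same marginal treatment probability; "
                "this design has unequal marginals — supply per-individual "
                "baseline estimates instead"
            )
        p = rec.marginals[0]
        mean_y = sum(rec.Y[i] for i in range(n)) / n
        return (mean_y - rec.alpha_hat) / p
    total = 0
    for i in range(n):
        total = total + (rec.Y[i] - rec.alpha_hat[i]) / rec.marginals[i]
    return total / n


def generalized_baseline_estimate(rec: ExperimentRecord, rho):
    """Baseline-adjusted estimator with per-individual control weights.

        (1/n) sum_i ( z_i/E[z_i] + (1-z_i) rho_i / E[1-z_i] ) (Y_i - alpha_i)

    ``rho_i`` is the design's conditional odds ratio
    ``P(z_k=0 | z_i=1) / P(z_k=1 | z_i=0)`` over i's in-edges; when that
    ratio is common across the in-edges of every i the estimator is unbiased
    for the TTE even under unequal marginals.  Under equal marginals the
    ratio is ``(1-p)/p`` and the estimator collapses to
    :func:`baseline_adjusted_estimate`.
    """
    n = rec.n
    if np.isscalar(rho) or isinstance(rho, Fraction):
        rho = [rho] * n
    if len(rho) != n:
        raise DimensionError("rho length does not match outcomes")
    if any(r < 0 for r in rho):
        raise ValueError("rho values must be nonnegative")
    alpha = rec.alpha_hat
    if rec.baseline_is_scalar:
        alpha = [rec.alpha_hat] * n
    total = 0
    for i in range(n):
        m = rec.marginals[i]
        zi = int(rec.z[i])
        weight = zi / (n * m) + (1 - zi) * rho[i] / (n * (1 - m))
        total = total + weight * (rec.Y[i] - alpha[i])
    return total


def difference_in_means(rec: ExperimentRecord):
    """Mean outcome of the treated arm minus mean outcome of the control arm."""
    treated = [rec.Y[i] for i in range(rec.n) if rec.z[i] == 1]
    control = [rec.Y[i] for i in range(rec.n) if rec.z[i] == 0]
    if not treated or not control:
        raise ValueError("difference in means requires both arms nonempty")
    return sum(treated) / len(treated) - sum(control) / len(control)


# ----------------------------------------------------------------------
def make_estimator(
    name: str, marginals: Sequence, alpha_hat=None, rho=None
) -> Callable:
    """Bind an estimator by name into a ``(z, Y) -> value`` callable.

    Names: ``"horvitz_thompson"`` (alias ``"ht"``), ``"baseline_adjusted"``,
    ``"generalized_baseline"``, ``"difference_in_means"``.  Used by the
    enumeration oracle and the Monte Carlo harness, which supply the
    outcomes per assignment.
    """
    if name in ("ht", "horvitz_thompson"):
        weights = ht_weights(marginals)
        return lambda z, Y: evaluate_linear(
            weights, ExperimentRecord(z, Y, 0, marginals)
        )
    if name == "baseline_adjusted":
        if alpha_hat is None:
            raise ValueError("baseline_adjusted requires alpha_hat")
        return lambda z, Y: baseline_adjusted_estimate(
            ExperimentRecord(z, Y, alpha_hat, marginals)
        )
    if name == "generalized_baseline":
        if alpha_hat is None or rho is None:
            raise ValueError("generalized_baseline requires alpha_hat and rho")
        return lambda z, Y: generalized_baseline_estimate(
            ExperimentRecord(z, Y, alpha_hat, marginals), rho
        )
    if name == "difference_in_means":
        return lambda z, Y: difference_in_means(
            ExperimentRecord(z, Y, 0, marginals)
        )
    raise ValueError(f"unknown estimator {name!r}")
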