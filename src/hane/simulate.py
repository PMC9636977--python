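"""Synthetic instances and a seeded Monte Carlo harness.

The generator builds interference networks (Erdős–Rényi, planted clusters,
star, chain, empty), draws heterogeneous model parameters from declared
distributions, and pairs them with a randomized design — everything
deterministic given the master seed, which spawns independent substreams
for the network, the parameters, the design draws, and baseline noise, so
changing the number of replications never changes the instance.

The harness replays a design many times, evaluates an estimator on each
realized experiment, and reports empirical mean and variance with Monte
Carlo standard errors next to the closed-form predictions from
:mod:`hane.theory`, so formula/simulation agreement is a one-line check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from . import theory
from .designs import Design, design_from_config
from .estimators import (
    ExperimentRecord,
    baseline_adjusted_estimate,
    difference_in_means,
    generalized_baseline_estimate,
    ht_estimate,
)
from .model import HANEModel

Edge = tuple[int, int]

_NETWORK_KINDS = ("erdos_renyi", "planted_clusters", "star", "chain", "empty")
_ESTIMATORS = (
    "baseline_adjusted",
    "baseline_adjusted_avg",
    "horvitz_thompson",
    "generalized_baseline",
    "difference_in_means",
)


@dataclass
class ScenarioSpec:
    """Full description of a synthetic experiment scenario.

    ``network`` is a dict like ``{"kind": "erdos_renyi", "q": 0.2}``;
    distributions are tuples ``("normal", mean, sd)``, ``("uniform", lo,
    hi)`` or ``("constant", value)``.  ``gamma_positive_frac`` mixes
    spillover signs: each drawn interference magnitude keeps its sign with
    this probability and is negated otherwise (spillovers can cut both
    ways).  ``design`` is a config for
    :func:`hane.designs.design_from_config`; a ``{"T": t}`` clusters entry
    is expanded to contiguous equal blocks.
    """

    n: int
    network: dict
    alpha_dist: tuple = ("normal", 0.0, 1.0)
    beta_dist: tuple = ("normal", 1.0, 0.5)
    gamma_dist: tuple = ("uniform", 0.1, 0.5)
    gamma_positive_frac: float = 1.0
    design: dict = field(default_factory=dict)
    estimator: str = "baseline_adjusted_avg"
    reps: int = 1000
    seed: int = 0


@dataclass
class SimResult:
    """Empirical estimator moments side by side with theory predictions."""

    estimate_mean: float
    estimate_var: float
    se_mean: float
    se_var: float
    tte: float
    predicted_mean: float | None
    predicted_var: float | None
    reps: int
    seed: int
    n_failed: int = 0

    @property
    def mean_discrepancy_se(self) -> float | None:
        """|empirical mean - predicted mean| in Monte Carlo SE units."""
        if self.predicted_mean is None:
            return None
        return abs(self.estimate_mean - self.predicted_mean) / self.se_mean

    @property
    def var_discrepancy_se(self) -> float | None:
        if self.predicted_var is None:
            return None
        return abs(self.estimate_var - self.predicted_var) / self.se_var

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_discrepancy_se"] = self.mean_discrepancy_se
        d["var_discrepancy_se"] = self.var_discrepancy_se
        return d


# ----------------------------------------------------------------------
def _draw(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        return rng.normal(dist[1], dist[2], size=size)
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=size)
    if kind == "constant":
        return np.full(size, float(dist[1]))
    raise ValueError(f"unknown distribution {dist!r}")


def generate_network(network: dict, n: int, rng: np.random.Generator) -> list[Edge]:
    """Directed edge list for the requested network kind."""
    kind = network["kind"]
    if kind == "empty":
        return []
    if kind == "star":
        return [(0, i) for i in range(1, n)]
    if kind == "chain":
        return [(i, i + 1) for i in range(n - 1)]
    seed = int(rng.integers(2**31))
    if kind == "erdos_renyi":
        g = nx.gnp_random_graph(n, network["q"], seed=seed, directed=True)
        return sorted(g.edges())
    if kind == "planted_clusters":
        t = int(network["T"])
        sizes = [n // t + (1 if r < n % t else 0) for r in range(t)]
        p_mat = [
            [network["q_in"] if a == b else network["q_out"] for b in range(t)]
            for a in range(t)
        ]
        g = nx.stochastic_block_model(sizes, p_mat, seed=seed, directed=True)
        return sorted(g.edges())
    raise ValueError(f"unknown network kind {kind!r}; choose from {_NETWORK_KINDS}")


def block_labels(n: int, T: int) -> list[int]:
    """Contiguous, nearly equal cluster labels 0..T-1 for n individuals."""
    sizes = [n // T + (1 if r < n % T else 0) for r in range(T)]
    labels: list[int] = []
    for t, s in enumerate(sizes):
        labels.extend([t] * s)
    return labels


def generate_instance(spec: ScenarioSpec) -> tuple[HANEModel, Design]:
    """Deterministically build (model, design) from a scenario spec."""
    ss = np.random.SeedSequence(spec.seed)
    net_seed, par_seed = ss.spawn(2)
    rng_net = np.random.default_rng(net_seed)
    rng_par = np.random.default_rng(par_seed)
    edges = generate_network(spec.network, spec.n, rng_net)
    alpha = _draw(spec.alpha_dist, spec.n, rng_par)
    beta = _draw(spec.beta_dist, spec.n, rng_par)
    gvals = _draw(spec.gamma_dist, len(edges), rng_par)
    if spec.gamma_positive_frac < 1.0:
        flip = rng_par.random(len(edges)) >= spec.gamma_positive_frac
        gvals = np.where(flip, -gvals, gvals)
    gamma = {e: float(v) for e, v in zip(edges, gvals) if v != 0}
    model = HANEModel(alpha, beta, gamma)
    design = _build_design(dict(spec.design), spec.n)
    return model, design


def _build_design(cfg: dict, n: int) -> Design:
    cfg.setdefault("n", n)
    if "T" in cfg and "clusters" not in cfg:
        cfg["clusters"] = block_labels(n, int(cfg.pop("T")))
    else:
        cfg.pop("T", None)
    return design_from_config(cfg)


# ----------------------------------------------------------------------
def _resolve_estimator(
    name: str,
    model: HANEModel,
    design: Design,
    marginals_f: list[float],
    rho,
) -> tuple[Callable, object]:
    """Return (per-draw evaluator taking (z, Y, alpha_hat), base alpha_hat)."""
    alpha = model.alpha.astype(float)
    if name == "baseline_adjusted":
        base = alpha.copy()
        fn = lambda z, Y, ah: baseline_adjusted_estimate(
            ExperimentRecord(z, Y, ah, marginals_f)
        )
    elif name == "baseline_adjusted_avg":
        base = float(np.mean(alpha))
        fn = lambda z, Y, ah: baseline_adjusted_estimate(
            ExperimentRecord(z, Y, ah, marginals_f)
        )
    elif name in ("horvitz_thompson", "ht"):
        base = None
        fn = lambda z, Y, ah: ht_estimate(ExperimentRecord(z, Y, 0.0, marginals_f))
    elif name == "generalized_baseline":
        if rho is None:
            raise ValueError("generalized_baseline requires rho")
        base = alpha.copy()
        fn = lambda z, Y, ah: generalized_baseline_estimate(
            ExperimentRecord(z, Y, ah, marginals_f), rho
        )
    elif name == "difference_in_means":
        base = None
        fn = lambda z, Y, ah: difference_in_means(
            ExperimentRecord(z, Y, 0.0, marginals_f)
        )
    else:
        raise ValueError(f"unknown estimator {name!r}; choose from {_ESTIMATORS}")
    return fn, base


def _theory_predictions(
    name: str,
    model: HANEModel,
    design: Design,
    noise_sd: float,
    offset: float,
) -> tuple[float | None, float | None]:
    tte = float(model.total_treatment_effect())
    marg = [float(m) for m in design.marginals()]
    if name in ("horvitz_thompson", "ht"):
        return tte + float(theory.bias_tte_hat(model, design)), None
    if name in ("baseline_adjusted", "baseline_adjusted_avg", "generalized_baseline"):
        mean = tte
        if name != "generalized_baseline":
            mean += float(theory.bias_baseline_adjusted(model, design))
        if name == "generalized_baseline":
            return mean, None
        var = float(theory.variance_general(model, design))
        n = model.n
        if name == "baseline_adjusted_avg":
            # scalar baseline shifted by eps moves the estimate by -eps/p
            mean -= offset / marg[0]
            var += (noise_sd / marg[0]) ** 2
        else:
            inv = [1.0 / m for m in marg]
            mean -= offset * float(np.mean(inv))
            var += noise_sd**2 * float(np.sum(np.square(inv))) / n**2
        return mean, var
    return None, None


def run_monte_carlo(
    model: HANEModel,
    design: Design,
    estimator: str = "baseline_adjusted_avg",
    reps: int = 1000,
    seed: int = 0,
    *,
    rho=None,
    noise_sd: float = 0.0,
    offset: float = 0.0,
) -> SimResult:
    """Replay the design ``reps`` times and summarize the estimator.

    ``noise_sd`` adds i.i.d. zero-mean Gaussian noise to the baseline
    estimates fresh on every replication; ``offset`` adds a constant
    misestimate.  Both feed only the estimator, never the outcomes.  Draws
    on which the estimator is undefined (an empty arm for the difference in
    means) are counted and skipped for that estimator; for the
    moment-exact estimators any failure aborts the run.
    """
    if reps < 2:
        raise ValueError("reps must be at least 2")
    ss = np.random.SeedSequence(seed)
    design_seed, noise_seed = ss.spawn(2)
    rng_design = np.random.default_rng(design_seed)
    rng_noise = np.random.default_rng(noise_seed)
    marginals_f = [float(m) for m in design.marginals()]
    fn, base_alpha = _resolve_estimator(estimator, model, design, marginals_f, rho)
    fmodel = model if not model.is_exact else model.as_float()
    values = []
    n_failed = 0
    for _ in range(reps):
        z = design.sample(rng_design)
        y = fmodel.evaluate_outcomes(z)
        alpha_hat = base_alpha
        if base_alpha is not None and (noise_sd > 0 or offset != 0.0):
            if np.isscalar(base_alpha):
                alpha_hat = base_alpha + offset + (
                    noise_sd * rng_noise.standard_normal() if noise_sd > 0 else 0.0
                )
            else:
                alpha_hat = base_alpha + offset
                if noise_sd > 0:
                    alpha_hat = alpha_hat + noise_sd * rng_noise.standard_normal(
                        model.n
                    )
        try:
            values.append(float(fn(z, y, alpha_hat)))
        except ValueError:
            if estimator != "difference_in_means":
                raise
            n_failed += 1
    vals = np.asarray(values)
    reps_eff = len(vals)
    mean = float(vals.mean())
    var = float(vals.var(ddof=1))
    se_mean = float(np.sqrt(var / reps_eff))
    centered = vals - mean
    m4 = float(np.mean(centered**4))
    se_var = float(
        np.sqrt(max(m4 - (reps_eff - 3) / (reps_eff - 1) * var**2, 0.0) / reps_eff)
    )
    pred_mean, pred_var = _theory_predictions(estimator, model, design, noise_sd, offset)
    return SimResult(
        estimate_mean=mean,
        estimate_var=var,
        se_mean=se_mean,
        se_var=se_var,
        tte=float(model.total_treatment_effect()),
        predicted_mean=pred_mean,
        predicted_var=pred_var,
        reps=reps_eff,
        seed=seed,
        n_failed=n_failed,
    )


def baseline_noise_study(
    model: HANEModel,
    design: Design,
    noise_sd: float,
    reps: int = 1000,
    seed: int = 0,
    *,
    offset: float = 0.0,
    baseline_mode: str = "average",
) -> SimResult:
    """Sensitivity of the baseline-adjusted estimator to baseline error.

    Zero-mean noise on the baseline estimate leaves the estimator unbiased
    (it enters linearly) but inflates the variance by ``(noise_sd/p)^2`` in
    average-baseline mode; a constant offset ``delta`` shifts the estimate
    by exactly ``-delta/p``.  Both predictions are embedded in the result
    for comparison against the empirical moments.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    name = "baseline_adjusted_avg" if baseline_mode == "average" else "baseline_adjusted"
    return run_monte_carlo(
        model,
        design,
        estimator=name,
        reps=reps,
        seed=seed,
        noise_sd=noise_sd,
        offset=offset,
    )


def run_scenario(spec: ScenarioSpec) -> tuple[HANEModel, Design, SimResult]:
    """Generate the instance and run the harness; bit-reproducible per seed."""
    model, design = generate_instance(spec)
    ss = np.random.SeedSequence(spec.seed)
    mc_seed = int(ss.spawn(3)[2].generate_state(1)[0] % (2**31))
    result = run_monte_carlo(
        model, design, estimator=spec.estimator, reps=spec.reps, seed=mc_seed
    )
    return model, design, result
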