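# hane — total treatment effect estimation under unknown-network interference

Randomized experiments on connected populations — public-health campaigns,
vaccine trials on a contact network, feature rollouts on a social platform —
violate SUTVA: treating one individual shifts the outcomes of others through
an interference network that is usually unknown and expensive to measure.
`hane` implements a design-based framework for estimating the **total
treatment effect** (TTE) in exactly that setting, together with the exact
enumeration and Monte Carlo machinery needed to certify every closed form it
ships.

## The model and the estimators

Outcomes follow the *heterogeneous additive network effects* model: for a
binary treatment vector `z ∈ {0,1}^n`,

```
Y_i(z) = α_i + β_i z_i + Σ_{(k,i)∈E} γ_ki z_k
```

with a per-individual baseline `α_i`, direct effect `β_i`, and an
edge-specific interference effect `γ_ki` for each directed edge of the hidden
network `E`. The estimand is the total treatment effect

```
TTE = (1/n) Σ_i (Y_i(1) − Y_i(0)) = (1/n) (Σ_i β_i + Σ_{(k,i)∈E} γ_ki).
```

Within the class of individually weighted linear estimators
`Σ_i (w_i z_i + v_i (1−z_i)) Y_i` (weights may depend on the design, never on
the realized `z`):

* **Without baseline information** the only candidate is the
  Horvitz–Thompson form `TTE^ = (1/n) Σ_i (z_i/E[z_i] − (1−z_i)/E[1−z_i]) Y_i`,
  and it is unbiased only if the design treats both endpoints of every edge
  identically — effectively cluster randomization over connected components.
  Its bias is `(1/n) Σ_{(k,i)∈E} (Cov[z_i,z_k]/Var[z_i] − 1) γ_ki`.
* **Given baseline estimates** (historical data or a pilot study), the
  baseline-adjusted estimator
  `TTE^{−α} = (1/n) Σ_i (Y_i(z) − α_i)/E[z_i]` is unbiased under *any* design
  with equal marginal treatment probabilities across edges — no knowledge of
  the network required. When all marginals equal `p` it needs only the
  population-average baseline: `TTE^{−α} = (1/p)(mean(Y) − mean(α))`.

Writing `L_i = β_i + Σ_k E[z_i] γ_ik / E[z_k]` for the *influence* of
individual `i`, the estimator is the inverse-propensity-weighted sample mean
`(1/n) Σ_i L_i z_i / E[z_i]`, so its design-based variance is

```
Var[TTE^{−α}] = Σ_{i,j} L_i L_j Cov(z_i, z_j) / (n² E[z_i] E[z_j]),
```

with closed forms for the completely randomized, cluster-randomized, and
(uniform or varying) saturation designs. All of these formulas — biases,
variances, and the unbiasedness conditions — are verified in the test suite
against an exhaustive-enumeration oracle in exact rational arithmetic.

## Worked example

```python
from fractions import Fraction
from hane import (bias_baseline_adjusted, bias_tte_hat, check_unbiasedness,
                  run_monte_carlo, variance_crd)
from hane.simulate import ScenarioSpec, generate_instance

spec = ScenarioSpec(
    n=30,
    network={"kind": "erdos_renyi", "q": 0.2},
    design={"kind": "completely_randomized", "m": 15},
    seed=7,
)
model, design = generate_instance(spec)
print("n, |E|, d_max:", model.n, len(model.gamma), model.max_outdegree())
print(f"TTE               = {model.total_treatment_effect():.4f}")
print(f"  direct part     = {model.direct_effect_part():.4f}")
print(f"  spillover part  = {model.interference_part():.4f}")
print(f"bias (HT, no baselines) = {float(bias_tte_hat(model, design)):.4f}")
print(f"bias (baseline-adj)     = {float(bias_baseline_adjusted(model, design)):.4f}")
print(f"Var (baseline-adj, CRD) = {float(variance_crd(model, Fraction(1, 2))):.4f}")
res = run_monte_carlo(model, design, estimator="baseline_adjusted_avg",
                      reps=5000, seed=7)
print(f"MC mean  = {res.estimate_mean:.4f}  (SE {res.se_mean:.4f})")
print(f"MC var   = {res.estimate_var:.4f}  (SE {res.se_var:.4f})")
```

Output:

```
n, |E|, d_max: 30 167 9
TTE               = 2.9268
  direct part     = 1.2780
  spillover part  = 1.6487
bias (HT, no baselines) = -1.7056
bias (baseline-adj)     = 0.0000
Var (baseline-adj, CRD) = 0.0139
MC mean  = 2.9250  (SE 0.0016)
MC var   = 0.0133  (SE 0.0003)
```

More than half of this TTE comes from spillovers. Ignoring baselines, the
Horvitz–Thompson form under completely randomized assignment would miss
most of that spillover mass (bias −1.71 of a 2.93 effect); subtracting the
population-average baseline removes the bias entirely, and the 5000-draw
Monte Carlo mean and variance land on the closed-form predictions within
sampling error.

A thin CLI wraps the same library: `hane generate`, `hane estimate`,
`hane theory`, `hane simulate` (see `hane --help`). Model files are plain
TSV/CSV; designs and scenarios are YAML/JSON.

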