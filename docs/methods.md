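# Methods

## Outcome model

The package works entirely inside the heterogeneous additive network
effects model: `Y_i(z) = α_i + β_i z_i + Σ_{(k,i)∈E} γ_ki z_k`, a finite
population of `n` individuals with `2n + |E|` free parameters. The edge set
is *defined* as the support of `γ`, so zero entries are dropped at
construction and a self-pair `(k, k)` is a validation error rather than
being folded into `β_k` — silent folding would corrupt outdegrees (and with
them every variance bound) and double-count direct effects. Edge direction
follows the convention "a record `(k, i, γ)` means treating `k` shifts
`i`'s outcome"; influence and bias formulas that sum over *outgoing* edges
of an individual are implemented (and tested) explicitly against that
storage convention, because the transpose mix-up is the classic bug in this
family of formulas.

The model deliberately excludes nonlinear responses — thresholds,
saturating spillovers, binary outcomes — which break the additivity that
everything downstream relies on. It is best suited to outcome variables on
a continuous scale (engagement levels, viral load) rather than binary
indicators.

Parameters may be `float` or `fractions.Fraction`. In the rational mode
every operation downstream (outcome evaluation, estimators, design moments,
enumeration) stays exact, which is what lets the test suite assert
`closed form == oracle` with no tolerance at all. Float paths are
vectorized through a cached sparse (CSR) interference matrix; a dense
`n × n` array is never materialized.

## Contagion reduction

Linear peer effects `Y_i = a_i + b_i z_i + Σ_k c_ki Y_k` are converted to
the additive model by solving `(I − Cᵀ) α = a` and `(I − Cᵀ) M = diag(b)`
and reading `β` off `M`'s diagonal and `γ` off its off-diagonal entries.
The elementwise recursion is taken as ground truth and the matrix algebra
is made to match it, with the fixed-point iterator as an independent oracle
on every instance — this pins down the row/column orientation of `C`
regardless of transpose conventions. The conversion never truncates the
Neumann series `Σ Cᵗ`; that form appears only in documentation. A spectral
radius strictly below 1 is required at construction (it is the precise
condition for the equilibrium to exist) and `|γ| < 1e−12` entries are
dropped after conversion so the support stays meaningful. Spectral radius
and the solves use dense linear algebra, which is the right tool at the
population sizes this package targets (up to a few thousand).

## Designs and their moments

Four designs are provided, each with exact closed-form `E[z_i]` and
`E[z_i z_j]` (as `Fraction`s for the count-based designs):

| design | marginal | second moment |
|---|---|---|
| Bernoulli(p) | `p` | `p²` (i ≠ j) |
| completely randomized (m of n) | `m/n` | `m(m−1)/(n(n−1))` |
| cluster (k of T clusters) | `k/T` | same cluster `k/T`; across `k(k−1)/(T(T−1))` |
| saturation (mₜ of nₜ per cluster) | `mₜ/nₜ` | same cluster `mₜ(mₜ−1)/(nₜ(nₜ−1))`; across `p_τ p_σ` |

The completely randomized constructor takes the integer treated count, not
a fraction: rounding `p·n` silently would change every moment, so the
caller must round explicitly. Saturation levels must yield integer
per-cluster counts (validated; levels are then stored as exact fractions
`mₜ/nₜ`). A cluster of size one has no within-cluster pairs, so the
`nₜ − 1` denominator in the same-cluster second moment is never evaluated
there. The budget identity `Σ nₜ pₜ = np` is checked only against an
optionally supplied budget and violating it raises a warning, not an
error — all moment formulas are well defined without it. The matched-pair
design is the saturation special case of size-two clusters at level 1/2.

Every design exposes `enumerate_support()` (exact probabilities) and
`covariance_quadratic_form(u)`, which evaluates
`Σᵢⱼ uᵢ uⱼ Cov(z_i, z_j)` through the block structure of the covariance
(two distinct values for CRD, per-cluster blocks for cluster/saturation) in
O(n). Sampling accepts an integer seed or a shared `numpy` Generator, so a
Monte Carlo run is reproducible from one master seed.

## Estimators

Weights are constructed from design moments only — the construction API
never sees a realized `z`, which enforces the defining restriction of the
individually weighted class. The baseline-adjusted estimator accepts two
distinct baseline modes: per-individual estimates (general form) or a
single population-average value, which is valid only under constant
marginals; mixing the average mode with heterogeneous marginals raises an
error because the simplified form is only an identity in that case. The
estimator takes baseline estimates as given; sensitivity to baseline error
is a property of the simulation harness (below), not a correction inside
the estimator.

The generalized baseline-adjusted estimator uses weights
`w_i = 1/(n E[z_i])`, `v_i = +ρ_i/(n E[1−z_i])` with
`ρ_i = P(z_k=0 | z_i=1)/P(z_k=1 | z_i=0)` constant over the in-edges of
`i`. The sign on `v_i` is the one required by the coefficient-matching
derivation: matching the interference coefficients `γ_ki` to `1/n` forces
`v_i = (E[z_i] − E[z_i z_k]) / (n E[z_i] (E[z_k] − E[z_i z_k])) ≥ 0`, which
equals `ρ_i/(n E[1−z_i])` with a **plus** sign, and only this sign makes
the equal-marginal case collapse to the plain baseline-adjusted estimator
(`ρ_i = (1−p)/p` then gives `v_i = w_i = 1/(np)`). The enumeration oracle
certifies unbiasedness of this form on designs satisfying the ratio
condition. The package verifies the ratio condition for a given design and
edge set (`check_unbiasedness`) rather than constructing designs that
satisfy it — no constructive recipe exists for general unequal-marginal
designs. Degenerate edges (endpoints treated identically almost surely)
are excluded from the ratio condition since their unbiasedness constraint
holds automatically.

## Bias, variance, and the oracle

Closed forms implemented: the HT-form bias
`(1/n) Σ (Cov[z_i,z_k]/Var[z_i] − 1) γ_ki`; the baseline-adjusted bias
`(1/n) Σ (E[z_source]/E[z_target] − 1) γ`; the general variance through the
influence vector and the design's quadratic form; and the per-design
variance displays (CRD `(1−p)/(p(n−1))·popvar(L)`, cluster over cluster-mean
influences with uniform cluster sizes enforced, saturation
`Σ_τ (1−p_τ) n_τ²/(p_τ n² (n_τ−1)) V_τ`). The uniform-saturation display is
the `p_τ ≡ p` specialization of the varying one; cluster randomization with
singleton clusters reduces to CRD; both identities are tested. With varying
saturation levels the influence terms themselves depend on the marginals,
so `V_τ` is computed under the design's own marginals. The within-cluster
derivation shows the varying-saturation display agrees with the general
covariance form exactly (clusters are independent, so no cross-cluster
correction arises), and the enumeration oracle confirms this on toy
instances.

`exhaustive_moments` walks the full support with exact probabilities and
returns exact expectation and variance of any estimator; a configurable cap
(default 10⁶ support points) redirects oversized problems to Monte Carlo.
Exact-arithmetic policy: oracle certification uses rational probabilities
and rational model parameters so "equals exactly" is literal; production
paths use doubles with a 1e−10 comparison tolerance (the n = 200
formula-vs-general checks come out around 1e−17).

The variance-bound diagnostic uses `popvar(L) ≤ B²(1 + d_max)²` with
`d_max` the maximum *outdegree*: each influence term is at most
`B(1 + d_i)` in magnitude when direct and interference effects are bounded
by `B` (the `+1` accounts for the direct effect alongside the `d_i`
outgoing edges). This preserves the `B² d_max²/pn` scaling of the variance.

## Synthetic instances and the Monte Carlo harness

The generator emulates the study conditions the theory addresses: directed
Erdős–Rényi networks (the canonical well-connected case; default
`q = 0.2` on `n = 30` for the agreement checks, dense enough that
spillovers dominate the TTE), planted-cluster (stochastic block) networks
for cluster/saturation designs, plus star, chain, and empty graphs as
analytically transparent extremes. Baselines default to `N(0, 1)`, direct
effects to `N(1, 0.5)`, interference effects to `Uniform(0.1, 0.5)` per
edge with an optional sign-mixing fraction for antagonistic spillovers —
heterogeneous but bounded effects of comparable magnitude to the direct
effects, so the interference component of the TTE is material without
dwarfing it. What the generator does *not* emulate: parameter correlation
with network position, degree heterogeneity beyond the block structure,
temporal dynamics, or outcome nonlinearity — passing tests certify the
design-based algebra, not robustness to those real-data features.

A master seed spawns independent substreams for network structure, model
parameters, design draws, and baseline noise, so changing the replication
count never changes the instance and every result is bit-reproducible.
Monte Carlo comparisons use a fixed four-standard-error criterion (the SE
of the variance uses the fourth-central-moment formula, not the normality
shortcut), keeping false failures negligible across the whole suite while
remaining sensitive. Default problem sizes (enumeration at `n = 8`, 50
rational instances; agreement runs at 5000 replications) keep the entire
certification battery in the seconds range.

Baseline-error sensitivity: zero-mean noise of standard deviation `s` on
the average-baseline estimate leaves the estimator unbiased (it enters
linearly) and inflates the variance by exactly `(s/p)²`; a constant offset
`δ` shifts the estimate by exactly `−δ/p`. Both propagation laws are
embedded in the harness predictions and verified by enumeration and
simulation.

## Known limitations

* No variance *estimation* from a single realized experiment: the formulas
  are population quantities in the unobserved influence terms.
* No confidence intervals or hypothesis tests; the closed-form variance is
  reported as-is.
* No optimal cluster construction from a known network, and no search over
  saturation levels trading bias against variance.
* The contagion module covers only the static linear fixed point — no
  dynamics over time.
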