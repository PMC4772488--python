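# Methods

## Model

The outcome is a binary indicator of skilled attendance at birth (doctor,
nurse or midwife). For woman *i* in district *j*,

y_ij | η_ij ~ Bernoulli(π_ij),  π_ij = exp(η_ij)/(1 + exp(η_ij)),

η_ij = α′λ_ij + Σ_k f_k(x_ijk) + f_str(S_j) + f_unstr(S_j).

The spatial term is deliberately split: f_str carries spatially *correlated*
heterogeneity (districts resemble their neighbours), f_unstr carries
spatially *unpatterned* heterogeneity. Comparing the two indicates whether
unexplained district variation is clustered or random, and watching f_str
shrink as covariate blocks enter quantifies how much of the geographic
pattern those covariates explain.

### Priors

* Fixed effects: N(0, 10⁶) — effectively diffuse. With ~12,000 observations
  the likelihood dominates at any plausible prior scale.
* Smooths: B-spline coefficients γ_k with the random-walk prior
  γ_k ~ N(0, τ²_k (DᵀD)⁻), D the second-order difference operator — the
  Bayesian form of a P-spline penalty. Defaults: cubic splines, 20
  equidistant knots over the observed range, second-order penalty. All
  configurable per term.
* Structured effect: intrinsic CAR, p(f_str) ∝ exp(−f′K f / 2τ²_str) with K
  the adjacency Laplacian. The density is improper (flat along the
  per-component constant), so each retained draw is constrained to sum to
  zero within every graph component. Districts with no neighbours cannot
  carry an ICAR effect; their f_str is pinned to 0 (with a logged warning)
  and the unstructured term absorbs their heterogeneity.
* Unstructured effect: iid N(0, τ²_unstr).
* All variance components: inverse-gamma(a, b) with a = b = 0.001 by
  default — the conventional weakly-informative choice for these models.
  The toy-posterior tests use a = 1, b = 0.5 instead, purely because a
  proper, lighter-tailed hyperprior makes the quadrature oracle
  numerically well-behaved; the contract being tested (sampler equals
  oracle under the *same* prior) is unaffected.

### Identifiability and centring

The intercept absorbs all level constraints. Each smooth is centred to mean
zero over the data at every iteration; because the B-spline basis is a
partition of unity, subtracting the data-mean uniformly from the
coefficients shifts the whole curve, so the stored coefficient draws are
themselves centred and the offset moves into the intercept exactly (a move
along the penalty's null space, leaving both likelihood and prior
unchanged). The structured effect is recentred per component each
iteration; when the graph is connected the shift is likewise transferred to
the intercept exactly. For a disconnected graph the per-component
recentring is the standard ICAR projection and is applied without
compensation. The unstructured effect needs no constraint — its proper
Gaussian prior centres it.

### Sampling

Polya-Gamma data augmentation: ω_ij ~ PG(1, η_ij) makes every coefficient
block conditionally Gaussian, so the sampler is a pure Gibbs scheme with
exact full conditionals — fixed effects, each smooth, the structured field
(a 110×110 sparse-precision Gaussian solve), the unstructured field
(diagonal), then conjugate inverse-gamma updates for every τ². The PG(1, z)
variates are drawn with an exact alternating-series rejection sampler
(Devroye's method; truncated inverse-Gaussian plus exponential-tail
proposal, t = 0.64), vectorised over observations and validated against the
closed-form mean tanh(z/2)/(2z) and variance. No truncation approximation
is involved.

Chain defaults for reporting runs are 12,000 iterations, 2,000 burn-in,
thin 10. The test suite and worked examples use shorter chains (e.g. 2,500
iterations, 500 burn-in, thin 4 for the 110-district recovery run; the
problem sizes and chain lengths used are stated where they appear). The
blocked conjugate updates mix fast enough that these shorter chains give
stable posterior means and 95% intervals at those sample sizes; this is a
numerical-budget choice for examples and tests, not a recommended analysis
setting.

The deviance D = −2 log p(y|θ) is stored each retained iteration; D(θ̄) is
evaluated at the posterior-mean predictor, which equals the deviance at the
posterior-mean parameters because η is linear in every block. DIC and
P_D = D̄ − D(θ̄) follow directly; a negative P_D (possible under poor
mixing) is reported with a warning rather than an error.

## Policy-period operationalisation

Calendar months are CMC integers (Jan-1900 = 1). Eras are assigned by
closed-start/open-end boundaries: cash and carry before Jun-1998; free
antenatal Jun-1998 onwards; free delivery from Sep-2003 in the configured
deprived regions (default: Northern, Upper East, Upper West, Central) and
from Apr-2005 elsewhere — months Sep-2003..Mar-2005 in non-deprived regions
remain free-antenatal; the insurance era starts Jul-2007. The short
premium-exemption window at the end of the analysis window (Jul–Oct 2008)
is not a separate category. Records claiming a skilled attendant outside a
facility are treated as recall error and removed (the fraction is
reported); missing partner's education merges into the "don't know / no
formal education" base level; any other missing value drops the record with
logging.

## Sequential build and retention rule

Model 1: intercept only. Model 2: + both spatial blocks. Model 3: + the
policy factor. Model 4: + controls (remaining categorical terms as fixed
effects, all continuous covariates as smooths). "Significant at p < 0.05"
is operationalised as the 95% equal-tailed credible interval excluding the
null — the coherent Bayesian reading of a frequentist retention rule. In
Model 4 a control categorical is dropped when *no* level's interval
excludes OR 1, and the model is refitted once; the policy factor is exempt.
Smooth terms are not subject to the rule.

Two scalar summaries of the spatial effects are computed, because printed
"posterior mean spatial effect [SD]" summaries are ambiguous: the posterior
mean [SD] of the variance components τ²_str and τ²_unstr (the default, and
the input to the percent-reduction decomposition), and the posterior mean
[SD] of the cross-district standard deviation of the effects.

## Synthetic data generator

The generator simulates the model forward under a known `TruthBundle`, so
recovery is testable. The default scenario mirrors the scale of the real
pooled birth-history file:

| quantity | default | basis |
|---|---|---|
| districts | 110 (10 × 11 rook lattice) | real district count |
| births | 12,200 | pooled file size (~12.2k) |
| era shares | 0.4135 / 0.3821 / 0.1319 / 0.0725 | era denominators |
| policy ORs | 1.17 / 1.67 / 1.65 | published adjusted estimates |
| control effects | published adjusted ORs; ethnicity 0 | final-model table |
| τ²_str | 1.0 | order of the published structured summary |
| τ²_unstr | 0.05 | published unstructured summary is near zero (0.02); a small value is a declared choice |
| band offsets | north −1.4, central +0.3, south +0.6 | north–south uptake gaps of regional magnitude (e.g. 2.5% vs 72% uptake implies a logit gap > 3) |
| inconsistency rate | 4 × 10⁻⁴ | "< 0.05%" exclusion share |
| intercept | 0.0 | gives ~49% overall uptake, matching the pooled 48.6% |

Covariates are drawn independently: age ~ N(28, 6.5²) truncated to
[15, 49]; parity 1 + Poisson(2.3); antenatal visits Poisson(4); distance
lognormal(1.2, 1.0) km (median ≈ 3.3 km); categorical mixes follow the
pooled composition. True smooths are increasing-saturating in age and
antenatal visits and decreasing in parity and distance, centred over the
generated sample. The structured truth is an exact ICAR draw (via
eigendecomposition of K, sampling only nonzero-eigenvalue directions) plus
the deterministic band gradient, recentred per component.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: two-stage cluster sampling and its
design effects, covariate–covariate and covariate–space correlation
(covariates are independent of district here, so there is no spatial
confounding), reporting error beyond the planted inconsistency flag, and
temporal autocorrelation of uptake within eras beyond the era means.

## Distance construction

Sampling clusters are snapped to the nearest road-network junction
(Euclidean), and the network distance to the closest maternity facility is
computed by multi-source Dijkstra, with the snap offset added — a
conservative, monotone rule (adding roads can only shorten distances).
Clusters whose network component contains no facility get the straight-line
distance to the nearest facility node, flagged as a fallback; how such
off-network clusters were handled in the original GIS workflow is not
documented, so this rule is a declared choice. Coordinates are planar (the
synthetic fixtures are in km); geographic coordinates would require a
great-circle snap and are out of scope for the default path.

## Descriptive layer

Era-by-characteristic percentage tables use Pearson chi-squared on the
2 × (eras present) counts per category level, without continuity correction
(cell counts at this scale are large); the degrees of freedom are adjusted
and flagged when an era is empty. Quartiles use linear interpolation
between closest ranks (the convention is declared because printed tables
rarely state one). The monthly uptake series carries empty months as
missing, not zero. Correlogram significance uses the white-noise band
1.96/√n. The policy-transition check correlates a fixed 8-month pre-policy
window with the same-length window offset forward by 1..8 months, so the
eighth lag aligns the comparison exactly at the transition point; the
published description of this procedure is loose, and this definition (with
a configurable window) is one faithful reading, applied to proportions
rather than counts.

## Numerical choices and edge cases

* Degenerate spline inputs (constant covariate, too few distinct values)
  raise a dedicated error instead of producing a singular basis.
* A tiny ridge (10⁻¹⁰) stabilises the spline-block Cholesky against the
  penalty null space before the data term is added.
* Possible separation is detected post-fit (posterior-mean |coefficient| >
  15) and reported as a warning with the offending terms, never silently.
* `percent_reduction` rounds to one decimal, matching the reporting
  convention of the tables it reproduces; it is scale-invariant.
* Pooling printed era percentages reconstructs counts by rounding
  pct·n/100; since the printed inputs carry only one decimal, the pooled
  value is only determined to about ±0.05 percentage points.
* All randomness flows through `numpy.random.Generator` seeded from the
  relevant config; identical configs reproduce identical draws, tables and
  artifacts byte-for-byte.

## Known limitations

* The retention rule tests each categorical as a block of marginal
  intervals; a joint test could retain a factor whose levels are only
  jointly informative.
* For disconnected district graphs the per-component recentring of f_str is
  applied without an exact compensating move; with an intercept in the
  model this is the standard approximation and is exact in the connected
  case.
* DIC is the only model-comparison criterion implemented (no WAIC/LOO), by
  design.
* Survey weights are not supported; the analyses this package reproduces
  did not use them.
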