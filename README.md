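# geosba

Bayesian geoadditive modelling of district-level **skilled birth attendance**
under successive maternity-fee policies.

Many low- and middle-income countries have moved through a sequence of
maternity fee regimes — full cost recovery ("cash and carry"), free antenatal
care, free delivery care (often rolled out to the most deprived regions
first), and finally integration into a national health insurance scheme.
Whether these policies raised the use of skilled birth attendants *and*
narrowed the gaps between districts is a spatial question: uptake clusters
geographically, and a national odds ratio says nothing about which districts
were left behind.

`geosba` implements the full analysis pipeline for pooled birth-history
survey data of the Ghana DHS type: one row per birth with a binary
skilled-attendance outcome, a district code, the birth month, and a set of
demographic, socioeconomic and accessibility covariates. Because such
microdata are access-restricted, the package ships a first-class synthetic
generator that emulates their structure with known ground truth, so every
stage of the pipeline is testable against the values that were planted.

## The model

For woman *i* in district *j*, with binary outcome
*y*<sub>ij</sub> ~ Bernoulli(π<sub>ij</sub>) and logit link, the structured
additive predictor is

    η_ij = α′λ_ij + Σ_k f_k(x_ijk) + f_str(S_j) + f_unstr(S_j)

* **α** — fixed effects of the categorical covariates λ (policy era at
  birth, maternal and partner's education, religion, ethnicity, household
  wealth quintile, urban/rural residence), dummy-coded against declared
  base levels;
* **f_k** — penalised-spline (P-spline) smooths of the continuous covariates
  (maternal age, parity, antenatal visits, road distance to the nearest
  facility): cubic B-splines on an equidistant knot grid with a
  second-order random-walk prior on the coefficients;
* **f_str** — spatially *structured* district effect with an intrinsic CAR
  (Gaussian Markov random field) prior, precision K/τ²_str where K is the
  adjacency-graph Laplacian, identified by a per-component sum-to-zero
  constraint: neighbouring districts shrink toward each other;
* **f_unstr** — exchangeable *unstructured* district effect, iid
  N(0, τ²_unstr);
* inverse-gamma hyperpriors on all variance components.

Posterior sampling uses **Polya-Gamma auxiliary-variable Gibbs**: given
ω<sub>ij</sub> ~ PG(1, η<sub>ij</sub>), every coefficient block has an exact
Gaussian full conditional. The per-iteration deviance D = −2 log p(y|θ) is
stored, giving the DIC decomposition

    P_D = D̄(θ) − D(θ̄),      DIC = D̄(θ) + P_D.

Model building is sequential: Model 1 (null) → Model 2 (+ spatial effects)
→ Model 3 (+ policy eras) → Model 4 (+ controls), with controls whose 95%
credible interval includes an odds ratio of 1 dropped and the model refitted
once (the primary policy factor is always retained). Districts are
classified *significantly low/high* when the 95% equal-tailed credible
interval of f_str lies entirely below/above zero.

## Worked example

```python
from geosba import (GeneratorConfig, make_lattice_graph, generate_survey,
                    default_full_spec, McmcConfig, sequential_build,
                    odds_ratio_table, classify_spatial, policy_crosstab)

cfg = GeneratorConfig(rows=4, cols=4, n_births=2000, seed=42)
graph = make_lattice_graph(cfg.rows, cfg.cols)
table, truth = generate_survey(cfg, graph)

print(policy_crosstab(table).cells[["period", "pct", "n"]])

result = sequential_build(table, graph, default_full_spec(n_knots=10),
                          McmcConfig(iterations=1000, burn_in=300, thin=2, seed=0))
```

The crude uptake rises across the eras, as planted:

```
        period  pct   n
cash_and_carry 46.7 824
free_antenatal 47.3 755
 free_delivery 55.9 261
          nhis 56.9 160
```

The DIC cascade shows the spatial block and the controls doing the heavy
lifting, with a smaller gain from the policy factor alone:

```
model1: DIC=2773.7  pD=1.0
model2: DIC=2440.2  pD=15.1
model3: DIC=2432.5  pD=18.5
model4: DIC=2231.7  pD=42.2
reductions: [333.4, 7.7, 200.8]
```

Adjusted policy odds ratios from Model 4 (truth 1.17 / 1.67 / 1.65; at this
reduced sample size the free-antenatal interval still includes 1):

```
                         term   or  lower  upper  significant
policy_period[free_antenatal] 1.06   0.82   1.34        False
 policy_period[free_delivery] 1.63   1.20   2.33         True
          policy_period[nhis] 1.73   1.16   2.63         True
```

`classify_spatial` on the Model 2 structured effects labels 3 of the 16
districts significantly low and 2 high (the planted north band), and the
builder drops the pure-noise control:

```
{'not_significant': 11, 'low': 3, 'high': 2}
dropped: {'ethnicity': '95% credible interval includes OR 1 for every level'}
```

The same pipeline is scriptable from the shell:

```bash
geosba run-all --config config.yaml --seed 7 --out-dir runs/demo
```

writing the exclusion log, era-by-characteristic tables, correlograms, the
four model fits with their DIC block, odds-ratio table, per-district
classification and percent-reduction report as plain CSV/JSON.

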