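# sarlogit

Bayesian **s**tructured **a**dditive **r**egression for binary survey
outcomes with spatial structure — built for mapping composite knowledge
indicators from national household surveys, such as women's knowledge of
mother-to-child transmission of HIV (MTCT) and its prevention (PMTCT).

## The problem and the model

DHS-style surveys ask women a battery of yes/no questions; a respondent
answering yes to all five MTCT/PMTCT questions (heard of HIV; transmission
possible during pregnancy, delivery, breastfeeding; aware of preventive
drugs) is said to have *sufficient knowledge*. Interest lies both in which
socio-demographic factors drive that binary outcome and in how it varies
across the country's regions after adjustment.

For woman *i* in household *k* of community (cluster) *j* in region *s*,
the outcome y ~ Bernoulli(p) follows a structured additive logistic model

    logit p = x'β + Σ_j f_j(z_j) + f_spat(s) + u_household + u_community

with

* **x'β** — dummy-coded categorical effects (residence, marital status,
  religion, ethnicity, education, wealth quintile, work status, media
  exposure) under vague N(0, 10⁶) priors;
* **f_j** — nonlinear effects of metrical covariates (current age, age at
  first birth, number of antenatal-care visits) as penalized B-splines
  whose coefficients follow a second-order random walk
  β_t = 2β_{t−1} − β_{t−2} + u_t, u_t ~ N(0, τ²);
* **f_spat** — an intrinsic CAR (ICAR) Gaussian Markov random field on the
  region contiguity graph: conditional on its neighbours, each region's
  effect is N(neighbour mean, τ²/N_s);
* **u** — iid Gaussian random intercepts at household and community level;
* every variance τ² carries a weakly informative inverse-Gamma IG(a, b)
  prior (default a = b = 0.001).

Models are compared along the nested ladder **M1** (spatial only), **M2**
(+ fixed effects + smooths), **M3** (+ household/community intercepts)
using the deviance information criterion DIC = D̄ + pD.

Inference is by a blocked Gibbs sampler with exact Pólya-Gamma
augmentation of the logistic likelihood (the PG(1, z) rejection sampler is
implemented in-package, numba-compiled). Sum-to-zero identifiability
constraints on the spatial field and each smooth are imposed by
conditioning-by-kriging. The sampler is validated against brute-force
posterior references (dense quadrature, long-run random-walk Metropolis)
in the test suite.

Because real DHS microdata are access-restricted, the package ships a
synthetic-data generator that emulates the survey's structure — regions on
a contiguity graph, clusters nested in regions, households in clusters,
published covariate marginals, and outcomes drawn from the predictor above
with known effects — so the whole pipeline is testable end to end.

## Worked example

```python
from sarlogit import (SimulationConfig, StructuredAdditiveLogit,
                      default_model_spec, simulate_dataset)

data = simulate_dataset(SimulationConfig(n_women=3000), seed=3)
spec = default_model_spec("M3", n_knots=12)
model = StructuredAdditiveLogit.from_dataframe(data.women, spec, data.graph)
result = model.fit(seed=1, n_iter=4000, burn=1000)
print(result.summary())
```

prints (abridged; a 600-iteration run of the same configuration):

```
Structured additive logistic regression (model M3, n=3000)
...
Fixed effects (logit scale):
                          mean      sd    q2.5   q97.5
intercept               0.8601  0.4914 -0.0198  1.7607
television=yes         -0.2836  0.0768 -0.4406 -0.1363
marital=never_married  -0.1856  0.0937 -0.3859 -0.0099
...
Variance parameters:
tau2_spatial            0.2444  0.1125  0.0959  0.5284
sigma2_community        0.1448  0.0540  0.0581  0.2846
...
Spatial field over 36 regions: posterior means in [-0.557, 0.456], sum 1.50e-15
DIC: 3890.01  (Dbar 3757.27, Dhat 3624.52, pD 132.75)
```

Read this as: watching television is associated with lower odds of
sufficient knowledge (posterior mean −0.28 on the logit scale, interval
excluding 0), the spatial field spans about ±0.5 logits across regions and
sums to zero by construction, and the effective parameter count pD ≈ 133
reflects the smooths, the field and the random intercepts.

From the result you can also pull report surfaces:

```python
result.or_table()          # posterior odds ratios, reference rows as 1/1/1
result.classify_regions()  # higher / lower / not_significant per region
result.smooth_curve("age") # posterior mean curve + 95% band on a grid
```

A thin CLI wraps the pipeline:

```bash
sarlogit simulate --seed 1 --n-women 5000 --out sim/
sarlogit fit --data sim/women.csv --graph sim/graph.txt --level M3 --seed 2 --out fit/
sarlogit report --results fit/ --out reports/
sarlogit tabulate --data sim/women.csv --out tables/
```

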