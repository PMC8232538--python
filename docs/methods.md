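# Methods

## Outcome construction

The binary outcome *sufficient knowledge of MTCT and PMTCT* is a composite
of five survey questions (ever heard of HIV; transmission during pregnancy;
during delivery; during breastfeeding; awareness of preventive drugs), each
coded 1 for yes. A respondent scores 5/5 to be classified sufficient;
anything less is insufficient. Records missing any of the five responses
are excluded before scoring and modelling (complete-case rule) and the
number dropped is logged and written to the run record — missing answers
are never coerced to "no". Percentages in descriptive tables are computed
from each table's own denominator and rounded half-up to one decimal at
presentation only; stored proportions are never rounded. The published
newspaper-readership rows total 34,866 against an overall sample of 34,837;
the package does not attempt to reproduce that internal inconsistency — its
tabulations are always self-consistent, and the generator normalises those
counts to proportions.

## The structured additive logistic model

For woman *i* (household *k*, community *j*, region *s*):

    y_i ~ Bernoulli(p_i),   logit p_i = x_i'β + Σ_m f_m(z_im) + f_spat(s_i) + u_jk + v_j

**Fixed effects.** Categorical covariates are dummy-coded against explicit
reference levels (rural, ever-married, "others" for religion/ethnicity, no
education, poorest, not working, "no" for each media channel). The
intercept and all coefficients carry independent N(0, 1/λ₀) priors with
λ₀ = 10⁻⁶ (sd = 1000), i.e. effectively flat. A consequence worth knowing:
a level with zero (or separated) observations in a given dataset has an
honestly diffuse posterior — the model reports it rather than regularising
it away.

**Smooths.** Each metrical covariate enters as a B-spline (default 20
equidistant knots spanning the observed range, cubic, boundary knots
repeated so the basis is a partition of unity) with a second-order
random-walk (RW2) penalty K = D₂'D₂ on the coefficients: the stochastic
form β_t = 2β_{t−1} − β_{t−2} + u_t, u_t ~ N(0, τ²). K has rank k−2 and
annihilates constant and linear coefficient sequences, so the prior shrinks
toward straight lines, not toward zero. The published formula for the
random walk mixes its indices; it is implemented as the standard RW2 above.
Knot count and degree are configurable; with an RW2 penalty the fit is
insensitive to the knot count, which is why 20/cubic is an adequate
default. Integer covariates (ANC visit counts) are treated as metrical.

**Spatial field.** An intrinsic CAR prior on the region contiguity graph:
jointly, precision Q/τ² with Q = diag(N_s) − A (the graph Laplacian), whose
full conditionals are N(neighbour mean, τ²/N_s). Q is singular (row sums
zero; rank = regions − components).

**Random intercepts.** iid N(0, σ²) at household and community level
(model M3 only).

**Variances.** Every τ² and σ² has an IG(a, b) prior with a = b = 0.001 by
default, overridable; posterior summaries are reported on the variance
scale.

**Identifiability.** The spatial field is constrained to sum to zero over
regions; each smooth is constrained to sum to zero over the observations
(equivalently 1'Bα = 0, orthogonality to the intercept only — smooths keep
their linear trends, which is what the reported effect curves should show).
Intercept/field and intercept/smooth level swaps therefore leave the
likelihood and the constrained solution unchanged (tested).

**Model ladder.** M1: intercept + spatial field (crude geography);
M2: M1 + fixed effects + smooths; M3: M2 + household and community
intercepts. M1 ⊂ M2 ⊂ M3 by construction from a single specification.

## Posterior computation

The posterior is approximated by a blocked Gibbs sampler using the
Pólya-Gamma augmentation of the logistic likelihood: with
ω_i ~ PG(1, η_i), every latent Gaussian block has a conjugate multivariate
normal full conditional, and every variance a conjugate inverse-Gamma one.
The PG(1, z) sampler is the exact alternating-series rejection method
(two-piece truncated-inverse-Gaussian / exponential proposal, series
squeeze), compiled with numba; it introduces no truncation or
approximation error, so the only approximation in the pipeline is Monte
Carlo. Sum-to-zero constraints are imposed by conditioning-by-kriging: each
unconstrained Gaussian block draw x is corrected to
x − Σa(a'x)/(a'Σa), which is an exact draw from the constrained
conditional. Defaults: 4000 iterations, 1000 burn-in; a seed is mandatory
and identical seed + settings reproduce results bitwise. Per-parameter
effective sample sizes are computed (arviz); a minimum ESS below 100 sets
an explicit non-convergence flag in the results and summary — never
silent. If a conditional precision matrix is numerically non-positive
(possible when a basis function has no data support), a 10⁻⁸ jitter is
added to its diagonal.

Correctness is defined by oracle equivalence, not by any particular
approximation: the test suite compares `fit` against dense quadrature
(1-2 free parameters) and long-run adaptive random-walk Metropolis
references (including a joint reference over the constrained spatial field
and log τ² under the IG hyperprior) on five small instances, requiring
agreement of posterior means and 95% quantiles within three times the
combined Monte Carlo standard errors.

**DIC.** D̄ is the mean deviance over retained draws; D̂ is the deviance at
the posterior mean of the *linear predictor* η (not of the parameters) —
well defined under the constraints and standard for latent Gaussian
models, but a choice on which DIC variants differ, hence stated here.
pD = D̄ − D̂ and DIC = D̄ + pD = D̂ + 2pD. Ties in model comparison are
broken by smaller pD.

**Odds ratios.** The reported OR "mean" is the posterior mean of the
exponentiated coefficient draws (quantiles commute with exp; the mean does
not, so draws are required). Reference levels are printed as 1/1/1.

**Significance maps.** A region is "higher" when the 95% credible interval
of its spatial effect lies above 0, "lower" when below, otherwise not
significant — judged on the logit scale, which is equivalent to
thresholding the OR interval at 1. The package exports the classification
as a CSV joinable to any shapefile; map rendering is out of scope.

## Synthetic data generator

The generator emulates a DHS-like women's survey: a rook-lattice region
graph (default 6×6 = 36 regions, standing in for the real 37-unit state
adjacency, which users can supply as a plain-text neighbour list), clusters
nested in regions (default 8 per region), households of 1-3 eligible women
(probabilities .75/.20/.05, matching the survey's ≈1.2 women per
household), categorical covariates drawn iid from the published 2018
marginals, ages drawn from the published age-group shares, age at first
birth from a truncated normal (mean 20, sd 4.5, capped at current age), and
ANC visits from a capped Poisson(4). Outcomes are Bernoulli draws from the
structured additive predictor with known truth:

* default fixed effects = the published all-women log posterior odds
  ratios; default intercept = log 2.242 (the published intercept OR);
* default age effect: an asymmetric Gaussian bump peaking at exactly 35
  (sd 10 rising, 4.5 falling — a smooth rise and drastic decline);
  age-at-first-birth: flat at zero below 20 then increasing (smoothed
  hinge, slope 0.05/yr); ANC visits: linear, 0.08/visit. All truth smooths
  are centred to mean zero over the sampled values;
* spatial field drawn from the sum-to-zero-constrained eigenexpansion of
  the ICAR prior (default τ² = 0.25), i.e. f = V₊ √(τ²/λ) z on the
  Laplacian eigenbasis with the null space removed — the intrinsic prior is
  improper and needs the constraint to define a sampling distribution;
  disconnected graphs are rejected with instructions to constrain per
  component;
* household/community effects iid normal, default sd 0.3 each (no
  magnitudes are published; small enough that fixed effects remain
  recoverable, large enough that M3 is detectably better than M2).

The five response indicators are generated consistently with the composite
outcome (sufficient ⇔ all five yes; insufficient rows get at least one no).

What the generator does **not** emulate: the survey's stratified two-stage
sampling and its weights (the analysis model is unweighted), real state
geography and heterogeneous region populations, item nonresponse patterns,
and any dependence of covariates on region beyond the spatial field.
Passing tests therefore demonstrate correctness of the estimator under the
model, not robustness to design features the generator omits.

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` run these studies at desk
scale (sizes are the package's own choices):

* **Descriptive reproduction** — tabulations re-derive the published
  percentages exactly from the published raw counts (including 59.2%
  sufficient knowledge). Since the published margins do not determine the
  joint distribution of the five answers among the insufficient, a
  consistent joint is reconstructed (staggered cyclic blocks, verified
  against every margin); any such joint yields identical tables.
* **Oracle equivalence** — five small instances (intercept-only; one
  binary covariate; spatial path with IG hyperprior; one 8-coefficient
  smooth; combined fixed + spatial) against quadrature/Metropolis
  references, 3× combined Monte Carlo SE.
* **Recovery and calibration** — fixed effects recovered within 3
  posterior sd at n = 2000; 95% intervals cover the truth 90-99% of the
  time over 100 replicates (observed ≈ 96%).
* **Smooth recovery** — fitted age curve peaks within ±3 years of the
  simulated peak 35 at n = 20,000.
* **Spatial recovery** — a region with true effect +1 is classified
  "higher" in ≥90% of 20 replicates at n = 10,000 (observed 100%).
* **DIC ladder** — with full structure in the truth, DIC orders
  M3 < M2 < M1 in a majority of 20 replicates at n = 1500.

The acceptance script uses 30/10/10 replicates for the
coverage/spatial/DIC studies and reports each quantity with the problem
size used.

## Known limitations

* Survey weights and the two-stage design are not modelled; estimates are
  model-based for the unweighted sample.
* DIC is the only model-comparison criterion (no WAIC/LOO).
* The ICAR field requires a connected graph in the generator (the improper
  prior needs one constraint per component to define a sampling
  distribution, and the generator refuses rather than guess). The *model*
  does handle disconnected graphs: one sum-to-zero constraint per
  connected component, and isolated regions get an independent zero-mean
  normal effect with variance τ².
* Empty or separated factor levels yield honestly diffuse posteriors under
  the vague prior; their OR summaries can be extreme and should be read
  with the interval, not the mean.
* pD (and hence DIC) can in principle be negative for badly misspecified
  models; it is reported as computed.
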