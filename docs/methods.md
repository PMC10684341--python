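# Methods

This note documents the statistical machinery implemented in `beebrains`,
its assumptions, defaults, and the design choices made where more than one
defensible option existed.

## The scientific question

Across bee species, does tolerance of human-altered habitats — urban
environments in particular — covary with brain investment?  The cognitive
buffer hypothesis predicts that species with larger brains *relative to
their body size* cope better with novel environments.  Testing this
comparatively requires four ingredients, each implemented as a module:

1. a species phylogeny and its covariance structure (`phylo`);
2. a body-size-corrected brain measure (`allometry`);
3. a per-species, per-habitat occupancy score that controls for how common
   each species and habitat are (`occupancy`);
4. comparative models that respect shared ancestry (`models`).

A synthetic-data generator (`simulate`) emulates the joint structure of
these data so the full pipeline (`pipeline`) can be exercised and validated
without any external download.

## Phylogenetic covariance and Pagel's lambda

For a rooted tree with branch lengths, the Brownian-motion covariance
between tips i and j is the depth of their most recent common ancestor
(shared root-to-tip path length); the diagonal holds root-to-tip distances.
Pagel's lambda multiplies the off-diagonal entries by `lam` in [0, 1] and
keeps the diagonal fixed — the convention used by trait-signal estimators
(`phytools::phylosig`-style).  For `0 <= lam <= 1` the transform stays
positive semi-definite because it equals `lam * V` plus a non-negative
diagonal.  Zero-length edges and multifurcations are accepted as-is.
Pruning reroots at the survivors' most recent common ancestor (the `ape
drop.tip` convention); the stem above it becomes a root edge that the
covariance excludes.

## Allometry: PGLS with maximum-likelihood lambda

Brain mass scales allometrically with body size, so relative brain size is
the residual of the log-log regression

    ln(brain) = b0 + b1 * ln(ITD) + e,    e ~ MVN(0, sigma2 * V(lambda))

Specimen measurements are log-transformed first and averaged within species
(log-then-average is variance-stabilizing for mass-like measurements; the
alternative order is a documented open choice).  Coefficients and `sigma2`
have closed-form profiles, leaving a one-dimensional likelihood in lambda
that is maximized on [0, 1] by a 51-point grid scan plus bounded Brent
refinement (tolerance 1e-10); endpoint estimates are reported as boundary
values.  On ultrametric trees a single eigendecomposition of V makes each
profile evaluation an O(n) solve; otherwise each evaluation refactorizes.
`r2` is the GLS variance explained under the fitted `V(lambda)`, i.e.
`1 - WRSS/WTSS` against the intercept-only GLS model — the deterministic
analogue of a Bayesian R² for this model.  The fit is by maximum
likelihood rather than MCMC: the quantities consumed downstream are point
estimates and residuals, and ML makes them reproducible and directly
testable (GLS normal equations hold at the optimum to < 1e-6).

## Habitat occupancy: fixed-margin null model

Occurrence records are filtered to collection years 1990-2022 (inclusive)
and coordinates with at least two decimal places.  Decimal places are
counted on the *textual* coordinate when available, because trailing zeros
are invisible in floats; the fallback is the shortest round-trip rendering
of the numeric value.  Records are assigned the habitat class (natural /
agricultural / urban) of the land-cover cell containing them; cells are
half-open `[lower, upper)` intervals in both axes with row 0 at the
minimum-latitude edge, so boundary points are assigned deterministically.
Species with fewer than 50 total records are dropped.

The species x habitat count matrix is scored against randomized matrices
with identical row and column sums, drawn from the conditional distribution
of independent counts given the margins,

    P(T) ∝ prod_i r_i! prod_j c_j! / (N! prod_ij t_ij!)

— the distribution targeted by Patefield's algorithm (AS 159, R's
`r2dtable`).  The sampler fills rows sequentially with multivariate
hypergeometric draws from the remaining column totals, which realizes
exactly this distribution; tests verify it against brute-force enumeration
of all margin-consistent tables and against an independent random-pairing
construction.  Internally rows and columns are put in a canonical order
before sampling so that permuting the input permutes the scores exactly.

The percentile of a cell is the percentage of simulated counts *strictly
below* the observed one (ties count as not-below; a half-tie policy is
available as `ties="half"`).  Classification is strict: percentile > 80 is
"high", < 20 is "low", boundary values are intermediate.  The default
number of randomized matrices is 10 000.

## Phylogenetic signal

Signal in a continuous trait is estimated by the same profile-lambda
machinery with an intercept-only design, and `lambda = 0` is tested by
likelihood ratio.  Three p-value references are offered:

- `chisq1` (default): chi-square(1).  Conservative, because the null pins
  lambda to the boundary of its parameter space.
- `mixture`: the asymptotic boundary law (50:50 point mass at zero and
  chi-square(1)).  Still only asymptotic — on unit-depth trees of a few
  hundred tips the point mass at zero is considerably larger than 0.5
  because lambda is weakly identified.
- `bootstrap`: a parametric-bootstrap Monte Carlo p-value.  Traits are
  simulated from the fitted lambda = 0 model, the LR statistic is
  recomputed for each, and the randomized rank of the observed statistic
  among the simulated ones is returned.  Ties (the atom at LR = 0) are
  broken uniformly at random, which makes this p-value *exactly* uniform
  under the null — the property the calibration study verifies.

## Phylogenetic logistic regression

The binary high/low occupancy class of each habitat is regressed on a
species-level predictor with a phylogenetically correlated random effect:

    logit P(y_i = 1) = b0 + b1 * x_i + u_i,   u ~ MVN(0, sigma2 * C)

where `C` is the phylogenetic covariance scaled to unit mean diagonal (so
estimates are invariant to the covariance's overall scale, which `sigma2`
absorbs).  Fitting is Laplace-approximated maximum likelihood: an inner
penalized IRLS (with step-halving) finds the joint mode of `(b, u)` at each
candidate `sigma2`, and the outer profile over `log sigma2` is maximized on
a bounded interval with the `sigma2 = 0` boundary (plain logistic
regression) always a candidate.  Standard errors come from the marginal
working information `X' (W^-1 + sigma2 C)^-1 X`; the reported
`r2_analogue` is the latent-scale variance partition
`var(Xb) / (var(Xb) + sigma2 + pi^2/3)`.  This is the deterministic
counterpart of the Bayesian mixed model the design emulates, whose
estimand is the same posterior mode; MCMC settings are provenance only.

Only the extremes are modelled (high vs low; intermediate species are
excluded): the occupancy-degree distribution is strongly 0-1 inflated, so
the extremes carry essentially all the information and the binary model
avoids parametric assumptions about the thin middle.  Because the
thresholded outcome can be near-separated when the underlying coupling is
strong, the *pipeline* fits use a weakly informative normal prior
(sd = 5, i.e. ridge 1/25) on the coefficients — the Laplace counterpart of
the weakly informative priors conventional for Bayesian versions of this
model.  `phylo_logistic_fit` itself defaults to no prior (pure ML) and
raises a separation error with advice if the slope diverges.

## Diet check

Differences in a continuous measure between two groups (e.g. oligolectic
vs polylectic species) use the two-sided Wilcoxon rank-sum test with
midranks for ties: exhaustive enumeration of rank assignments for
`n_a + n_b <= 12`, otherwise the normal approximation with tie correction
and a continuity correction clamped at the mean (identical groups give
p = 1 exactly; exact and approximate p-values agree within 0.02 at
`n_a = n_b = 6`).

## Synthetic-data generator

The generator's defaults encode the study conditions the pipeline targets:

- **Tree**: Yule (or birth-death) tree, ultrametric, scaled to unit depth;
  around 150 species.
- **Traits**: ln body size by Brownian motion (root 0.7 ≈ ln 2 mm ITD, tip
  sd 0.4); ln brain mass with intercept -3.0, slope 2.5 and residuals of
  sd 0.33 with lambda 0.6 — giving a strong allometry (R² ≈ 0.9 analogue)
  with moderately heritable deviations, the regime the method is built
  for.  One specimen per species by default (intraspecific variation is
  small relative to interspecific variation in this setting).
- **Records**: per-species counts negative-binomial (mean 120, dispersion
  5; GBIF-style overdispersion), floored at 50 unless the min-records
  filter itself is under test; years uniform in 1990-2022; coordinates
  printed at 4 decimals so the precision filter passes by construction.
- **Habitat coupling**: class probabilities are a softmax of the grid
  mixture log-odds (natural 0.5, agricultural 0.3, urban 0.2 — urban
  rarest) with `gamma * residual` added to the urban component only,
  implementing the urban-specific hypothesis; `gamma = 0` is the matched
  null scenario.  Records land uniformly in a uniformly chosen cell of
  their class.

Everything is deterministic per seed; the scenario seed is split into
independent substreams (tree, traits, grid, records) via `SeedSequence`,
so stages can be re-run in isolation.

What the generator does *not* emulate: spatially autocorrelated sampling
effort, observer bias, coordinate error, taxonomic misidentification, and
range edges.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness of the
biological conclusion to those real-data complications.

## Validation studies and problem sizes

`beebrains.evaluation` re-simulates data under known truth and measures
recovery; `scripts/acceptance.py` runs the same studies end to end.  The
sizes used are: sampler exactness on all enumerable tables at N = 10-12
(1e5-2e5 draws); PGLS and signal recovery with 100 replicates on 200-tip
trees; logistic recovery and null calibration with 100 replicates at
n = 200; end-to-end directionality over 50 seeds at 150 species with 1000
randomized matrices per run (the null model's default remains 10 000; the
replicate studies use 1000, which changes percentile Monte Carlo error
from ±0.5 to ±1.6 points and nothing else).  Null-calibration uniformity
uses 99 bootstrap draws per replicate.

## Known limitations

- The lambda LR test's default chi-square(1) reference is conservative at
  the boundary; use the bootstrap reference when calibrated p-values
  matter.
- The Laplace approximation biases `sigma2` downward for binary data at
  these sample sizes (often to 0 when the true value is modest); slope
  estimates remain approximately unbiased, which is what the recovery
  study checks.
- Percentiles from a finite simulation are granular (1/n_sim); boundary
  classifications near 20/80 can flip between seeds at small `n_sim`.
- The edge-of-range exclusion present in the motivating study design has
  no reproducible rule and is supported only as a user-supplied exclusion
  list.
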