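# beebrains

Phylogenetic comparative analysis linking bees' relative brain size to
their degree of occupancy of natural, agricultural and urban habitats.

Not every pollinator suffers equally from land-use change: some bee
species persist or even thrive in cities.  The cognitive buffer hypothesis
proposes that enlarged brains buy the behavioural plasticity needed to
exploit novel environments.  `beebrains` implements the comparative
pipeline for testing that idea at the species level:

1. **Relative brain size** — residuals of a log-log phylogenetic
   generalized least squares (PGLS) regression of brain mass (mg) on
   intertegular span (mm), with Pagel's λ estimated by maximum
   likelihood: `ln(brain) = β₀ + β₁ ln(ITD) + ε`,
   `ε ~ MVN(0, σ²V(λ))`.
2. **Degree of habitat occupancy** — georeferenced occurrence records are
   filtered (years 1990–2022, ≥ 2 coordinate decimals, ≥ 50 records per
   species), assigned a land-cover class (natural / agricultural /
   urban), and tabulated into a species × habitat count matrix.  Each
   cell is scored against 10 000 randomized matrices with identical row
   and column sums (Patefield's algorithm / `r2dtable` semantics): the
   percentile is the share of simulated counts strictly below the
   observed one; > 80 is *high* occupancy, < 20 is *low*.
3. **Comparative models** — Pagel's λ phylogenetic signal with a
   likelihood-ratio test (chi-square, boundary-mixture or
   parametric-bootstrap reference); a phylogenetic Bernoulli regression
   of the high/low class on relative brain size,
   `logit P(high) = β₀ + β₁x + u`, `u ~ MVN(0, σ²C)`, fitted by
   Laplace-approximated maximum likelihood; and a Wilcoxon rank-sum check
   for diet confounding.
4. **Synthetic data** — a generator producing birth–death trees,
   Brownian-motion traits with a controlled allometric slope and λ, and
   multinomial occurrence records over a synthetic habitat grid, with a
   coupling parameter γ that shifts each species' urban log-odds by
   γ × (allometric residual).  It defines the study conditions under
   which every estimator is validated.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Run the full pipeline on a synthetic scenario in which large-brained
species are pulled toward urban habitats (γ = 1.5):

```python
from beebrains import PipelineConfig, ScenarioConfig, run_pipeline

config = PipelineConfig(
    scenario=ScenarioConfig(n_species=150, gamma=1.5, seed=1),
    n_sim=1000,
    seed=1,
)
report = run_pipeline(config, out_dir="demo")
```

This prints (via the report fields) the following on seed 1:

```
allometry: slope=2.590  lambda=0.446  R2=0.827
signal(relative brain size): lambda=0.446  p=0.0003
occupancy natural      low= 48  intermediate= 64  high= 38
occupancy agricultural low= 45  intermediate= 69  high= 36
occupancy urban        low= 58  intermediate= 40  high= 52
logistic natural      beta1=-8.101 (se 1.602)  sigma2=1.484  R2~=0.599
logistic agricultural beta1=-5.647 (se 1.305)  sigma2=0.000  R2~=0.482
logistic urban        beta1=+11.607 (se 2.059)  sigma2=0.000  R2~=0.802
```

Reading the output: the PGLS recovers the generating allometric slope
(2.5) and detects phylogenetic signal in the residuals; the null model
classifies most species as high or low in each habitat (the 0–1-inflated
pattern typical of these scores); and the phylogenetic logistic
regressions recover the built-in directionality — a strongly positive
urban slope (species with relatively larger brains occupy cities) with
negative slopes for natural and agricultural habitats.  The same analysis
is available from the shell:

```bash
beebrains run --seed 1 --out-dir demo          # scenario defaults
beebrains simulate --n-species 150 --seed 1 --out-dir bundle
beebrains occupancy --records bundle/records.csv --grid bundle/grid \
    --n-sim 10000 --seed 1 --out occupancy.csv
```

Real data plug in the same way: a Newick tree, a specimen CSV
(`species,brain_mg,itd_mm[,region]`), an occurrence CSV (GBIF simple-CSV
column names accepted) and a land-cover grid directory, referenced from a
YAML config passed to `beebrains run --config`.

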