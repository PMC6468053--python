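# indivnet

Individual-resource network analysis for within-population diet studies.

When the diet of every captured animal in a population is recorded as the
occurrence of food-item categories (from fecal samples, gut contents,
etc.), the population can be analysed as a bipartite network: individual
consumers on one side, food-item categories on the other, a link wherever
an individual's sample contained an item.  The structure of that network —
whether specialists eat nested subsets of generalists' diets, or whether
the population splits into modules of individuals specialised on distinct
resource sets — reveals how individual diet specialization responds to
resource availability and habitat structure.  `indivnet` provides the full
chain for such studies, built for highly seasonal systems (its synthetic
study design mirrors a 4-site x 2-season small-mammal trapping campaign):

* **Matrix construction** — parse long-format diet-occurrence records,
  retain one sample per individual per season for statistical
  independence, and build labelled binary incidence matrices.
* **Network metrics** — connectance `C = L/(I·R)`; per-individual degree
  distribution; Chao1 richness coverage of the food-item inventory;
  **nestedness** by matrix temperature `T` ∈ [0, 100] (isocline
  construction of Rodríguez-Gironés & Santamaría, minimized over row and
  column orderings; reported both as `T` and as `N = (100 − T)/100`); and
  **modularity** `Q = Σ_c (e_c/L − (d_c/2L)²)` by fast-greedy
  agglomerative maximization (Newman–Girvan) on the bipartite graph
  treated as unipartite.
* **Null models** — Erdős–Rényi ensembles (independent links with p = 0.5,
  or exact observed connectance), two-sided Monte-Carlo p-values with the
  plus-one correction, and standardized effect sizes
  `SES = (Metric_obs − mean(Metric_sim)) / sd(Metric_sim)`, read against
  the ±2 normal-approximation band.
* **Environmental predictors** — exponential Shannon diversity exp(H′) of
  arthropod dry mass across orders, total dry mass, log-transformed fruit
  counts, and PC1/PC2 of eight Z-scored habitat-structure variables; each
  network metric is regressed on each predictor by simple OLS, with a
  Spearman collinearity screen.
* **Synthetic studies** — generative forms of the three classic models of
  individual diet specialization (shared preference, distinct preference,
  competitive refuge), plus matched seasonal resource and habitat
  covariates, so the whole pipeline is testable end to end without field
  data.

## Worked example

Simulate a dense population under the competitive-refuge model (shared
core of 5 items, 3 alternative-resource groups), describe its network, and
test modularity against 1,000 Erdős–Rényi matrices:

```python
from indivnet import (DietModelParams, simulate_competitive_refuge,
                      compute_network_metrics, metric_evaluator, monte_carlo_test)

params = DietModelParams(model="competitive_refuge", n_individuals=40,
                         n_resources=20, density=0.9, core_size=5,
                         n_groups=3, noise=0.05, seed=7)
m = simulate_competitive_refuge(params)
nm = compute_network_metrics(m, seed=1, effort="thorough")
fn = metric_evaluator("modularity")
res = monte_carlo_test(nm.modularity, fn, m, n_sim=1000, seed=2,
                       metric_name="modularity")
```

which prints (via the obvious f-strings):

```
matrix: 40 individuals x 20 items, 373 links
connectance     C = 0.466
temperature     T = 44.63
nestedness      N = 0.554
modularity      Q = 0.268  (3 modules)
Chao1 coverage    = 1.00
modularity null:  p = 0.0020, SES = 13.84 (null mean 0.140, sd 0.009)
```

Read: the fast-greedy algorithm recovers the three planted consumer
groups; observed modularity (0.268) sits ~14 null standard deviations
above the Erdős–Rényi mean (0.140), so the network is far more modular
than chance (SES ≫ 2, Monte-Carlo p = 2/1001).  Chao1 coverage of 1.00
says no food item was seen only once, i.e. the item inventory is judged
complete.

The same analyses are available from the shell:

```sh
indivnet simulate --model competitive_refuge --n 40 --resources 20 \
    --density 0.9 --seed 7 --out matrix.csv --manifest run.json
indivnet metrics  --matrix matrix.csv --seed 1 --effort thorough --out metrics.json
indivnet nulltest --matrix matrix.csv --metric modularity --nsim 1000 \
    --seed 2 --out null.json
indivnet run --config study.yaml --out report/   # full multi-site study
```

A minimal `study.yaml` for a fully synthetic 4-site x 2-season study:

```yaml
seed: 5
simulate:
  individuals_range: [27, 72]
  n_resources: 20
null:
  mode: bernoulli_half
  n_sim: 1000
  metrics: [nestedness, modularity]
metrics:
  effort: thorough
```

`indivnet run` writes `report.csv` (one row per site x season with all
metrics, p-values, SES and environmental predictors), `regressions.csv`
(one OLS fit per predictor x metric pair), `report.json` (everything plus
the run manifest) and `run.log`.  Reruns with the same configuration are
byte-identical.

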