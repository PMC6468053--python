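# Methods

This note documents the models and procedures implemented in `indivnet`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generators do and do not
emulate.

## Incidence matrices

The unit of analysis is a binary individuals x food-items matrix per
population (site) and season.  Interactions are *occurrences*: a cell is 1
if the individual's retained sample contained the item, regardless of how
many fragments were found.  Counts are deliberately not supported — with
fecal material, differential digestibility makes counts unreliable while
occurrence is robust.

**One sample per individual per season.**  Individuals recaptured within a
season would otherwise contribute correlated rows.  A capture event is the
set of records sharing (individual, site, season, capture date); the
retained event is the one with the earliest date, dated events taking
precedence over undated ones and remaining ties resolving by input order.
Undated records of the same individual and season cannot be told apart and
are treated as one event.  The rule is configurable (`first` | `union`);
`first` is the default.  The same individual appearing in both seasons
contributes one independent row to each seasonal network, since seasons
are analysed separately.

After construction, matrices contain no all-zero rows or columns by
definition; matrices read from CSV are validated cell-by-cell (binary
values, unique labels) and pruned explicitly.

## Nestedness: matrix temperature

Nestedness is quantified as matrix temperature `T` on a 0–100 scale
(0 = perfectly nested), reported alongside the headline rescaling
`N = (100 − T)/100`.

For a given row/column ordering (generalist rows at the top, widely used
items at the left) each cell center maps into the unit square, and the
isocline of perfect nestedness for the observed fill φ is the curve
`(1−x)^p + (1−y)^p = 1`, with `p` solved from
`φ = 1 − Γ(1+1/p)² / Γ(1+2/p)` (the closed form of the area condition;
solved by bracketed root-finding on log p to ~1e−12, well inside the 1e−4
relative-error target).  Each presence beyond the isocline and each
absence within it scores `u = (d/D)²`, where `d` is the distance from the
cell to the isocline along the cell's 45° diagonal and `D` that diagonal's
length inside the square.  The temperature of the ordering is
`100 · Σu/(mn) / 0.04145`, clamped to [0, 100] (the constant is the
classical maximum expected unexpectedness; small matrices can exceed it,
hence the clamp).

Two deliberate refinements:

* **Discrete-violation gate.**  A wrong-side cell only scores if it also
  violates nestedness discretely — a presence with at least one absence in
  its upper-left rectangle, or an absence with at least one presence in
  its lower-right rectangle.  A smooth isocline cannot pass exactly along
  a staircase boundary, so without this gate a perfectly nested matrix
  would score a small positive temperature.  With it, `T = 0` holds
  *exactly* for every matrix whose packed form is a staircase, which is
  the defining property of the scale.  On disordered matrices the gate is
  almost always satisfied by wrong-side cells, so scores match the
  classical construction (validated in development against an independent
  implementation of the same isocline geometry at cell-level agreement
  ~1e−5).
* **Minimization over orderings.**  The reported `T` is the minimum over
  row/column orderings.  Matrices with `rows! · cols! ≤ 20,000` are solved
  exhaustively.  Larger ones use a canonical degree-sorted start (ties
  refined by iterated neighbor-color multisets, so the start — and hence
  the result — is invariant to the input row/column order) followed by
  seeded swap hill-climbing with restarts.  Effort presets: `fast`
  (2 restarts, 30 iterations per node) for null ensembles, `thorough`
  (8 restarts, 150 per node) for observed matrices.  The search is a
  heuristic: reported temperatures are upper bounds on the true minimum,
  which is the correct conservative direction (overestimating T
  understates nestedness).  On 4x4 matrices the search provably equals the
  exhaustive minimum (tested over 500 random cases).

## Modularity: fast greedy

Modularity uses the Newman–Girvan quality
`Q = Σ_c (e_c/L − (d_c/2L)²)` on the bipartite graph treated as an
ordinary unipartite graph (individuals ∪ items as nodes, interactions as
edges) — no one-mode projection.  The agglomerative search starts from
singleton modules, repeatedly merges the connected pair with the largest
ΔQ, and returns the partition with maximum Q along the merge path.  Exact
ties in ΔQ resolve by the lowest (module id, module id) pair
(`tie_rule="lex"`, configurable to `revlex`), making results fully
deterministic.  Greedy Q is a lower bound on the optimum; tests verify it
never exceeds the exhaustive-partition maximum on small graphs and that it
recovers exact optima on cleanly separated blocks.  An independent
fast-greedy implementation (igraph) agrees closely, with small per-graph
differences attributable to tie-cascade order.

## Null models, Monte-Carlo p, SES

Default null: `bernoulli_half` — every individual-item link present
independently with probability 0.5, matrix size matched to the observed
network.  The alternative `match_connectance` places exactly
`round(C_obs · I · R)` links uniformly at random.  Both are exposed
because size-matched 50% links and connectance-matched fills answer
slightly different questions; the pipeline records which was used.

Significance is a two-sided Monte-Carlo test with the plus-one
correction: `p = min(1, 2·min(p_low, p_high))`,
`p_high = (#{sim ≥ obs}+1)/(n_sim+1)` and symmetrically for `p_low`;
nominal level 5%.  When the observed network is itself a draw from the
null, exchangeability makes the test exactly calibrated up to the
discreteness of `n_sim` — the acceptance script measures the empirical
type-I error at 200 observed networks x 500 replicates.

The standardized effect size `SES = (obs − mean(null))/sd(null)` uses the
sample (n−1) standard deviation.  Under the null, SES is approximately
standard normal, so ~95% of null SES values fall in [−2, 2] (measured at
300 x 500 in the acceptance script); |SES| > 2 is read as a significant
departure.  Degenerate draws are handled per metric: temperature prunes
empty rows/columns and rejects sub-2x2 remnants; modularity rejects
edgeless draws; rejected draws are redrawn (counts logged in the result).
At the default 30x20–70x20 sizes, degenerate draws are vanishingly rare.

## Environmental predictors and regressions

* **Arthropod diversity**: `exp(H′)` with proportions from dry mass per
  order (masses recorded to 0.0001 g); equals the effective number of
  equally common orders, between 1 and the number of orders.
* **Fruit abundance**: `log10(count + 1)`; the offset keeps zero counts
  defined, and natural log is available (`base="ln"`).  The log base only
  rescales regression slopes, not their p-values.
* **Habitat structure**: one PCA over all stations pooled across sites and
  seasons (per-season PCAs would not give common axes for the
  regressions).  Variables are Z-scored, the correlation matrix is
  eigen-decomposed, and each axis's sign is fixed so its
  largest-magnitude loading is positive, making gradient directions
  reproducible.  Predictors are the mean PC1/PC2 station scores per
  site x season.
* **Regressions**: simple OLS per (predictor, metric) pair with two-sided
  p for the slope; p < 0.05 marks a reportable trend.  With 8 site x
  season points these tests have little power and the two seasonal
  observations per site are not strictly independent — results carry `n`
  so users see the limitation; no mixed model is layered on top.
  Connectance is computed but not regressed by default (it is strongly
  negatively rank-correlated with modularity; a flag re-enables it).
* **Collinearity screen**: pairwise Spearman rho with p ≤ 0.1 flagging.

## Synthetic data: what it emulates, and what it does not

The three diet-specialization models are described verbally in the
literature; the generators give them one explicit parameterization each
(every choice recorded in the manifest):

* **Shared preference** — one global resource ranking; individual i
  consumes the top `b_i` items, `b_i` uniform on a stated breadth range.
  Perfectly nested by construction at zero noise.
* **Distinct preference** — private independent rankings; breadth
  `b = round(b_min + density·(b_max − b_min))` grows with density, so
  specialization is strongest in sparse populations and dissolves as
  competition widens diets.
* **Competitive refuge** — a shared core of `core_size` top items consumed
  by everyone, the remaining items split into `n_groups` disjoint
  alternative sets; each individual consumes a `density` fraction of its
  group's alternatives.  Modular structure strengthens with density.

`density` is an abstract [0, 1] forager-density proxy, not an estimated
animal density.  Observation noise is a symmetric bit-flip with
probability `noise` (default 0.05 — a few percent misreads, comparable to
occasional misidentified fragments); rows or columns left empty by noise
or by low density are pruned.  Default sizes mirror the empirical setting:
27–72 individuals, 20 food items, 4 sites x 2 seasons.

The environment generator produces lognormal arthropod masses per order
(warm-wet seasons more even — sd 0.6 vs 1.4 on the log scale — and
heavier), negative-binomial fruit counts (warm-wet mean 600 vs 150,
dispersion 5), and habitat stations (57–78 per site x season) from a
stated 8x2 factor-loading matrix — a vegetation-density factor shifted by
+1 between seasons and a tree-spacing factor that varies by site.  The
full-study generator ties diet-model density to season (0.3 cool-dry, 0.9
warm-wet), which under the competitive-refuge default reproduces the
qualitative seasonal contrast of interest: warm-wet networks more modular
relative to chance.

What the generators do *not* emulate: detection biases of fecal analysis,
spatial structure within grids, individual covariates (sex, age, body
mass), temporal autocorrelation within a season, and any coupling between
the resource-availability tables and the simulated diets beyond the
season-density link.  Passing tests therefore demonstrate that the
*analysis chain* behaves correctly and that the stated constructions carry
their intended signatures — not that real populations follow these models.

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; study runs derive child seeds from a single
manifest seed, and a rerun with the same configuration is byte-identical.
The acceptance script uses 200 observed networks x 500 null replicates
(type-I error) and 300 x 500 (SES coverage) at 30x20 — sizes chosen so
binomial noise sits well below the quantities' interpretation bands while
a single-CPU run finishes in minutes.  The test suite uses smaller
replicate counts for the same checks plus exhaustive enumeration
(orderings for temperature, set partitions for modularity) as independent
oracles on small instances.

## Known limitations

* Temperature is a heuristic minimum beyond the exhaustive regime; effort
  presets trade accuracy for speed in null ensembles.
* The `bernoulli_half` null fixes link probability at 50% regardless of
  observed fill; for sparse networks its temperature/modularity baselines
  sit far from the data, which inflates |SES|.  This matches the stated
  null definition; `match_connectance` is available when a fill-matched
  baseline is wanted.
* Chao1 uses the classic singleton/doubleton form with the bias-corrected
  additive term when doubletons are absent.
* Degree distributions are computed per matrix row (one retained sample
  per individual-season), not per capture.
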