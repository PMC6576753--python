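# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the limits of what the package's tests demonstrate.

## Data model and spatial conventions

The analysis operates on a regular grid of square cells in planar km
coordinates; coordinates are cell centroids and "north" is larger `y`.
Cells with less than 70% of their area inside the study region are
excluded (boundary inclusive: exactly 70% is retained). The invaded-region
domain is further clipped 200 km north of the northernmost presence of the
focal species; the native-region domain is the convex hull of the native
presences (boundary-inclusive point-in-polygon via shapely). Dates are
plain integers — simulation steps, or day ordinals when ISO dates are
read — because only their ordering matters.

Predictor columns carry one of three tags: `environmental`, `anthropic`,
or `distance_to_first_record`. The last is recomputed per species as the
Euclidean distance to the cell of the earliest dated record (ties at the
earliest date break to the lowest cell id, deterministically).

## Scenarios

* `INVADED`: environmental + distance-to-first-record columns; invaded
  training records only.
* `NATIVE`: environmental columns only; training rows are all native
  presences (plus an equal number of native pseudo-absences) together with
  the invaded training presences and their pseudo-absences. Anthropic
  columns are excluded by construction — human-activity layers tend to
  associate negatively with a species in its native range and positively
  in its invaded range, so pooling them across regions is incoherent.
* `MIXED`: environmental + anthropic + distance-to-first-record.

All scenarios are evaluated on the same invaded-region test split, so
their effect sizes are directly comparable. (Whether native-trained models
should ever be scored on native data is moot here: the question the
framework answers is transferability into the invaded range.)

## Training/testing design

Records are split temporally: the oldest `round(0.7 n)` (half-up rounding)
train, the rest test; records tied at the boundary date are ordered by
cell id. Training pseudo-absences are drawn uniformly from cells without a
focal presence, as many as there are training presences (prevalence 0.5 by
design). An optional `pool="sampled"` restricts the pseudo-absence pool to
cells covered by related-native records; the default is the unrestricted
pool, with the related-native coverage reported as a sampling-effort
diagnostic rather than folded into the model.

Test pseudo-absences are bias-corrected. The sorting-bias diagnostic is
`ratio = d_p / d_a`, where `d_p` (`d_a`) is the mean distance from each
test presence (test absence) to its nearest training presence; expanding
invasions give ratios well below 1, which inflates apparent accuracy.
Pairwise distance sampling fixes this: candidates are drawn (pool size
10 × the number of test presences, excluding presence cells and training
pseudo-absence cells), and each test presence with nearest-training
distance `d_f` is greedily paired — in order of increasing `d_f` — with an
unused candidate whose distance `d_s` satisfies `|d_s − d_f| ≤ 0.33 d_f`,
taking the closest admissible candidate (ties to the lowest index).
Unmatched presences are dropped from the test set and counted. The 0.33
relative band and the greedy order follow the convention of the dismo
implementation of the method; both are configurable.

## Collinearity

`VIF_j = 1/(1 − R²_j)` with `R²_j` from an explicit least-squares
regression of column `j` on all other retained columns (with intercept).
Elimination is iterative-greedy: while any VIF exceeds 10, remove the
worst column and recompute. `R² ≥ 1 − 1e−10` is treated as infinite VIF,
so exact duplicates and linear combinations are always removed;
zero-variance columns are dropped first. The procedure is idempotent and
is applied per scenario to the assembled training matrix.

## Algorithms

All learners share one estimator contract (scikit-learn `BaseEstimator`
subclasses): `fit(X, y)` with binary `y`, `predict_suitability(X)` in
[0, 1], `get_params`/`set_params`, fitted attributes with trailing
underscores. Defaults:

| algorithm | implementation | key defaults |
|---|---|---|
| GLM | unpenalized logistic regression on linear + per-feature quadratic terms | — |
| GAM | logistic regression on per-feature cubic B-spline bases | 5 knots, mild L2 (C = 1) |
| BRT | gradient-boosted trees | learning rate 0.01, depth 3, ≤1000 trees, early stopping on a 20% internal holdout |
| RF | random forest | 500 trees |
| MAXENT | L1-penalized logistic regression on linear + quadratic features | C = 1 |

The MAXENT entry is the penalized-likelihood formulation equivalent to
maximum-entropy presence/background modelling with linear + quadratic
feature classes; it is an approximation of the Java implementation and is
documented as such.

Two deliberate contract choices:

* **Failure is a first-class outcome.** `fit` returns a status rather than
  raising on non-convergence, so the permutation engine can count failures
  (boosted-tree nulls are the classic casualty). A null distribution with
  more than 50% failed fits is declared void.
* **Row-order invariance.** Training rows are sorted into a canonical
  order (by response, then lexicographically by features) inside `fit`, so
  the bootstrap/subsampling learners give identical seeded predictions
  under any permutation of the training rows.

The ensemble is a convex combination: members are scored on an internal
20% stratified holdout of the training rows (TSS at the training-chosen
threshold, truncated below at 0, averaged with AUC), weights are the
normalized scores, members are refit on the full training data, and failed
members get weight 0. If every member scores 0 the survivors share equal
weights.

## Accuracy statistics and null models

TSS uses the rule `score ≥ threshold ⇒ presence`; the threshold maximizes
TSS on the training predictions (smallest score among exact ties) and is
then frozen for testing — choosing it on test data would leak. AUC is the
rank (Mann–Whitney) statistic with ties counted ½.

Null models refit the identical specification on permuted data: the rows
of the combined train + test predictor matrix are re-assigned to
observation rows by one random permutation per replicate, leaving the
response vector and the split membership untouched. Joint row permutation
preserves the inter-predictor correlation structure while destroying the
predictor–response and predictor–space association; per-column independent
permutation is available behind `mode="per_column"`. The null summary is
the 97.5th percentile (linear interpolation between order statistics, the
common type-7 rule), and effect sizes are
`TSSes = TSS_real − TSSnull_97.5`, `AUCes = AUC_real − AUCnull_97.5`,
with "better than null" meaning strictly positive. The default is 1,000
permutations per species × scenario × algorithm; the packaged demo uses 99
and the calibration studies 199 or 59, sizes chosen so that the full test
suite remains a coffee-break run on one CPU.

Calibration: with pure-noise suitability, an unbiased test set, and
exchangeable permutations, the real model exceeds its null 97.5th
percentile in ≈2.5% of replicates; the acceptance suite verifies this with
a 200-replicate binomial check and verifies that mean null AUC is 0.5.

## Comparison layer

`best_scenario_table` labels each species × algorithm × statistic with the
scenario of largest strictly positive effect size, `Null` when none is
positive, and exact ties joined with `=` (`Mixed=Native`), then reports
category shares.

`fit_performance_lmm` models one effect size (TSSes or AUCes) over the
models better than null on that statistic: fixed effects scenario (+
treatment coding, baseline `INVADED`), algorithm, scenario × algorithm,
N–S record span, number of presences, economic interest, and time since
introduction; random intercept per species (REML; plain OLS in the
degenerate single-species limit, where the random variance is 0). Numeric
covariates are z-scored before fitting — their raw units differ by orders
of magnitude — and the scaling is returned. Wald chi-squares are joint
tests of each term's coefficient block against the fitted fixed-effect
covariance; constant covariates and single-level factors are dropped and
reported, and rank-0 blocks raise an aliasing error naming the term.
Least-square means per scenario × algorithm cell set numeric covariates to
their (standardized) mean and average over the observed factor levels;
on a balanced design they reduce to raw cell means.

## Synthetic study system

The simulator emulates the statistical structure the analysis assumes,
not any particular geography:

* **Grid**: 40 × 50 cells of 5 × 5 km (2,000 cells) per region — small
  enough for 1,000-permutation nulls on a laptop, large enough for spatial
  structure. The outermost ring of cells gets partial area fractions so
  the validity filter is exercised.
* **Environmental layers**: Gaussian-kernel low-pass filtered white noise,
  standardized; correlation ranges 15–70 km across five layers. The two
  regions share layer names but are independent realizations.
* **Anthropic layers**: Euclidean distance to uniformly placed facilities
  (10 cities, 40 pet stores, 15 ports) plus a population-density field
  with a deliberately short 8 km correlation range — propagule pressure is
  patchy at near-cell scale, which is what makes driver attribution
  identifiable at all: a smooth anthropic field is indistinguishable from
  an incidental environmental gradient on a single landscape.
* **Invasion dynamics**: discrete steps; an uncolonized cell colonizes
  through two independent channels — diffusion with probability
  `logistic(β·x) · exp(−d/dispersal_scale)` (`d` = distance to the nearest
  colonized cell) and human-mediated jumps with probability
  `jump_rate · logistic(β_anthropic·x_anthropic)`. Coefficients apply to
  z-scored layers. The parent of a new colonist is its nearest colonized
  cell, so dates form a forest rooted at the introduction cell; the
  introduction cell is drawn from the top decile of generating
  suitability (establishment requires favourable conditions).
* **Driver regimes** (`make_truth`): `environmental` — β on environmental
  layers, diffusion-dominated (intercept −3, |β| up to 1.8, dispersal
  4.5 km, jump rate 0.001); `anthropic` — β on anthropic layers only
  (negative on distances, dominant positive on density), jump-dominated
  (intercept −2.5, effect 2.5, jump rate 0.03, dispersal 1 km); `mixed` —
  both at half strength. These settings yield 200–500 colonized cells in
  25 steps, i.e. presence counts in the tens-to-hundreds range typical of
  documented aquatic invaders, at realistic prevalence.
* **Observation**: each colonized cell is detected with probability
  `detection_prob × bias(cell)` (default 0.8; optional logistic
  accessibility bias declining with distance to the nearest city), dated
  at its colonization step. Related-native records cover a configurable
  fraction of cells (default 0.72). Native-range presences are Bernoulli
  draws from the environmental part of the truth.

Every generator is a pure function of configuration and seed; the pipeline
fans one master seed out by fixed offsets, making result CSVs
byte-identical across reruns.

What the simulator does **not** emulate: river-network topology (riparian
land-use is just another column), raster/GIS processing, observation
errors other than under-detection (no false presences, no positional
error), niche shifts between regions, temporal change in the layers, and
species interactions. Passing recovery tests therefore show the framework
is internally sound — it finds drivers it is pointed at and controls its
false-positive rate under its own assumptions — not that any real
species' spread is attributable from real data.

## Numerical and degenerate-input choices

* Smallest-threshold tie-break in TSS maximization; exact float equality
  defines effect-size ties in the best-scenario table.
* An essentially constant smoothed field (relative spread below 1e−8, the
  infinite-correlation-range limit) standardizes to the zero field rather
  than amplifying rounding noise.
* `dispersal_scale = 0` disables diffusion exactly; `jump_rate = 0`
  disables jumps; with both, only the introduction cell is ever colonized.
* Perfect collinearity: `R² ≥ 1 − 1e−10` ⇒ infinite VIF.
* The test pseudo-absence pool excludes training pseudo-absence cells (the
  alternative is defensible; the choice is logged).
* MixedLM falls back from the default optimizer to Powell on singular
  steps; boundary variance estimates are accepted.

## Known limitations

* Wald tests use the estimated fixed-effect covariance (no small-sample
  denominator-df correction); with few species the scenario test runs
  slightly liberal, which the 200-replicate calibration bounds.
* The ensemble weighting rule ("mean of truncated TSS and AUC on an
  internal 20% holdout, normalized") is one concrete reading of
  metric-weighted averaging; other SDM platforms weight differently.
* Pairwise distance sampling equalizes only the nearest-training-presence
  distance; residual spatial information (direction, local density)
  remains available to smooth predictors, so effect sizes are
  conservative but not perfectly immune to spatial leakage.
* The demo's mixed-model stage is skipped when too few models beat their
  nulls to support the design — expected at demo size.
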