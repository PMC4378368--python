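# Methods

## Data model

The analytical substrate is a subject × type × age tensor of non-negative
severity scores: for each subject, the severity of exposure to each of a
canonical set of 10 maltreatment types during each year of childhood
(ages 1–18, 1-based calendar years: `SexA_18` means exposure during the
18th year). Cells absent from an input file are *structurally absent* and
tracked separately from observed zeros; only observed cells can enter the
model. A (type, year) counts as "experienced" when severity > 0, matching
instruments whose items score 0 when unendorsed (the presence threshold is
configurable).

Three global exposure measures summarize each subject's history:
multiplicity (distinct types with any exposure), severity (summed severity
over all cells), duration (years with any exposure). They are computed from
the **full** matrix; the 5% prevalence filter applies to cell features
only, since the filter exists to stabilize per-cell estimates, not to
redefine a subject's overall burden. Multiplicity analyses group counts as
0, 1, 2, 3, 4-plus (`cap = 4`).

## Conditional inference trees and forests

The base learner separates *variable selection* from *split-point search*,
which is what removes the cardinality/scale bias of impurity-based trees:

- At each node, `mtry` candidate features are drawn (default ⌈√p⌉).
- For each candidate, the standardized linear association statistic
  between the feature's midranks and the response scores is computed:
  z = corr(h, g)·√(n−1), with h the feature midranks and g the response
  (class indicator for classification — equivalent to the rank-sum
  statistic — or response midranks for regression, a Spearman-type
  statistic). Midranks handle the heavy ties of ordinal severities; the
  asymptotic normal p-value is Bonferroni-adjusted over the candidates.
- If the smallest adjusted p ≥ `alpha_split` (default 0.05) the node
  becomes a leaf. Otherwise the winner (largest |z|; ties to the lowest
  canonical feature index) is split at the observed cutpoint maximizing the
  standardized two-sample statistic |S_L − E S_L|/sd(S_L), where S_L is the
  left-group response-score sum with permutation-null moments; ties go to
  the smallest cutpoint.

This rank-test formulation is a deliberately self-contained stand-in for
the full conditional-permutation-test framework of the conditional-tree
literature; it preserves the selection-unbiasedness property (verified
empirically: over 50 seeded datasets with 20 outcome-independent features
of 2–20 levels, the Spearman correlation between cardinality and mean
importance is small and non-significant).

Defaults: `n_trees` 500 (validation studies use 100), `min_node` 7 (a node
smaller than this is never split), `min_child` 3, subsampling without
replacement at fraction 0.632, `max_depth` 30 as a safety bound. Ordinal
severities are treated as numeric for splitting since they are ordered.

Candidate features are drawn by stateless hashed priorities per
(tree, node-path, feature), so candidate draws at one node do not depend on
the shape of the rest of the tree, and appending a new feature leaves the
priorities of existing features untouched. An appended feature can still
displace one existing candidate in the nodes where its priority wins —
under any fixed-size candidate draw this is unavoidable — so tree structure
is preserved exactly in all trees whose candidate sets the new feature
never enters.

Trees are stored as flat arrays and serialized to versioned JSON together
with config, seed and per-tree subsample indices.

## Permutation importance

importance(f) = mean over trees of (baseline metric − mean metric over
`n_permutations` permutations of column f), each tree evaluated on its own
out-of-subsample rows; accuracy for classification, negative squared error
for regression. A feature unused by a tree contributes exactly zero for
that tree; a constant feature has importance exactly zero. Default
`n_permutations` = 5 per feature per tree, a variance/cost compromise;
importances are averaged in raw degradation units, never rescaled.

## Cross-validation harness

Monte Carlo (leave-group-out) cross-validation: within each repeat,
`n_runs` random 75/25 splits, stratified on the outcome for binary
outcomes (optionally jointly on a stratum label). Stratification is not in
the source procedure's description but prevents empty-class training sets
at realistic case rates; proportions are preserved within ±1 subject.
Run-level test metrics (accuracy, Cohen's kappa, rank-sum ROC area with
ties counted ½; fraction of variance explained for regression) and
importances are averaged into repeat-level values; "mean ± value"
summaries are means and standard deviations over repeats. Full-data fit
summaries (sensitivity, specificity, kappa, and the predicted-risk odds
ratio with a Wald log-scale CI, Haldane–Anscombe 0.5 correction iff a cell
is zero) come from refitting on all rows.

## The sensitive-period decision

From the repeat-level importance matrix: the focal single cell is the cell
with the highest mean importance; the focal pair is the same-type
adjacent-age pair with the highest combined repeat-level importance (the
per-repeat mean of the two members by default; a per-repeat max mode is
available, since the source criterion's "one or two adjacent ages" phrasing
does not fix the combination). Each focal is compared with each global
measure by a one-sided paired t-test (focal > global, df = R − 1); the
directional alternative follows from the criterion itself. A sensitive
period is declared iff all three comparisons are significant at α = 0.05
for the single **or** for the pair; no correction is applied across the
three globals because the intersection requirement is already conservative
in that direction. The decision is invariant to any common positive
rescaling of importances; focal ties break to the lowest canonical type
index, then the youngest age. Collapsed profiles report the max mean
importance per age (over types) and per type (over ages, with the globals
appended).

## Synthetic data

Latent model per subject i, type t, age a:

    L[i,t,a] = λ·U[i] + √(1−λ²)·Z[i,t,a]

with U a shared standard-normal adversity propensity (λ = 0.5) inducing
the strong multiplicity–severity correlation seen in real data, and Z a
stationary AR(1) over ages (coefficient 0.7 by default) reproducing the
adjacent-age collinearity that motivates the forest approach. L is
marginally N(0,1) and is thresholded at normal quantiles into ordinal
severities 0–3 honoring a per-(type, age) target prevalence profile
(P(≥2) = 0.5·P(≥1), P(≥3) = 0.2·P(≥1)). The default profile gives parental
types a broad mid-childhood plateau, peer types an adolescent peak, and
sexual abuse a rarer late-childhood rise, with base levels chosen so that
mid-childhood cells clear a 5% prevalence filter at n in the hundreds
while edges of the grid fall below it.

Outcomes are computed from the exposure tensor itself: a weighted sum of
the planted cells — each cell standardized first, so weights encode
relative contributions rather than being confounded with cell prevalence —
or the total severity under the global-burden flag. The standardized
signal is mixed with Gaussian noise so it explains `target_r2` of the
latent variance (default 0.10); binary outcomes threshold the latent
variable at the normal quantile of the base rate (default 0.34, a
realistic lifetime depression rate for an enriched sample). `target_r2 =
0` yields a pure-noise outcome. Everything is bit-reproducible from the
scenario seed.

Named study conditions (all n = 560, 10 types × 18 ages): `single_window`
(NVEA during year 14), `dual_window` (PVA year 5 + NVEA year 14, an early
and a late window), `global_burden` (severity-sum-driven — the pattern
expected of symptom clusters sensitive throughout development), `null`
(no signal). The generator emulates marginal prevalences, adjacent-age
autocorrelation, and cross-type dependence; it does **not** emulate
item-level response processes, recall bias, age-varying autocorrelation,
or panel attrition — so passing validation shows the pipeline recovers
effects under the assumed covariance structure, not that real recall data
meet that structure.

## Mediation

Single-mediator model on standardized variables: a from m ~ x; b and c′
from y ~ x + m; c from y ~ x (OLS). ab = a·b with a percentile bootstrap
CI over case resamples (subjects, matching an observational design;
default 5000 replicates). The identity c = c′ + ab holds to numerical
precision for OLS paths. The ratio reported is |ab|/|c′|. Binary outcomes
are fitted as a linear-probability model by default (keeping the
standardized-coefficient scale and the exact decomposition), with a
logistic option that is flagged because a and b then live on different
scales. The Sobel z = ab/√(b²·se_a² + a²·se_b²) is provided for
comparison; it assumes normality of ab, which the bootstrap does not.

## Validation studies and problem sizes

The validation harness runs each named scenario across 10 master seeds
with 5 runs × 10 repeats LGOCV and 100-tree forests — repeats stay at 10
so the focal-vs-global t statistics keep df = 9, while runs and trees are
set to hold a full scenario analysis to ~10–30 s on one CPU. Measured
operating characteristics: planted single-window recovery + declaration
10/10 seeds; global-burden null retention 10/10; dual-window age recovery
(both planted ages within ±1 year of the two top profile peaks) 8/10.

## Known limitations

- **Pure-noise outcomes are not safe from declarations.** In a fixed
  sample of n = 560 the maximum chance |correlation| between a noise
  outcome and ~100 collinear exposure cells is typically 0.10–0.17. A cell
  with chance r ≳ 0.12 is a *genuine within-sample predictor*: every
  LGOCV resample of the same subjects reproduces it, so the repeat-level
  paired t-test — which measures consistency across resamplings, not
  across datasets — rejects with ease, and increasing runs or trees makes
  the spurious t larger, not smaller. In our null-scenario study only
  about half the seeds retained the null (5 of 10 in the shipped test
  run). The declaration framework therefore
  establishes that a focal cell out-predicts global burden *in this
  sample*; it does not control the dataset-level false-positive rate under
  a global null. Corroboration on independent data (or sample-splitting
  at the dataset level) is required before a causal sensitive-period
  interpretation.
- Repeat-level t-tests treat repeats as independent observations; they are
  resamples of one sample, so p-values are anti-conservative in general
  (same root cause as above).
- The rank-test node criterion is asymptotic; at very small node sizes
  (< ~10) the normal approximation is rough, which matters little for
  forests (min_node 7) but is why the tree-oracle checks use the same
  criterion rather than exact permutation p-values.
- Training error of a subsample-averaged forest is *not* monotone in the
  number of trees (individual trees overfit their subsample; averaging
  removes that apparent fit). Held-out error is the monotone quantity and
  is what the tests check.
- Binary-outcome mediation paths are reported on the linear-probability
  scale by default; logistic paths are available but break the exact
  c = c′ + ab decomposition.
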