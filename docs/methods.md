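# Methods

This note documents the statistical procedures `tabml` implements, the
defaults it ships, the numerical choices that matter, and what the synthetic
data used in its tests does and does not demonstrate.

## The pipeline

A run under one seed executes: preprocessing (fit on the full table) →
train/test split → hyperparameter tuning by repeated k-fold
cross-validation on the training set → refit of the best combination on the
whole training set → held-out evaluation → optional permutation importance
on the test set.  The multi-seed workflow repeats everything per seed; the
spread of held-out metrics across seeds is the reported uncertainty.

### Preprocessing

Stages, in order; each stage's bookkeeping is kept so that every original
column is accounted for exactly once:

1. **Constant removal.**  A feature whose non-missing values are all
   identical carries no information and is dropped.
2. **Categorical encoding.**  A feature with L > 2 levels becomes L binary
   indicators `<feature>_<level>`; a two-level feature becomes a single
   indicator named after the lexicographically second level (one column
   suffices — the second indicator would be its complement and would be
   collapsed as perfectly anti-correlated anyway).  Missing categorical
   values propagate to missing in every derived indicator.
3. **Imputation.**  Missing continuous values are replaced by the feature's
   median; missing indicator values by 0 (with a warning).  This keeps all
   samples; anything richer (model-based imputation) would overclaim given
   the simple MCAR settings the pipeline is validated on.
4. **Normalization.**  Continuous features are centered and scaled with the
   sample standard deviation (denominator n − 1).  Binary 0/1 indicator
   columns are never normalized.  A column already standardized to
   mean 0, sd 1 within 1e-12 is left bit-identical, which makes the whole
   pipeline exactly idempotent rather than idempotent up to float noise.
5. **Near-zero-variance filter.**  A feature is removed iff its frequency
   ratio (most-common count / second-most-common count; +∞ for a single
   distinct value) is ≥ `freq_cut` and its distinct-value percentage is
   ≤ `unique_cut`.  Defaults `freq_cut` = 95/5 = 19 and `unique_cut` = 10
   follow the convention of the R caret ecosystem this style of filter
   comes from.  Zero-variance features are always removed.
6. **Correlated collapse.**  A graph is built with an edge wherever
   |Pearson r| ≥ `corr_threshold` (default 1, applied with a 1e-10
   tolerance so exact copies survive floating-point round-off; correlation
   is taken in absolute value, so y = −x collapses too).  Within each
   connected component the feature first in the original column order is
   kept — a deterministic tie-break.  The groups, including singletons, are
   the units permutation importance permutes jointly.

**Leakage caveat.**  Preprocessing statistics (means, SDs, filter and
collapse decisions) are computed on the *full* table before splitting,
matching the behaviour of the reference pipelines this design follows.
Test samples therefore contribute to the normalization parameters.  For the
filters and scaling used here the effect is mild, but it is a known,
deliberate bias of the design; train-only preprocessing is out of scope and
the documentation, not the code, carries the warning.

### Splitting

*Stratified* (default): per outcome class c with n_c samples, the training
side receives round(f·n_c) samples (round-half-even) drawn uniformly under
the seed.  If the summed training size drifts by more than one sample from
round(f·n), the class whose rounding error has the matching sign is nudged
by one — this restores the global target while keeping every per-class
deviation at most one sample.  Continuous outcomes are stratified on
quartile bins of the outcome, which preserves the outcome distribution in
the same spirit.  A class with a single sample is an error (it cannot
appear on both sides).

*Grouped*: group labels are shuffled under the seed and assigned whole to
the training side until the cumulative sample count first reaches f·n;
remaining groups form the test side.  No label ever appears on both sides,
which is the point: with batch- or site-correlated features, a random split
leaks batch identity into the test set.  The greedy size-targeting rule is
a design choice (no outcome balancing across groups is attempted); if the
test side ends up empty, the last-assigned group is moved over with a
warning.

### Models and tuning

Six model families, all behind one opaque handle exposing exactly two
contracts (per-class probability-like scores, and point predictions):

| model id | backend | default grid |
|---|---|---|
| `glmnet_logistic` | scikit-learn `LogisticRegression` (L2, C = 1/λ) | λ ∈ {1e-4 … 10}, α = 0 |
| `glmnet_linear` | scikit-learn `Ridge` (α = λ) | λ ∈ {1e-4 … 10} |
| `svm_rbf` | `SVC`/`SVR` | C ∈ {1e-3 … 1e2}; γ = median heuristic ×{0.1, 1, 10} |
| `decision_tree` | `DecisionTreeClassifier/Regressor` | max depth ∈ {1, 2, 4, 8, 16, 32} |
| `random_forest` | `RandomForestClassifier/Regressor` (500 trees) | mtry ∈ {⌊√p/2⌋, ⌊√p⌋, 2⌊√p⌋} |
| `xgboost` | `XGBClassifier/Regressor` | η ∈ {0.01, 0.1, 0.3} × depth ∈ {2, 4, 6} × 100 rounds |

The grids are this package's defaults, chosen to span the usual useful
range per family; they are overridable and are serialized into every
results file for provenance.  The SVM kernel width uses the median
heuristic γ = 1/median(‖x_i − x_j‖²) on (up to 200 rows of) the training
features, ±1 decade; without data it falls back to 1/p.

Tuning draws `cv_times` independent stratified k-fold partitions of the
training set (one sub-seed per repetition) and scores every grid
combination on every held-out fold; the CV table aggregates mean and sd
over all k·`cv_times` resamples.  Ties in mean metric break toward the
earlier combination in enumeration order.  Should a repetition produce a
training fold missing an outcome class, folds are redrawn with an
incremented sub-seed (up to 10 times, then a warning) — unreachable when
the precondition k ≤ min class count holds.  Library defaults are
`training_frac` 0.8, k = 5, `cv_times` = 100 (the reference-fidelity
value); the CLI defaults to `cv_times` = 10 for desk-scale runs, and the
tests use 1–5.  Tuning metrics default to AUROC (binary), mean one-vs-rest
AUROC (multiclass) and RMSE (continuous).

### Evaluation

The ROC curve is a descending-score threshold sweep with tied scores
grouped into a single step; AUROC is the trapezoidal area, which equals the
Mann–Whitney U statistic divided by n₊·n₋ with ties counted ½ — the tests
verify this identity against a brute-force pairwise count on random
instances.  The positive class is the lexicographically second outcome
level unless overridden, and is echoed in every output.  Threshold metrics
use a 0.5 cut-off on the positive-class score.  AUPRC is average precision
(its chance level is the positive prevalence).  Multiclass AUROC is the
unweighted mean of one-vs-rest AUROCs.

### Permutation importance

On the held-out test set, per feature group and permutation iteration, the
rows of all member columns are shuffled with ONE shared permutation — this
preserves the intra-group correlation structure while severing the group's
link to the outcome, which is exactly why collapsed groups are permuted
together.  The test set is re-scored and the metric recorded;
`perf_metric_diff` is the original metric minus the mean permuted metric.
The empirical p-value uses the add-one rule
p = (#{permuted ≥ original} + 1)/(nperm + 1) (inequality reversed for
loss-type metrics), so p is never 0 and lies exactly on the lattice
{k/(nperm+1)}.  Default `nperm` = 100.  The caller's test table is never
mutated (columns are restored after each group).  When collapsed group
members are no longer present in the processed table, the surviving
representative is permuted and the record reports the full membership.

### Seeds and reproducibility

Every stage seed derives from the run seed by hashing
`"{seed}|{stage tag}"` with SHA-256 and keeping 31 bits — no global random
state, no wall-clock seeding anywhere.  Runs are therefore bit-reproducible
across machines, and multi-seed execution is result-identical whether
serial or parallel (each seed carries all of its randomness).

## Synthetic data

The generator plants exactly the structure the pipeline's stages assume:
standard-normal continuous features with logistic (binary), multinomial
(multiclass) or linear (continuous) planted effects; the intercept is 0, so
binary prevalence is ≈ 50%; categorical features with 3–5 levels,
optionally with a planted last-level effect; exact affine copies for
correlated pairs (guaranteeing |r| = 1 deterministically — a separate noisy
regime is exercised in tests via explicit sub-threshold correlations);
near-zero-variance columns with a dominant value in ≥ 98% of rows; constant
columns; MCAR missingness; and random group labels.  Ground truth
(coefficients, structural roles) is returned for recovery tests.

What it does **not** emulate: compositionality and sparsity of real
relative-abundance data, correlated noise between features, informative
missingness, or batch effects that correlate with the outcome.  Passing
tests therefore demonstrate the pipeline's statistical mechanics
(calibration of the null, monotone signal recovery, zero split leakage,
exact bookkeeping), not performance claims on real microbiome data.

Default study conditions used by the test suite and the acceptance script:
n = 200 samples, 10 continuous features, 5 informative at log-odds 2
(strong-signal conditions) or 0 (null control), 20 independent train/test
splits per condition.  These sizes give simulation standard errors small
enough for 3-SE null checks while each condition completes in seconds.

## Numerical choices

- Sample sd (ddof = 1) throughout; medians use the usual midpoint rule.
- Correlation threshold 1 is applied as ≥ 1 − 1e-10.
- Round-half-even for split sizes (avoids systematic upward bias).
- CV-table sd over a single resample is reported as 0, as is the sd of a
  single-record summary.
- A grid search over combinations with exactly equal means keeps the
  first combination in enumeration order.
- Degenerate inputs fail loudly: all-constant tables, single-sample
  classes, single groups, single-class AUROC, metrics undefined for the
  outcome kind.

## Known limitations

- Preprocess-before-split leakage (documented above, deliberate).
- No nested cross-validation: the multi-seed outer loop estimates split
  variability, not a bias-corrected generalization error.
- Grouped splits do not balance outcome prevalence across sides; severely
  unbalanced groups can produce unbalanced test sets.
- `glmnet`-style models are ridge-penalised only (the default grid fixes
  the elastic-net mixing at 0); the λ grid is on the sklearn `C = 1/λ`
  scale, not glmnet's standardized-deviance path.
- Missingness in a member of a correlated pair breaks exact correlation
  after median imputation, so such pairs may legitimately fail to collapse
  at threshold 1.
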