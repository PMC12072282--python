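# Methods

## The procedure

`glio_select` implements a hybrid feature-selection-and-weighting pipeline
for binary classification of high-dimensional omics tables (samples ×
features, continuous intensities or {0,1} mutation indicators, with a
two-class label such as female/male).

1. **Stratified fold plan.** Samples are partitioned into `n_folds`
   (default 5) stratified folds, fixed by a seed and reused by every later
   stage, so feature selection and classifier evaluation see identical
   splits. Every fold's per-class count is within one sample of exact
   proportionality.
2. **Per-fold base selection.** On each fold's training split two
   selectors run independently:
   - *LASSO*: the support (nonzero coefficients) of an L1-penalised linear
     model of the class code on the features, at penalty `alpha`.
     Continuous data are z-scored with statistics fit on the training
     split; binary indicator data are used as-is.
   - *mRMR* (greedy forward, FCQ variant): step 1 picks the feature with
     the largest one-way F statistic against the label; each later step
     picks `argmax relevance(f) / mean_{s selected} |corr(f, s)|`
     (quotient scheme; a difference scheme is available). Exactly
     `min(k, p)` features are returned, default cardinality `k = 50`.
3. **Rank-based weight accumulation.** Each selector receives an integer
   rank weight — 2 for the better-ranked method, 1 for the other. A
   feature's accumulated weight is the sum of the weights of every
   (fold, selector) selection containing it, so the maximum is
   `n_folds × 3 = 15` at five folds. By default both static assignments
   (lasso=2/mrmr=1 and lasso=1/mrmr=2) are enumerated and carried through
   evaluation side by side; an optional *dynamic* mode instead ranks the
   two selectors per fold by the held-out accuracy of a reference
   classifier (logistic regression by default), ties and empty selections
   resolving in favour of LASSO.
4. **Threshold sweep.** For every threshold `k = 1 .. max observed
   weight`, the candidate panel is `{f : weight(f) ≥ k}`. Panels are
   nested and non-increasing in size; thresholds yielding identical panels
   are retained as separate rows, as sweep tables conventionally print
   them.
5. **Six-classifier evaluation.** Every candidate panel is scored by SVM,
   logistic regression, k-nearest neighbours (k=5), random forest,
   AdaBoost, and a soft-voting ensemble of those five (argmax of summed
   class probabilities, exact tie → class 0), all with library-default
   hyperparameters and `random_state=0`. The score is the unweighted mean
   over folds of the fold accuracy `ACC = (TP+TN)/(TP+TN+FP+FN)`.
6. **Best result.** The winning cell maximises mean accuracy; ties go to
   the smallest panel (largest dimensionality reduction), then the larger
   threshold, then the canonical model order (SVM, LR, KNN, RF, AdaBoost,
   Voting), then the lasso=2/mrmr=1 block. All tie-breaks are logged.
7. **Clustergram.** The selected panel is displayed as per-feature
   z-scores, features ordered by average-linkage hierarchical clustering
   on correlation distance (1 − Pearson r), samples grouped by class, and
   a grey rank bar giving each feature's weight rank.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_folds` | 5 | stratified CV folds shared by all stages |
| `seed` | 0 | fold-plan shuffle seed |
| `lasso_alpha` | 0.01 (pipeline) / 1.0 (bare `SelectorConfig`) | L1 penalty; 0.01 suits highly correlated omics features, larger values shrink every coefficient to zero on standardised data |
| `lasso_max_iter` | 10 000 | coordinate-descent budget; non-convergence logs a warning and returns the current support |
| `mrmr_k` | 50 | greedy cardinality; bounds each fold's mRMR contribution and hence the low-threshold union sizes |
| `random_state` | 0 | fixed for all six classifiers |
| `pseudocount` | 1.0 | shift in `log2(x + pseudocount)`; safe for zero intensities |
| `holdout_fraction` | 0.25 (when enabled) | stratified untouched split for honest evaluation |

Classifier hyperparameters are scikit-learn defaults (recorded in the run
manifest); SVM is configured to emit class probabilities so soft voting is
possible. Scale-sensitive members (SVM, KNN, LR) see training-split-fit
z-scoring on continuous data; tree ensembles never do.

## Evaluation caveat, and the holdout option

By design the final evaluation reuses the *same* fold plan that drove
feature selection. This mirrors how such pipelines are commonly reported,
but it embeds selection bias: features were chosen using every fold's
training split, so the fold accuracies of the chosen panel are optimistic.
The package makes this measurable: `run_with_holdout` sets aside a
stratified fraction before any selection, runs the pipeline on the
remainder, and scores the winning (panel, model) once on the untouched
split. On signal-free data the internal CV accuracy of the selected panel
can approach 1.0 while the holdout accuracy stays at the majority-class
share — exactly the calibration the test suite checks.

## What the synthetic generators emulate — and what they do not

`generate_continuous` produces Gaussian intensity panels with a planted
subset of features carrying a between-class mean shift (`effect_size`, in
SD units, default 2.0), default 68/32 class imbalance over ~100 samples,
optional equicorrelated feature blocks (the highly correlated regime that
motivates the small LASSO penalty), and an optional lognormal transform so
the `log2(x+1)` path is exercised. `generate_binary` produces
mutation-style Bernoulli indicators with class-specific rates (default
baseline 0.3, informative delta 0.3 over 352 × 20). Defaults were fixed
once, before any result was inspected.

Not emulated: realistic proteome/metabolome covariance structure, batch
effects, missingness, heavy-tailed intensity distributions, or
feature-feature interactions. Passing the recovery tests therefore shows
the machinery is correct and well-calibrated under its stated model, not
that panels selected from real cohorts are biologically valid.

## Numerical choices

- mRMR ties (identical criterion values) break to the lowest feature
  index; the mean redundancy in the quotient scheme is floored at 1e-6;
  constant features get relevance 0 and correlation 0, so they are never
  chosen before a non-constant feature.
- LASSO support ordering (|coefficient| descending, ties by index) is for
  reporting only; weighting consumes the unordered support.
- Infinite F statistics (perfect separators) are mapped to the largest
  finite float so the argmax stays well-defined.
- Soft-voting ties resolve to class 0; `select_best` tie-breaks are
  deterministic and logged.
- Accuracy is mean-of-folds, not pooled; fold sizes may differ by one
  sample, so the two differ slightly — the winning configuration's pooled
  accuracy is computed too and recorded in the run manifest.
- Features are tracked by name across folds; results are invariant to
  feature-column permutation (clustergrams use a name-sorted canonical
  order internally) and to sample-row permutation in the selectors.

## Problem sizes used in the checks

The automated checks run the complete pipeline on 100 × 1000 planted
cohorts (ten generator seeds for recovery, ten for null calibration) and
352 × 20 binary cohorts; oracle equivalence uses up to 6 folds × 50
features (weight accumulation) and up to 60 × 12 (exhaustive mRMR). These
sizes exercise every code path at a scale a laptop handles comfortably
while preserving the p ≫ n regime the method targets.

## External smoke test (not automated)

Given a user-supplied copy of the public glioma-grading mutation table
(352 patients × 20 binary gene features, sex as the label), running

    glio-select run --input glioma.csv --label-col Gender --alpha 0.01 --out out/

is expected to land near ~64% best accuracy with a 3-feature panel. The
table is not bundled and the check is not part of the test suite.

## Known limitations

- Only two base selectors; the interfaces generalise but >2 is untested.
- Relevance/redundancy estimators are fixed to F statistic and |Pearson|;
  no mutual-information mRMR (a discretisation policy would be needed).
- Accuracy is the only metric, matching the sweep-table convention the
  pipeline reproduces; imbalanced-data users may want balanced accuracy,
  which the confusion counts make easy to add.
- With `n_folds=5` and small cohorts, fold accuracies are coarse-grained
  (steps of 1/fold-size), so sweep tables contain many exact ties; the
  documented tie-break order decides them reproducibly.
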