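"""End-to-end orchestration of the hybrid selection-and-weighting pipeline.

One call runs the whole procedure on a dataset: plan stratified folds, run
LASSO and mRMR per training fold, accumulate rank-based weights (both
static assignments by default, or the dynamic per-fold ranking), sweep the
weight thresholds, score every candidate panel with the six classifiers,
and pick the smallest panel with the highest mean accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .classify import (
    MODEL_NAMES,
    BestResult,
    SweepReport,
    accuracy,
    confusion_counts,
    full_sweep_evaluation,
    make_model,
    pooled_accuracy,
    select_best,
)
from .datasets import FoldPlan, OmicsDataset, PreprocessSpec, make_fold_plan
from .selectors import SelectorConfig, SelectorOutput
from .weighting import (
    STATIC_ASSIGNMENTS,
    FeatureWeightTable,
    SweepRow,
    accumulate_weights,
    accumulate_weights_dynamic,
    dynamic_rank_per_fold,
    run_fold_selections,
    threshold_sweep,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "default_selector_config", "run_pipeline", "run_with_holdout"]


def default_selector_config() -> SelectorConfig:
    """Operating defaults for omics data: alpha=0.01 (suited to highly
    correlated features), mRMR cardinality 50."""
    return SelectorConfig(lasso_alpha=0.01, mrmr_k=50)


@dataclass(frozen=True)
class PipelineResult:
    """Everything one pipeline run produces."""

    dataset_shape: tuple[int, int]
    plan: FoldPlan
    selections: list[SelectorOutput]
    weight_tables: dict[str, FeatureWeightTable]
    sweeps: dict[str, list[SweepRow]]
    report: SweepReport
    best: BestResult
    best_pooled_accuracy: float = float("nan")
    config: dict = field(default_factory=dict)


def run_pipeline(
    ds: OmicsDataset,
    n_folds: int = 5,
    seed: int = 0,
    selector_cfg: SelectorConfig | None = None,
    prep: PreprocessSpec | None = None,
    mode: str = "static",
    models: tuple[str, ...] = MODEL_NAMES,
    random_state: int = 0,
) -> PipelineResult:
    """Run the full pipeline on a dataset.

    ``mode='static'`` (default) enumerates both rank assignments
    (lasso=2/mrmr=1 and lasso=1/mrmr=2) and carries both through
    evaluation; ``mode='dynamic'`` ranks the two selectors per fold by the
    held-out accuracy of a reference classifier.  Deterministic for fixed
    inputs and seeds.
    """
    selector_cfg = selector_cfg or default_selector_config()
    prep = prep or PreprocessSpec(standardize=ds.value_kind == "continuous")
    plan = make_fold_plan(ds.labels, n_folds=n_folds, seed=seed)
    selections = run_fold_selections(ds, plan, selector_cfg, prep)

    weight_tables: dict[str, FeatureWeightTable] = {}
    if mode == "static":
        for assignment in STATIC_ASSIGNMENTS:
            weight_tables[assignment.tag] = accumulate_weights(
                selections, assignment, n_folds=n_folds
            )
    elif mode == "dynamic":
        per_fold = dynamic_rank_per_fold(ds, plan, selections, prep=prep)
        weight_tables["dynamic"] = accumulate_weights_dynamic(
            selections, per_fold, n_folds=n_folds
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sweeps = {tag: threshold_sweep(table) for tag, table in weight_tables.items()}
    report = full_sweep_evaluation(ds, plan, sweeps, models, prep, random_state)
    best = select_best(report, ds.feature_names)
    # pooled accuracy reported alongside: fold sizes may differ by one
    best_pooled = pooled_accuracy(
        ds, set(best.feature_indices), best.model, plan, prep, random_state
    )
    logger.info(
        "best: %s k=%d %s, %d features, mean accuracy %.3f",
        best.assignment,
        best.k,
        best.model,
        best.n_features,
        best.mean_accuracy,
    )
    config = {
        "n_folds": n_folds,
        "seed": seed,
        "random_state": random_state,
        "mode": mode,
        "lasso_alpha": selector_cfg.lasso_alpha,
        "lasso_max_iter": selector_cfg.lasso_max_iter,
        "mrmr_k": selector_cfg.mrmr_k,
        "mrmr_scheme": selector_cfg.scheme,
        "log2": prep.log2,
        "pseudocount": prep.pseudocount,
        "standardize": prep.standardize,
        "models": list(models),
        "label_mapping": dict(ds.label_mapping),
    }
    return PipelineResult(
        dataset_shape=(ds.n_samples, ds.n_features),
        plan=plan,
        selections=selections,
        weight_tables=weight_tables,
        sweeps=sweeps,
        report=report,
        best=best,
        best_pooled_accuracy=best_pooled,
        config=config,
    )


def run_with_holdout(
    ds: OmicsDataset,
    holdout_fraction: float = 0.25,
    n_folds: int = 5,
    seed: int = 0,
    selector_cfg: SelectorConfig | None = None,
    prep: PreprocessSpec | None = None,
    mode: str = "static",
    models: tuple[str, ...] = MODEL_NAMES,
    random_state: int = 0,
) -> tuple[PipelineResult, float]:
    """Honest-evaluation variant: hold out a stratified split first.

    A stratified ``holdout_fraction`` of samples is set aside before any
    selection; the pipeline runs on the remainder, then the winning model
    is refit on that development portion restricted to the winning panel
    and scored once on the untouched holdout.  Returns
    ``(pipeline_result, holdout_accuracy)``.
    """
    idx = np.arange(ds.n_samples)
    dev_idx, hold_idx = train_test_split(
        idx,
        test_size=holdout_fraction,
        stratify=ds.labels,
        random_state=seed,
    )
    dev = OmicsDataset(
        sample_ids=[ds.sample_ids[i] for i in dev_idx],
        feature_names=ds.feature_names,
        values=ds.values[dev_idx],
        labels=ds.labels[dev_idx],
        value_kind=ds.value_kind,
        label_mapping=ds.label_mapping,
    )
    result = run_pipeline(
        dev, n_folds, seed, selector_cfg, prep, mode, models, random_state
    )
    prep = prep or PreprocessSpec(standardize=ds.value_kind == "continuous")
    cols = np.asarray(result.best.feature_indices)
    X = ds.values
    if prep.log2 and ds.value_kind == "continuous":
        from .datasets import log2_transform

        X = log2_transform(ds, prep.pseudocount).values
    standardize = prep.standardize and ds.value_kind == "continuous"
    model = make_model(result.best.model, random_state, standardize)
    model.fit(X[np.ix_(dev_idx, cols)], ds.labels[dev_idx])
    pred = model.predict(X[np.ix_(hold_idx, cols)])
    hold_acc = accuracy(confusion_counts(ds.labels[hold_idx], pred))
    logger.info("holdout accuracy of best panel: %.3f", hold_acc)
    return result, float(hold_acc)
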