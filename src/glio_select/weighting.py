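"""Rank-based weight accumulation over folds and selectors, and the
weight-threshold sweep.

Each of the two base selectors gets an integer rank weight (2 for the
better-ranked method, 1 for the other).  A feature's accumulated weight is
the sum, over all cross-validation folds, of the weights of the selectors
that picked it in that fold — so with 5 folds and weights {2, 1} the maximum
possible weight is 15.  Thresholding the weight table at every k from 1 up
to the maximum observed weight yields a nested family of candidate feature
panels, which the classification stage then scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .datasets import FoldPlan, OmicsDataset, PreprocessSpec, log2_transform
from .selectors import SelectorConfig, SelectorOutput, lasso_select, mrmr_select

logger = logging.getLogger(__name__)

__all__ = [
    "RankAssignment",
    "FeatureWeightTable",
    "SweepRow",
    "run_fold_selections",
    "accumulate_weights",
    "accumulate_weights_dynamic",
    "threshold_sweep",
    "dynamic_rank_per_fold",
    "weight_table_frame",
]

METHODS = ("lasso", "mrmr")


@dataclass(frozen=True)
class RankAssignment:
    """Integer rank weights for the two selectors: one gets 2, the other 1."""

    w_lasso: int
    w_mrmr: int

    def __post_init__(self) -> None:
        if {self.w_lasso, self.w_mrmr} != {1, 2}:
            raise ValueError("rank weights must be {1, 2} split between the methods")

    def weight(self, method: str) -> int:
        return self.w_lasso if method == "lasso" else self.w_mrmr

    @property
    def tag(self) -> str:
        """Short label, e.g. 'L2M1' for lasso=2, mrmr=1."""
        return f"L{self.w_lasso}M{self.w_mrmr}"


LASSO_FIRST = RankAssignment(w_lasso=2, w_mrmr=1)
MRMR_FIRST = RankAssignment(w_lasso=1, w_mrmr=2)
STATIC_ASSIGNMENTS = (LASSO_FIRST, MRMR_FIRST)


@dataclass(frozen=True)
class FeatureWeightTable:
    """Accumulated per-feature integer weights under one rank assignment.

    Features never selected are absent (implicit weight 0).
    ``assignment`` is None for the dynamic per-fold mode, where the weights
    of the winning method vary fold by fold.
    """

    assignment: RankAssignment | None
    weights: dict[int, int]
    n_folds: int

    def __post_init__(self) -> None:
        cap = self.n_folds * 3
        for f, w in self.weights.items():
            if not 0 <= w <= cap:
                raise ValueError(
                    f"weight {w} for feature {f} outside [0, {cap}]"
                )

    @property
    def max_weight(self) -> int:
        return max(self.weights.values(), default=0)


@dataclass(frozen=True)
class SweepRow:
    """Candidate panel at one weight threshold: all features with weight >= k."""

    k: int
    feature_set: frozenset[int]

    @property
    def n_features(self) -> int:
        return len(self.feature_set)


def run_fold_selections(
    ds: OmicsDataset,
    plan: FoldPlan,
    cfg: SelectorConfig,
    prep: PreprocessSpec | None = None,
) -> list[SelectorOutput]:
    """Run both base selectors on every fold's training split.

    Standardisation (when enabled and the data are continuous) is fit on the
    training split only before LASSO; the mRMR criterion is invariant to
    per-feature affine scaling so it sees the unscaled training values.
    Returns ``2 * n_folds`` outputs, lasso then mrmr per fold.
    """
    prep = prep or PreprocessSpec()
    if prep.log2:
        ds = log2_transform(ds, prep.pseudocount)
    X, y = ds.values, ds.labels
    outputs: list[SelectorOutput] = []
    for fold, (train_idx, _) in enumerate(plan.splits()):
        X_tr, y_tr = X[train_idx], y[train_idx]
        if prep.standardize and ds.value_kind == "continuous":
            X_lasso = StandardScaler().fit_transform(X_tr)
        else:
            X_lasso = X_tr
        try:
            outputs.append(lasso_select(X_lasso, y_tr, cfg, fold_index=fold))
            outputs.append(mrmr_select(X_tr, y_tr, cfg.mrmr_k, cfg, fold_index=fold))
        except Exception as exc:
            raise RuntimeError(f"selector failed on fold {fold}: {exc}") from exc
    return outputs


def _check_coverage(selections: list[SelectorOutput]) -> set[int]:
    seen: set[tuple[int, str]] = set()
    for sel in selections:
        key = (sel.fold_index, sel.method)
        if key in seen:
            raise ValueError(f"duplicate selection for fold {key[0]}, {key[1]}")
        seen.add(key)
    return {f for f, _ in seen}


def accumulate_weights(
    selections: list[SelectorOutput],
    assignment: RankAssignment,
    n_folds: int | None = None,
) -> FeatureWeightTable:
    """Sum rank weights over every (fold, method) selection containing a feature.

    weight(f) = sum over folds of
    ``w_lasso * [f in lasso fold selection] + w_mrmr * [f in mrmr fold selection]``.
    """
    folds = _check_coverage(selections)
    if n_folds is None:
        n_folds = max(folds, default=-1) + 1
    weights: dict[int, int] = {}
    for sel in selections:
        w = assignment.weight(sel.method)
        for f in sel.selected:
            weights[f] = weights.get(f, 0) + w
    return FeatureWeightTable(assignment=assignment, weights=weights, n_folds=n_folds)


def accumulate_weights_dynamic(
    selections: list[SelectorOutput],
    per_fold: dict[int, RankAssignment],
    n_folds: int | None = None,
) -> FeatureWeightTable:
    """Accumulate with a per-fold rank assignment (dynamic mode)."""
    folds = _check_coverage(selections)
    if n_folds is None:
        n_folds = max(folds, default=-1) + 1
    weights: dict[int, int] = {}
    for sel in selections:
        w = per_fold[sel.fold_index].weight(sel.method)
        for f in sel.selected:
            weights[f] = weights.get(f, 0) + w
    return FeatureWeightTable(assignment=None, weights=weights, n_folds=n_folds)


def threshold_sweep(table: FeatureWeightTable) -> list[SweepRow]:
    """One row per threshold k = 1 .. max observed weight.

    Rows with identical feature sets are all retained, mirroring how the
    sweep is reported; the sets are nested and non-increasing in size.
    """
    rows: list[SweepRow] = []
    for k in range(1, table.max_weight + 1):
        fs = frozenset(f for f, w in table.weights.items() if w >= k)
        rows.append(SweepRow(k=k, feature_set=fs))
    return rows


def dynamic_rank_per_fold(
    ds: OmicsDataset,
    plan: FoldPlan,
    selections: list[SelectorOutput],
    reference_model=None,
    prep: PreprocessSpec | None = None,
) -> dict[int, RankAssignment]:
    """Rank the two selectors per fold by held-out accuracy of a reference model.

    For each fold the reference classifier (default: logistic regression,
    scaled) is trained on the training split restricted to each method's
    selection and scored on the held-out split; the higher-accuracy method
    gets weight 2.  Exact ties and folds where a method selected nothing
    resolve in favour of LASSO (w_lasso=2), logged.
    """
    prep = prep or PreprocessSpec()
    if prep.log2:
        ds = log2_transform(ds, prep.pseudocount)
    if reference_model is None:
        reference_model = make_pipeline(
            StandardScaler(), LogisticRegression(random_state=0, max_iter=1000)
        )
    by_fold: dict[int, dict[str, SelectorOutput]] = {}
    for sel in selections:
        by_fold.setdefault(sel.fold_index, {})[sel.method] = sel
    X, y = ds.values, ds.labels
    result: dict[int, RankAssignment] = {}
    for fold, (train_idx, test_idx) in enumerate(plan.splits()):
        accs: dict[str, float] = {}
        for method in METHODS:
            sel = by_fold[fold][method]
            if not sel.selected:
                logger.warning(
                    "fold %d: %s selected no features; it receives weight 1",
                    fold,
                    method,
                )
                accs[method] = -np.inf
                continue
            cols = np.asarray(sel.selected)
            model = clone(reference_model)
            model.fit(X[np.ix_(train_idx, cols)], y[train_idx])
            accs[method] = float(
                model.score(X[np.ix_(test_idx, cols)], y[test_idx])
            )
        if accs["lasso"] >= accs["mrmr"]:
            if accs["lasso"] == accs["mrmr"]:
                logger.info("fold %d: tie (%.3f); lasso takes weight 2", fold, accs["lasso"])
            result[fold] = LASSO_FIRST
        else:
            result[fold] = MRMR_FIRST
    return result


def weight_table_frame(
    selections: list[SelectorOutput],
    feature_names: list[str],
    n_folds: int | None = None,
) -> pd.DataFrame:
    """Tidy export: per-feature selection counts and weights under both
    static assignments, sorted by weight_21 descending then name."""
    counts = {m: {} for m in METHODS}
    for sel in selections:
        for f in sel.selected:
            counts[sel.method][f] = counts[sel.method].get(f, 0) + 1
    w21 = accumulate_weights(selections, LASSO_FIRST, n_folds)
    w12 = accumulate_weights(selections, MRMR_FIRST, n_folds)
    feats = sorted(w21.weights)
    df = pd.DataFrame(
        {
            "feature_name": [feature_names[f] for f in feats],
            "selection_count_lasso": [counts["lasso"].get(f, 0) for f in feats],
            "selection_count_mrmr": [counts["mrmr"].get(f, 0) for f in feats],
            "weight_21": [w21.weights[f] for f in feats],
            "weight_12": [w12.weights[f] for f in feats],
        }
    )
    return df.sort_values(
        ["weight_21", "feature_name"], ascending=[False, True]
    ).reset_index(drop=True)
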