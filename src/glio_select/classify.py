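"""Six-classifier evaluation of candidate panels and best-result selection.

Every candidate feature panel from the weight-threshold sweep is scored by
SVM, LR, KNN, RF, AdaBoost and a soft-voting ensemble of those five, under
the same stratified folds used for feature selection.  The figure of merit
is the unweighted mean over folds of the fold accuracy

    ACC = (TP + TN) / (TP + TN + FP + FN)

and the winning configuration is the one with the highest mean accuracy,
ties resolved toward the smallest panel (largest dimensionality reduction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    RandomForestClassifier,
    VotingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datasets import FoldPlan, OmicsDataset, PreprocessSpec
from .weighting import RankAssignment, SweepRow

logger = logging.getLogger(__name__)

# SVC must emit class probabilities for soft voting; newer sklearn flags the
# probability switch as deprecated on every fit
warnings.filterwarnings(
    "ignore", message="The `probability` parameter", category=FutureWarning
)

__all__ = [
    "MODEL_NAMES",
    "ConfusionCounts",
    "SweepReportRow",
    "SweepReport",
    "BestResult",
    "accuracy",
    "soft_vote",
    "make_model",
    "confusion_counts",
    "evaluate_subset",
    "evaluate_all_models",
    "full_sweep_evaluation",
    "select_best",
]

#: canonical model order (also the tie-break order for best-result selection)
MODEL_NAMES = ("SVM", "LR", "KNN", "RF", "AdaBoost", "Voting")
_SCALE_SENSITIVE = {"SVM", "LR", "KNN"}


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correct predictions, (TP+TN)/(TP+TN+FP+FN)."""
    if c.total == 0:
        raise ValueError("accuracy undefined for zero evaluated samples")
    return (c.TP + c.TN) / c.total


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Counts with class 1 as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def soft_vote(member_probabilities: list[np.ndarray]) -> int:
    """Predicted class by the soft-voting rule.

    Sums the five members' class-probability vectors and returns the argmax
    class; an exact tie resolves to class 0.
    """
    if len(member_probabilities) != 5:
        raise ValueError(
            f"soft voting requires all 5 member probability vectors, "
            f"got {len(member_probabilities)}"
        )
    probs = np.asarray(member_probabilities, dtype=float)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each member probability vector must sum to 1")
    return int(np.argmax(probs.sum(axis=0)))  # argmax ties -> lowest class = 0


def make_model(name: str, random_state: int = 0, standardize: bool = True):
    """Construct one of the six classifiers with library-default settings.

    ``random_state`` is fixed for every model; scale-sensitive members
    (SVM, KNN, LR) are wrapped in a training-split-fit StandardScaler when
    ``standardize`` is on, tree ensembles never are.  SVM is configured to
    emit class probabilities so that soft voting is possible.
    """

    def scaled(est):
        return make_pipeline(StandardScaler(), est) if standardize else est

    if name == "SVM":
        return scaled(SVC(probability=True, random_state=random_state))
    if name == "LR":
        return scaled(LogisticRegression(random_state=random_state, max_iter=1000))
    if name == "KNN":
        return scaled(KNeighborsClassifier())
    if name == "RF":
        return RandomForestClassifier(random_state=random_state)
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=random_state)
    if name == "Voting":
        members = [
            (m, make_model(m, random_state, standardize))
            for m in ("SVM", "KNN", "LR", "RF", "AdaBoost")
        ]
        return VotingClassifier(estimators=members, voting="soft")
    raise ValueError(f"unknown model {name!r}")


def evaluate_subset(
    ds: OmicsDataset,
    features: "frozenset[int] | set[int]",
    model_name: str,
    plan: FoldPlan,
    prep: PreprocessSpec | None = None,
    random_state: int = 0,
) -> float:
    """Mean over folds of the held-out fold accuracy for one feature panel.

    Per fold the model is fit on the training split restricted to the panel
    (any scaling fit on the training split only) and scored on the held-out
    split; the unweighted mean of the fold accuracies is returned.
    Deterministic given ``random_state``.
    """
    if not features:
        raise ValueError("empty feature panel")
    prep = prep or PreprocessSpec()
    if prep.log2 and ds.value_kind == "continuous":
        from .datasets import log2_transform

        ds = log2_transform(ds, prep.pseudocount)
    cols = np.asarray(sorted(features), dtype=int)
    if cols.min() < 0 or cols.max() >= ds.n_features:
        raise ValueError("feature index outside dataset")
    standardize = prep.standardize and ds.value_kind == "continuous"
    X, y = ds.values[:, cols], ds.labels
    fold_accs = []
    for fold, (train_idx, test_idx) in enumerate(plan.splits()):
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {fold}: training split has a single class")
        model = make_model(model_name, random_state, standardize)
        model.fit(X[train_idx], y_tr)
        pred = model.predict(X[test_idx])
        fold_accs.append(accuracy(confusion_counts(y[test_idx], pred)))
    return float(np.mean(fold_accs))


def pooled_accuracy(
    ds: OmicsDataset,
    features: "frozenset[int] | set[int]",
    model_name: str,
    plan: FoldPlan,
    prep: PreprocessSpec | None = None,
    random_state: int = 0,
) -> float:
    """Accuracy pooled over all held-out predictions.

    Unlike the mean-of-folds figure, every sample counts once regardless of
    fold size; with unequal folds the two differ slightly.
    """
    if not features:
        raise ValueError("empty feature panel")
    prep = prep or PreprocessSpec()
    if prep.log2 and ds.value_kind == "continuous":
        from .datasets import log2_transform

        ds = log2_transform(ds, prep.pseudocount)
    standardize = prep.standardize and ds.value_kind == "continuous"
    cols = np.asarray(sorted(features), dtype=int)
    X, y = ds.values[:, cols], ds.labels
    y_pred = np.empty_like(y)
    for train_idx, test_idx in plan.splits():
        model = make_model(model_name, random_state, standardize)
        model.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = model.predict(X[test_idx])
    return accuracy(confusion_counts(y, y_pred))


_VOTING_MEMBERS = ("SVM", "KNN", "LR", "RF", "AdaBoost")


def evaluate_all_models(
    ds: OmicsDataset,
    features: "frozenset[int] | set[int]",
    plan: FoldPlan,
    prep: PreprocessSpec | None = None,
    random_state: int = 0,
    models: tuple[str, ...] = MODEL_NAMES,
) -> dict[str, float]:
    """Mean fold accuracy of every requested model for one panel.

    Equivalent to calling :func:`evaluate_subset` per model, but the five
    base classifiers are fit once per fold and the soft-voting accuracy is
    derived from their summed class probabilities, so the ensemble costs no
    extra fits.
    """
    if not features:
        raise ValueError("empty feature panel")
    prep = prep or PreprocessSpec()
    if prep.log2 and ds.value_kind == "continuous":
        from .datasets import log2_transform

        ds = log2_transform(ds, prep.pseudocount)
    standardize = prep.standardize and ds.value_kind == "continuous"
    cols = np.asarray(sorted(features), dtype=int)
    X, y = ds.values[:, cols], ds.labels
    need_voting = "Voting" in models
    members = tuple(
        m for m in _VOTING_MEMBERS if need_voting or m in models
    )
    fold_accs: dict[str, list[float]] = {m: [] for m in models}
    for fold, (train_idx, test_idx) in enumerate(plan.splits()):
        y_tr, y_te = y[train_idx], y[test_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {fold}: training split has a single class")
        prob_sum = np.zeros((len(test_idx), 2))
        for name in members:
            model = make_model(name, random_state, standardize)
            model.fit(X[train_idx], y_tr)
            if name in models:
                pred = model.predict(X[test_idx])
                fold_accs[name].append(accuracy(confusion_counts(y_te, pred)))
            if need_voting:
                prob_sum += model.predict_proba(X[test_idx])
        if need_voting:
            vote_pred = np.argmax(prob_sum, axis=1)
            fold_accs["Voting"].append(accuracy(confusion_counts(y_te, vote_pred)))
    return {m: float(np.mean(a)) for m, a in fold_accs.items()}


@dataclass(frozen=True)
class SweepReportRow:
    assignment: str  # e.g. "L2M1", or "dynamic"
    k: int
    feature_set: frozenset[int]
    accuracies: dict[str, float]  # model name -> mean accuracy in [0, 1]

    @property
    def n_features(self) -> int:
        return len(self.feature_set)


@dataclass(frozen=True)
class SweepReport:
    """All (assignment, threshold, model) mean accuracies — one sweep table
    block per rank assignment."""

    rows: tuple[SweepReportRow, ...]

    def to_frame(self, feature_names: list[str] | None = None) -> pd.DataFrame:
        """Table mirroring the published sweep layout, accuracies in %."""
        records = []
        for row in self.rows:
            rec = {
                "assignment": row.assignment,
                "k": row.k,
                "n_features": row.n_features,
            }
            rec.update(
                {m: round(100.0 * row.accuracies[m], 3) for m in MODEL_NAMES}
            )
            records.append(rec)
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class BestResult:
    """The winning (assignment, threshold, model, panel) configuration."""

    assignment: str
    k: int
    model: str
    feature_indices: tuple[int, ...]
    feature_names: tuple[str, ...]
    mean_accuracy: float

    @property
    def n_features(self) -> int:
        return len(self.feature_indices)


def full_sweep_evaluation(
    ds: OmicsDataset,
    plan: FoldPlan,
    sweeps: dict[str, list[SweepRow]],
    models: tuple[str, ...] = MODEL_NAMES,
    prep: PreprocessSpec | None = None,
    random_state: int = 0,
) -> SweepReport:
    """Score every (assignment, threshold) panel with every model.

    ``sweeps`` maps an assignment tag (e.g. "L2M1") to its threshold sweep.
    Identical feature sets are evaluated once per model and the accuracy
    reused, so duplicate rows are exactly equal by construction.
    """
    cache: dict[frozenset[int], dict[str, float]] = {}
    rows: list[SweepReportRow] = []
    for tag, sweep in sweeps.items():
        for sweep_row in sweep:
            if sweep_row.feature_set not in cache:
                try:
                    cache[sweep_row.feature_set] = evaluate_all_models(
                        ds, sweep_row.feature_set, plan, prep, random_state, models
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"evaluation failed for assignment {tag}, "
                        f"k={sweep_row.k}: {exc}"
                    ) from exc
            accs = dict(cache[sweep_row.feature_set])
            rows.append(
                SweepReportRow(
                    assignment=tag,
                    k=sweep_row.k,
                    feature_set=sweep_row.feature_set,
                    accuracies=accs,
                )
            )
    return SweepReport(rows=tuple(rows))


#: assignment preference order for final tie-breaks
_ASSIGNMENT_ORDER = {"L2M1": 0, "L1M2": 1, "dynamic": 2}


def select_best(report: SweepReport, feature_names: list[str]) -> BestResult:
    """Pick the best cell: highest mean accuracy, then fewest features.

    Remaining ties prefer the larger threshold k, then the canonical model
    order (SVM, LR, KNN, RF, AdaBoost, Voting), then the lasso=2/mrmr=1
    assignment block.  Every tie-break step is logged.
    """
    if not report.rows:
        raise ValueError("empty sweep report")
    candidates = [
        (row, model, row.accuracies[model])
        for row in report.rows
        for model in MODEL_NAMES
        if model in row.accuracies
    ]
    best_acc = max(acc for _, _, acc in candidates)
    pool = [c for c in candidates if c[2] == best_acc]
    if len(pool) > 1:
        min_n = min(row.n_features for row, _, _ in pool)
        logger.info(
            "%d cells at accuracy %.4f; keeping panels of %d features",
            len(pool),
            best_acc,
            min_n,
        )
        pool = [c for c in pool if c[0].n_features == min_n]
    if len(pool) > 1:
        max_k = max(row.k for row, _, _ in pool)
        logger.info("tie on panel size; preferring threshold k=%d", max_k)
        pool = [c for c in pool if c[0].k == max_k]
    if len(pool) > 1:
        logger.info("tie on k; applying model order then assignment order")
        pool.sort(
            key=lambda c: (
                MODEL_NAMES.index(c[1]),
                _ASSIGNMENT_ORDER.get(c[0].assignment, 99),
            )
        )
    row, model, acc = pool[0]
    idx = tuple(sorted(row.feature_set))
    return BestResult(
        assignment=row.assignment,
        k=row.k,
        model=model,
        feature_indices=idx,
        feature_names=tuple(feature_names[i] for i in idx),
        mean_accuracy=acc,
    )
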