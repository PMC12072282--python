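"""The two base feature selectors run on every training fold.

* :func:`lasso_select` — embedded selection: the support (nonzero
  coefficients) of an L1-penalised linear model of the class code on the
  features.
* :func:`mrmr_select` — filter selection: greedy forward
  minimum-redundancy-maximum-relevance with the FCQ criterion (F-statistic
  relevance, |Pearson| redundancy, quotient combination).

Both are deterministic and invariant to sample order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import f_classif
from sklearn.linear_model import Lasso

logger = logging.getLogger(__name__)

__all__ = [
    "SelectorConfig",
    "SelectorOutput",
    "lasso_select",
    "mrmr_select",
    "selections_frame",
]

#: guard against zero mean redundancy in the quotient scheme
REDUNDANCY_EPS = 1e-6


@dataclass(frozen=True)
class SelectorConfig:
    """Settings shared by the two base selectors.

    ``lasso_alpha`` defaults to 1.0 (library parity); the pipeline operating
    default is 0.01, suited to highly correlated omics features.  ``mrmr_k``
    is the greedy selection cardinality; it bounds how many features each
    fold's mRMR pass can contribute, so it directly shapes the low-threshold
    union sizes in the weight sweep.
    """

    lasso_alpha: float = 1.0
    lasso_max_iter: int = 10_000
    mrmr_k: int = 50
    relevance: str = "f_stat"
    redundancy: str = "abs_pearson"
    scheme: str = "quotient"

    def __post_init__(self) -> None:
        if self.lasso_alpha <= 0:
            raise ValueError("lasso_alpha must be positive")
        if self.mrmr_k < 1:
            raise ValueError("mrmr_k must be >= 1")
        if self.relevance != "f_stat":
            raise ValueError(f"unsupported relevance {self.relevance!r}")
        if self.redundancy != "abs_pearson":
            raise ValueError(f"unsupported redundancy {self.redundancy!r}")
        if self.scheme not in ("quotient", "difference"):
            raise ValueError(f"unsupported scheme {self.scheme!r}")


@dataclass(frozen=True)
class SelectorOutput:
    """Ordered selection from one method on one training fold."""

    method: str  # "lasso" | "mrmr"
    fold_index: int
    selected: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.method not in ("lasso", "mrmr"):
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.scores) != len(self.selected):
            raise ValueError("one score per selected feature required")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


def selections_frame(selections, feature_names: list[str]):
    """Tidy per-fold selections: one row per selected feature.

    Columns: fold, method, rank (1 = first selected / largest |coef|),
    feature_name, score.
    """
    import pandas as pd

    records = [
        {
            "fold": sel.fold_index,
            "method": sel.method,
            "rank": rank,
            "feature_name": feature_names[f],
            "score": score,
        }
        for sel in selections
        for rank, (f, score) in enumerate(zip(sel.selected, sel.scores), start=1)
    ]
    return pd.DataFrame.from_records(
        records, columns=["fold", "method", "rank", "feature_name", "score"]
    )


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")


def lasso_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: SelectorConfig,
    fold_index: int = 0,
) -> SelectorOutput:
    """Support of the L1-penalised linear model of y on X.

    Features with nonzero coefficient at penalty ``cfg.lasso_alpha`` are
    returned ordered by |coefficient| descending, ties broken by ascending
    feature index (the ordering is for reporting; downstream weighting uses
    the set).  Non-convergence at ``lasso_max_iter`` logs a warning and the
    current support is returned.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    _check_two_classes(y_train)
    model = Lasso(alpha=cfg.lasso_alpha, max_iter=cfg.lasso_max_iter)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X_train, y_train)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            logger.warning(
                "lasso did not converge in %d iterations (fold %d); "
                "returning current support",
                cfg.lasso_max_iter,
                fold_index,
            )
    coef = np.abs(model.coef_)
    support = np.flatnonzero(coef > 0)
    # sort by |coef| descending, ties by ascending index
    order = np.lexsort((support, -coef[support]))
    selected = support[order]
    return SelectorOutput(
        method="lasso",
        fold_index=fold_index,
        selected=tuple(int(i) for i in selected),
        scores=tuple(float(coef[i]) for i in selected),
    )


def _f_relevance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way F statistic of each feature grouped by class; 0 where undefined."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features emit runtime warnings
        f_stats, _ = f_classif(X, y)
    return np.nan_to_num(f_stats, nan=0.0, posinf=np.finfo(float).max, neginf=0.0)


def mrmr_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    k: int | None = None,
    cfg: SelectorConfig = SelectorConfig(),
    fold_index: int = 0,
) -> SelectorOutput:
    """Greedy forward mRMR selection (FCQ variant by default).

    Step 1 picks the feature with the largest relevance (one-way F statistic
    against the class label).  Each later step picks the feature maximising

        relevance(f, y) / mean_{s in selected} |corr(f, s)|     (quotient)
        relevance(f, y) - mean_{s in selected} |corr(f, s)|     (difference)

    with the mean redundancy floored at ``REDUNDANCY_EPS`` in the quotient
    scheme.  Ties are broken by ascending feature index.  Constant features
    have relevance 0 and are never chosen before a non-constant feature.
    Returns exactly ``min(k, n_features)`` features in selection order,
    with the greedy criterion value of each step as its score.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    _check_two_classes(y)
    n_features = X.shape[1]
    if k is None:
        k = cfg.mrmr_k
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_features:
        logger.warning("mrmr k=%d exceeds %d features; truncating", k, n_features)
        k = n_features

    relevance = _f_relevance(X, y)
    sd = X.std(axis=0)
    constant = sd == 0
    # center/scale once so redundancy is a plain dot product
    Xc = X - X.mean(axis=0)
    denom = np.where(constant, 1.0, sd)
    Xn = Xc / denom

    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(n_features)
    available = np.ones(n_features, dtype=bool)
    n = X.shape[0]
    for step in range(k):
        if step == 0:
            criterion = relevance.copy()
        else:
            mean_red = redundancy_sum / step
            if cfg.scheme == "quotient":
                criterion = relevance / np.maximum(mean_red, REDUNDANCY_EPS)
            else:
                criterion = relevance - mean_red
        criterion = np.where(available, criterion, -np.inf)
        best = int(np.argmax(criterion))  # first max -> ascending-index tie-break
        selected.append(best)
        scores.append(float(criterion[best]))
        available[best] = False
        # |Pearson r| of every feature with the newly selected one;
        # correlation with a constant feature is undefined -> treated as 0
        r = np.abs(Xn.T @ Xn[:, best]) / n
        r[constant | constant[best]] = 0.0
        redundancy_sum += np.minimum(r, 1.0)
    return SelectorOutput(
        method="mrmr",
        fold_index=fold_index,
        selected=tuple(selected),
        scores=tuple(scores),
    )
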