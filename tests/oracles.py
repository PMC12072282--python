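"""Naive reference implementations used only as cross-checks in tests.

These deliberately avoid the package's vectorised code paths: scalar loops,
scipy.stats per-feature statistics, explicit double summation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from glio_select.selectors import REDUNDANCY_EPS, SelectorOutput
from glio_select.weighting import RankAssignment


def naive_accumulate(
    selections: list[SelectorOutput], assignment: RankAssignment
) -> dict[int, int]:
    """Double-loop rank-weight summation over (fold, method) selections."""
    weights: dict[int, int] = {}
    folds = sorted({s.fold_index for s in selections})
    for fold in folds:
        for method in ("lasso", "mrmr"):
            for sel in selections:
                if sel.fold_index != fold or sel.method != method:
                    continue
                w = assignment.w_lasso if method == "lasso" else assignment.w_mrmr
                for f in sel.selected:
                    weights[f] = weights.get(f, 0) + w
    return weights


def _f_stat(x: np.ndarray, y: np.ndarray) -> float:
    groups = [x[y == c] for c in np.unique(y)]
    if any(np.ptp(g) == 0 for g in groups) and np.ptp(x) == 0:
        return 0.0
    f, _ = stats.f_oneway(*groups)
    if not np.isfinite(f):
        return 0.0 if np.isnan(f) else np.finfo(float).max
    return float(f)


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    r, _ = stats.pearsonr(a, b)
    return abs(float(r))


def naive_mrmr(
    X: np.ndarray, y: np.ndarray, k: int, scheme: str = "quotient"
) -> list[int]:
    """Per-step exhaustive re-evaluation of the greedy FCQ/FCD criterion."""
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    k = min(k, n_features)
    relevance = [_f_stat(X[:, j], y) for j in range(n_features)]
    selected: list[int] = []
    for _ in range(k):
        best_j, best_val = None, None
        for j in range(n_features):
            if j in selected:
                continue
            if not selected:
                val = relevance[j]
            else:
                red = np.mean([_abs_pearson(X[:, j], X[:, s]) for s in selected])
                if scheme == "quotient":
                    val = relevance[j] / max(red, REDUNDANCY_EPS)
                else:
                    val = relevance[j] - red
            if best_val is None or val > best_val:  # strict > keeps lowest index
                best_j, best_val = j, val
        selected.append(best_j)
    return selected


def random_selections(
    rng: np.random.Generator, n_folds: int, n_features: int
) -> list[SelectorOutput]:
    """Random but valid per-(fold, method) selections."""
    out = []
    for fold in range(n_folds):
        for method in ("lasso", "mrmr"):
            size = int(rng.integers(0, n_features + 1))
            chosen = rng.choice(n_features, size=size, replace=False)
            out.append(
                SelectorOutput(
                    method=method,
                    fold_index=fold,
                    selected=tuple(int(c) for c in chosen),
                    scores=tuple(float(s) for s in rng.random(size) + 0.01),
                )
            )
    return out
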