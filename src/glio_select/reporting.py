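"""Result export, clustergram computation, and the run manifest.

The clustergram is the standard panel visualisation: per-feature z-scored
intensities, features ordered by hierarchical clustering (average linkage
on correlation distance), samples grouped by class, and a rank bar giving
each panel feature's weight rank (1 = highest accumulated weight).  The
tested surface is the :class:`ClustergramData` structure; rendering it to
an image is a thin optional layer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .classify import MODEL_NAMES, BestResult, SweepReport
from .datasets import OmicsDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ClustergramData",
    "clustergram",
    "linkage_to_text",
    "write_sweep_tsv",
    "read_sweep_tsv",
    "write_best_json",
    "write_clustergram_data",
    "write_run_manifest",
]

#: correlation distance assigned to pairs involving a constant feature
_MAX_CORR_DISTANCE = 2.0


@dataclass(frozen=True)
class ClustergramData:
    """Everything needed to draw a clustergram of a selected panel.

    ``z_matrix`` is features x samples (per-feature z-scores); rows follow
    ``panel_features``.  ``feature_order`` is the dendrogram leaf order as
    indices into ``panel_features``; ``sample_order`` puts class-0 samples
    first, preserving within-class order.  ``rank_bar[i]`` is the weight
    rank (1 = highest) of ``panel_features[i]``.
    """

    panel_features: tuple[str, ...]
    z_matrix: np.ndarray
    feature_order: tuple[int, ...]
    feature_linkage: np.ndarray
    sample_order: tuple[int, ...]
    rank_bar: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.feature_order) != list(range(len(self.panel_features))):
            raise ValueError("feature_order must be a permutation of the panel")
        if sorted(self.rank_bar) != list(range(1, len(self.panel_features) + 1)):
            raise ValueError("rank_bar must be the unique ranks 1..n")


def _zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row z-score; constant rows become zeros (flagged)."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd_safe
    z[constant] = 0.0
    return z, constant


def clustergram(ds: OmicsDataset, panel: list[str]) -> ClustergramData:
    """Compute clustergram data for an ordered feature panel.

    ``panel`` lists feature names in weight-rank order (rank 1 first).
    Features are clustered with average linkage on correlation distance
    (1 - Pearson r); the result is invariant to the input feature
    permutation because distances are computed over a name-sorted canonical
    order.  Constant features get a zero z-row (logged) and maximal
    distance to every other feature.
    """
    if len(panel) < 2:
        raise ValueError("clustergram needs at least 2 features")
    missing = [p for p in panel if p not in ds.feature_names]
    if missing:
        raise ValueError(f"panel features not in dataset: {missing[:5]}")
    name_to_col = {n: j for j, n in enumerate(ds.feature_names)}

    # canonical name-sorted order makes the linkage permutation-invariant
    canon = sorted(range(len(panel)), key=lambda i: panel[i])
    values = ds.values[:, [name_to_col[panel[i]] for i in canon]].T
    z, constant = _zscore_rows(values)
    if constant.any():
        logger.warning(
            "%d constant feature(s) in panel; z-rows set to zero", constant.sum()
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(z)
    dist = 1.0 - corr
    bad = constant[:, None] | constant[None, :]
    dist[bad] = _MAX_CORR_DISTANCE
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, _MAX_CORR_DISTANCE)
    Z = linkage(squareform(dist, checks=False), method="average")
    leaf_order = [canon[i] for i in leaves_list(Z)]

    sample_order = np.concatenate(
        [np.flatnonzero(ds.labels == 0), np.flatnonzero(ds.labels == 1)]
    )
    # undo the canonical permutation so z rows follow the panel order
    inv = np.argsort(canon)
    return ClustergramData(
        panel_features=tuple(panel),
        z_matrix=z[inv],
        feature_order=tuple(int(i) for i in leaf_order),
        feature_linkage=Z,
        sample_order=tuple(int(i) for i in sample_order),
        rank_bar=tuple(range(1, len(panel) + 1)),
    )


def linkage_to_text(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a linkage matrix as a nested bracket expression with heights.

    Each merge renders as ``(left,right):height``; leaves render as their
    labels.  The output is a plain-text, diff-able record of the tree.
    """
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    for m, (a, b, height, _) in enumerate(Z):
        nodes[n + m] = f"({nodes[int(a)]},{nodes[int(b)]}):{height:.6g}"
    return nodes[n + len(Z) - 1] if len(Z) else labels[0]


def write_sweep_tsv(
    report: SweepReport, path: str | Path, feature_names: list[str] | None = None
) -> Path:
    """Write the sweep table (accuracies as percentages, 3 decimals)."""
    path = Path(path)
    df = report.to_frame(feature_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path


def read_sweep_tsv(path: str | Path) -> pd.DataFrame:
    """Re-parse an exported sweep table."""
    return pd.read_csv(path, sep="\t")


def write_best_json(best: BestResult, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "assignment": best.assignment,
        "k": best.k,
        "model": best.model,
        "n_features": best.n_features,
        "mean_accuracy": round(best.mean_accuracy, 6),
        "mean_accuracy_pct": round(100.0 * best.mean_accuracy, 3),
        "feature_names": list(best.feature_names),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_clustergram_data(data: ClustergramData, outdir: str | Path) -> dict[str, Path]:
    """Write z-matrix, leaf order, rank bar, and linkage text to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    z_path = outdir / "clustergram_z.tsv"
    pd.DataFrame(
        data.z_matrix,
        index=list(data.panel_features),
        columns=[f"sample_{i}" for i in range(data.z_matrix.shape[1])],
    ).to_csv(z_path, sep="\t", index_label="feature")
    order_path = outdir / "clustergram_order.tsv"
    pd.DataFrame(
        {
            "leaf_position": range(len(data.feature_order)),
            "feature_name": [data.panel_features[i] for i in data.feature_order],
            "rank": [data.rank_bar[i] for i in data.feature_order],
        }
    ).to_csv(order_path, sep="\t", index=False)
    linkage_path = outdir / "clustergram_linkage.txt"
    linkage_path.write_text(
        linkage_to_text(data.feature_linkage, list(data.panel_features)) + "\n"
    )
    return {"z_matrix": z_path, "order": order_path, "linkage": linkage_path}


def write_run_manifest(
    path: str | Path,
    config: dict,
    label_mapping: dict | None = None,
    tie_break_log: list[str] | None = None,
    extra: dict | None = None,
) -> Path:
    """Emit a JSON manifest sufficient to reproduce the run bit-exactly."""
    import importlib.metadata as md

    versions = {}
    for pkg in ("numpy", "scipy", "pandas", "scikit-learn", "glio-select"):
        try:
            versions[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            versions[pkg] = "unknown"
    payload = {
        "config": config,
        "versions": versions,
        "label_mapping": label_mapping or config.get("label_mapping", {}),
        "tie_break_log": tie_break_log or [],
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def render_clustergram(data: ClustergramData, path: str | Path):  # pragma: no cover
    """Optional image rendering (heatmap + rank bar); requires matplotlib.

    Colour limits are clipped to [-3, 3] z-units for display only; exported
    data are unclipped.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(data.feature_order)
    z = np.clip(data.z_matrix[order][:, list(data.sample_order)], -3, 3)
    fig, (ax_bar, ax_hm) = plt.subplots(
        1, 2, figsize=(10, 0.4 * len(order) + 2), width_ratios=[1, 20]
    )
    ranks = np.array([data.rank_bar[i] for i in order])
    ax_bar.imshow(ranks[:, None], aspect="auto", cmap="Greys")
    ax_bar.set_xticks([])
    ax_bar.set_yticks(range(len(order)))
    ax_bar.set_yticklabels([data.panel_features[i] for i in order], fontsize=7)
    im = ax_hm.imshow(z, aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax_hm.set_yticks([])
    ax_hm.set_xlabel("samples (class 0 then class 1)")
    fig.colorbar(im, ax=ax_hm, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
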