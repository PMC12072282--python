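"""Seeded synthetic-data generators.

The generators produce datasets with the statistical structure the pipeline
assumes — a binary class label, a handful of planted class-associated
features, and a large majority of uninformative ones — so every stage can
be exercised and the planted ground truth recovered, without any external
download.  Continuous data mimic serum proteomic intensity panels (default
class imbalance 68/32 across roughly a hundred samples and thousands of
features); binary data mimic per-gene mutation-status tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import OmicsDataset

__all__ = ["ContinuousSpec", "BinarySpec", "generate_continuous", "generate_binary"]


@dataclass(frozen=True)
class ContinuousSpec:
    """Parameters of the continuous-intensity generator.

    ``n_informative`` features carry a between-class mean shift of
    ``effect_size`` standard-deviation units; the rest are pure noise.
    Optional correlated blocks (equicorrelation ``block_rho`` within each of
    ``n_corr_blocks`` consecutive 10-feature blocks) emulate the highly
    correlated feature groups typical of omics panels.  ``lognormal``
    exponentiates the Gaussian field so intensities are strictly positive
    and the log2 preprocessing path is exercised.
    """

    n_samples: int = 109
    n_features: int = 7289
    n_informative: int = 17
    class_share: float = 0.68  # fraction of samples in class 1
    effect_size: float = 2.0  # mean shift in SD units
    n_corr_blocks: int = 0
    block_rho: float = 0.0
    block_size: int = 10
    noise_sd: float = 1.0
    lognormal: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.class_share < 1:
            raise ValueError("class_share must be in (0, 1)")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_corr_blocks * self.block_size > self.n_features:
            raise ValueError("correlated blocks exceed n_features")


@dataclass(frozen=True)
class BinarySpec:
    """Parameters of the mutation-indicator generator.

    Informative features are Bernoulli with rate ``baseline_rate`` in class
    0 and ``baseline_rate + informative_delta`` in class 1; uninformative
    features use ``baseline_rate`` in both classes.
    """

    n_samples: int = 352
    n_features: int = 20
    n_informative: int = 3
    class_share: float = 0.62
    baseline_rate: float = 0.3
    informative_delta: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.class_share < 1:
            raise ValueError("class_share must be in (0, 1)")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        for r in (self.baseline_rate, self.baseline_rate + self.informative_delta):
            if not 0 <= r <= 1:
                raise ValueError("rates and rate+delta must lie in [0, 1]")


def _labels(n_samples: int, class_share: float) -> np.ndarray:
    """Deterministic label vector matching class_share exactly (rounded)."""
    n1 = int(round(n_samples * class_share))
    n1 = min(max(n1, 1), n_samples - 1)
    return np.concatenate([np.zeros(n_samples - n1, dtype=int), np.ones(n1, dtype=int)])


def generate_continuous(
    spec: ContinuousSpec = ContinuousSpec(), seed: int = 0
) -> tuple[OmicsDataset, set[int]]:
    """Generate a continuous dataset plus the planted-feature ground truth.

    Informative features occupy the first ``n_informative`` columns (class-
    dependent mean shift); correlated blocks, when requested, occupy the
    following columns.  Bit-identical for a fixed (spec, seed).
    """
    rng = np.random.default_rng(seed)
    y = _labels(spec.n_samples, spec.class_share)
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_features))
    truth = set(range(spec.n_informative))
    shift = spec.effect_size * spec.noise_sd
    X[:, : spec.n_informative] += np.outer(y, np.ones(spec.n_informative)) * shift
    # equicorrelated blocks: shared factor sqrt(rho), idiosyncratic sqrt(1-rho)
    for b in range(spec.n_corr_blocks):
        lo = spec.n_informative + b * spec.block_size
        hi = lo + spec.block_size
        factor = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        X[:, lo:hi] = np.sqrt(spec.block_rho) * factor[:, None] + np.sqrt(
            1 - spec.block_rho
        ) * X[:, lo:hi]
    if spec.lognormal:
        X = np.exp(X)
    ds = OmicsDataset(
        sample_ids=[f"S{i:04d}" for i in range(spec.n_samples)],
        feature_names=[f"feat_{j:05d}" for j in range(spec.n_features)],
        values=X,
        labels=y,
        value_kind="continuous",
        label_mapping={"female": 0, "male": 1},
    )
    return ds, truth


def generate_binary(
    spec: BinarySpec = BinarySpec(), seed: int = 0
) -> tuple[OmicsDataset, set[int]]:
    """Generate a {0,1} mutation-indicator dataset plus ground truth."""
    rng = np.random.default_rng(seed)
    y = _labels(spec.n_samples, spec.class_share)
    rates = np.full((spec.n_samples, spec.n_features), spec.baseline_rate)
    truth = set(range(spec.n_informative))
    rates[y == 1, : spec.n_informative] += spec.informative_delta
    X = (rng.random(size=rates.shape) < rates).astype(float)
    ds = OmicsDataset(
        sample_ids=[f"S{i:04d}" for i in range(spec.n_samples)],
        feature_names=[f"gene_{j:03d}" for j in range(spec.n_features)],
        values=X,
        labels=y,
        value_kind="binary",
        label_mapping={"female": 0, "male": 1},
    )
    return ds, truth
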