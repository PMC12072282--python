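import numpy as np
import pytest

from glio_select import ContinuousSpec, OmicsDataset, generate_continuous


@pytest.fixture(scope="session")
def planted_small():
    """60 samples x 120 features, 5 planted at a strong (3 SD) shift."""
    ds, truth = generate_continuous(
        ContinuousSpec(
            n_samples=60, n_features=120, n_informative=5, effect_size=3.0
        ),
        seed=11,
    )
    return ds, truth


@pytest.fixture()
def tiny_dataset():
    """10 samples x 4 features with a perfectly separating first feature."""
    rng = np.random.default_rng(5)
    y = np.array([0, 1] * 5)
    X = rng.normal(size=(10, 4))
    X[:, 0] = y.astype(float)
    return OmicsDataset(
        sample_ids=[f"s{i}" for i in range(10)],
        feature_names=["sep", "a", "b", "c"],
        values=X,
        labels=y,
    )
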