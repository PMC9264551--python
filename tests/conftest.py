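import numpy as np
import pytest

from bbbuq.models import ModelSpec, train_classifier
from bbbuq.synthetic import FixtureConfig, corrupt_records, make_benchmark_records


@pytest.fixture(scope="session")
def blob_data():
    """Linearly separable two-class Gaussian blobs."""
    rng = np.random.default_rng(42)
    n = 120
    x_pos = rng.normal(loc=2.0, scale=0.5, size=(n, 8))
    x_neg = rng.normal(loc=-2.0, scale=0.5, size=(n, 8))
    X = np.vstack([x_pos, x_neg])
    y = np.array([1] * n + [0] * n)
    return X, y


@pytest.fixture(scope="session")
def small_mlp(blob_data):
    """A small trained MLP used by dropout/latent tests."""
    X, y = blob_data
    spec = ModelSpec(
        family="mlp",
        feature_kind="pcp",
        hyperparameters={"hidden_layer_sizes": (16, 8), "max_iter": 300},
        dropout_rate=0.2,
    )
    return train_classifier(spec, X, y, seed=0)


@pytest.fixture(scope="session")
def fixture_cfg():
    return FixtureConfig(n_molecules=150, seed=11)


@pytest.fixture(scope="session")
def fixture_records(fixture_cfg):
    records, truth = make_benchmark_records(fixture_cfg)
    return records, truth


@pytest.fixture(scope="session")
def library2000():
    """Full-size fixture library with labels (shared; generation is slow)."""
    from bbbuq.synthetic import assign_synthetic_labels, generate_library

    cfg = FixtureConfig(n_molecules=2000, seed=17)
    smiles = generate_library(cfg)
    labels, truth = assign_synthetic_labels(smiles, cfg)
    return smiles, labels, truth


@pytest.fixture(scope="session")
def corrupted_fixture(fixture_cfg, fixture_records):
    records, _ = fixture_records
    entries, truth = corrupt_records(records, fixture_cfg)
    return entries, truth
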