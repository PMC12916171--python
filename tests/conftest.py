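import numpy as np
import pytest

from grnlag.data_io import split_samples
from grnlag.delay import default_window_config
from grnlag.model import ModelConfig
from grnlag.pipeline import RunConfig, featurize_pairs, preprocess
from grnlag.synthetic import SyntheticConfig, simulate_dataset

# a deliberately small planted-edge instance: fast enough for training tests
SMALL = SyntheticConfig(
    n_genes=24, n_cells=240, n_tfs=5, n_edges=12, lag_range=(4, 20),
    effect=1.0, noise_sd=0.5, smoothness=40.0, seed=3,
)


def tiny_model_config(**overrides) -> ModelConfig:
    """A scaled-down classifier that trains in seconds on SMALL features."""
    base = dict(
        gru_units=8, conv_filters=[4, 2], dense_sizes=[16, 1],
        epochs=25, patience=6, batch_size=8, seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def small_data():
    return simulate_dataset(SMALL)


@pytest.fixture(scope="session")
def small_features(small_data):
    """Preprocessed, featurized and split pairs of the SMALL instance."""
    expr, gold = small_data
    cfg = RunConfig(seed=3, top_n=SMALL.n_genes)
    expr2, gold2, samples = preprocess(expr, gold, cfg)
    window = default_window_config(expr2.n_cells)
    feats = featurize_pairs(expr2, samples, window, cfg)
    fmap = {(f.tf_id, f.target_id): f for f in feats}
    tr, va, te = split_samples(samples, seed=3)
    return {
        "window": window,
        "train": [fmap[(s.tf_id, s.target_id)] for s in tr],
        "val": [fmap[(s.tf_id, s.target_id)] for s in va],
        "test": [fmap[(s.tf_id, s.target_id)] for s in te],
        "all": feats,
        "gold": gold2,
        "expr": expr2,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
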