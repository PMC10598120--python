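import numpy as np
import pytest

import tripletgene as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """60 samples x 80 genes, clearly separable, unnormalized."""
    return tg.generate(
        tg.SyntheticConfig(
            n_samples=60, n_genes=80, n_informative=20, effect_size=2.0, seed=7
        )
    )


@pytest.fixture
def tiny_train_val(small_dataset):
    ds = tg.normalize_features(small_dataset)
    tr, va, _ = tg.train_val_test_split(ds, (0.6, 0.2, 0.2), seed=3)
    return tr, va


@pytest.fixture
def fast_training_config():
    return tg.TrainingConfig(
        n_triplets=400, batch_size=100, max_epochs=10, patience=5,
        min_semi_hard=10, seed=5,
    )
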