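import numpy as np
import pytest

import rpinet as rp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """60+60 planted-rule pairs with structures; shared across tests."""
    config = rp.SyntheticConfig(n_rna=60, n_protein=60, n_positive=60,
                                rna_length_range=(50, 150),
                                protein_length_range=(50, 150), seed=7)
    return rp.simulate_dataset_with_structures(config)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    from rpinet.model import PairFeatures

    return PairFeatures.from_dataset(small_dataset)


@pytest.fixture
def fast_config():
    """Tiny training schedule for unit tests of the training machinery."""
    from rpinet.model import ModuleConfig

    return ModuleConfig(max_epochs_adam=2, max_epochs_sgd=1, patience=2,
                        sae_pretrain_epochs=3, batch_size=32, seed=5)
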