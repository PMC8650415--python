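import numpy as np
import pytest

from epa import AaeConfig, SyntheticSpec, make_pcm_dataset, train_pcm_aae


@pytest.fixture(scope="session")
def pcm_balanced():
    """Balanced 500-row synthetic set with entity structure for splitting."""
    spec = SyntheticSpec(n_pos=250, n_neg=250, dim=60, latent_dim=8,
                         n_compounds=60, n_kinases=30, seed=11)
    ds, manifest = make_pcm_dataset(spec)
    return ds, manifest


@pytest.fixture(scope="session")
def pcm_imbalanced_small():
    """Small 1:4 imbalanced set (low dim for fast model fits)."""
    spec = SyntheticSpec(n_pos=60, n_neg=240, dim=40, latent_dim=8,
                         n_compounds=40, n_kinases=20, seed=5)
    ds, manifest = make_pcm_dataset(spec)
    return ds, manifest


@pytest.fixture(scope="session")
def tiny_aae():
    """A quickly trained AAE on low-dimensional synthetic positives."""
    spec = SyntheticSpec(n_pos=150, n_neg=0, dim=60, latent_dim=8,
                         label_range_pos=(6.5, 10.5), n_compounds=30,
                         n_kinases=10, seed=3)
    positives, _ = make_pcm_dataset(spec)
    config = AaeConfig(iterations=400, latent_dim=8, encoder_layers=[48],
                       decoder_layers=[48], generator_layers=[32],
                       discriminator_layers=[32], seed=1)
    return positives, train_pcm_aae(positives, config)
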