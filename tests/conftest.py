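import numpy as np
import pytest

import omicvae as ov


@pytest.fixture(scope="session")
def small_dataset():
    """120-sample, 3-view synthetic dataset with full ground truth."""
    spec = ov.SyntheticSpec(
        n_samples=120,
        view_features=(20, 15, 10),
        latent_dim=4,
        mcar_rate=0.1,
        view_absence_rate=0.0,
        seed=2,
    )
    return ov.generate(spec)


@pytest.fixture(scope="session")
def small_config():
    return ov.ModelConfig(
        joint_latent_dim=6,
        batch_size=64,
        view_latent_cap=32,
        learning_rate=1e-3,
        dropout_p=0.1,
        seed=1,
    )


@pytest.fixture(scope="session")
def trained_model(small_dataset, small_config):
    """A briefly trained VAE shared across tests that need a fitted network."""
    dataset, _ = small_dataset
    model = ov.MultiOmicVAE(dataset, small_config)
    results = model.fit(epochs=30)
    return model, results
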