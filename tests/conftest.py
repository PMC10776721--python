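import numpy as np
import pytest

from fedmdl.clustergan import (LatentPrior, LossConfig, assign_domains,
                               federated_train_clustergan)
from fedmdl.federated import TrainConfig
from fedmdl.synthetic import SyntheticConfig, generate_federation


@pytest.fixture(scope="session")
def small_federation():
    """High-SNR 4-client federation with 2 true domains (fast fixture)."""
    return generate_federation(SyntheticConfig(
        n_clients=4, n_domains_true=2, samples_per_client=60,
        image_size=16, noise_sd=0.05, seed=5))


@pytest.fixture(scope="session")
def three_domain_federation():
    """High-SNR 4-client federation with 3 true domains."""
    return generate_federation(SyntheticConfig(
        n_clients=4, n_domains_true=3, samples_per_client=120,
        image_size=16, noise_sd=0.05, seed=11))


@pytest.fixture(scope="session")
def trained_gan(three_domain_federation):
    """A briefly trained federated ClusterGAN at the true K."""
    prior = LatentPrior(K=3)
    cfg = TrainConfig(learning_rate=5e-4, batch_size=32, max_rounds=3,
                      early_stop_patience=3, seed=11)
    model = federated_train_clustergan(three_domain_federation.clients, prior,
                                       LossConfig(), cfg, epochs=2)
    return model


@pytest.fixture(scope="session")
def trained_assignment(trained_gan, three_domain_federation):
    return assign_domains(trained_gan, three_domain_federation.clients, 3, seed=11)
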