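import numpy as np
import pytest

from rbpdeep.network import NetConfig, build_model, stack_bundles, train
from rbpdeep.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200-sample planted-motif dataset shared across tests."""
    cfg = SimConfig(n_pos=100, n_neg=100, motif_strength=1.0, seed=20)
    bundles, labels, truth = generate_dataset(cfg)
    return bundles, labels, truth


@pytest.fixture(scope="session")
def small_inputs(small_dataset):
    bundles, labels, truth = small_dataset
    return stack_bundles(bundles), np.asarray(labels), truth


@pytest.fixture(scope="session")
def tiny_net_config():
    """A fast architecture for plumbing tests (not for learning checks)."""
    return NetConfig(nb_filter=8, filter_length=7, cnn_dense=16,
                     hidden_sizes={"region_type": (16, 8), "cobinding": (16, 8),
                                   "structure": (16, 8), "motif": (16, 8)},
                     merge_hidden=16, max_epochs=3, batch_size=50, seed=5)


@pytest.fixture(scope="session")
def trained_tiny_model(small_inputs, tiny_net_config):
    """A small model trained briefly on the planted dataset."""
    X, y, _ = small_inputs
    model = build_model(tiny_net_config)
    train(model, {k: v[:150] for k, v in X.items()}, y[:150],
          {k: v[150:] for k, v in X.items()}, y[150:], tiny_net_config)
    return model
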