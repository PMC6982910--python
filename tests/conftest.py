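from __future__ import annotations

import numpy as np
import pytest

from bruxsense.classify import (
    NetworkConfig,
    TrainConfig,
    build_network,
    make_session_blocks,
    save_checkpoint,
    train,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


class TrainedModel:
    """Desk-scale classifier trained once per session on separable blocks:
    width/4 network, batch 32, 30 epochs, 300 simulated sessions."""

    def __init__(self, tmp_dir):
        self.x, self.y, self.standardizer = make_session_blocks(100, seed=7)
        self.net_config = NetworkConfig(width_divisor=4, seed=7)
        self.train_config = TrainConfig(batch_size=32, epochs=30, seed=7)
        net = build_network(self.net_config)
        self.network, self.history = train(net, self.x, self.y,
                                           self.train_config)
        self.path = tmp_dir / "model.ckpt"
        save_checkpoint(self.network, self.path, self.standardizer)

    def __iter__(self):  # (path, net, std, history) unpacking
        return iter((self.path, self.network, self.standardizer,
                     self.history))


@pytest.fixture(scope="session")
def trained_model(tmp_path_factory):
    return TrainedModel(tmp_path_factory.mktemp("model"))
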