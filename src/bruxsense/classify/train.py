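"""Momentum-SGD training, prediction and checkpointing for the classifier."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..features import Standardizer
from .layers import cross_entropy_with_grad, softmax
from .network import Network, NetworkConfig, build_network

__all__ = [
    "TrainConfig", "AdjustmentLevel", "altitude_of", "group_split",
    "train", "predict_level", "save_checkpoint", "load_checkpoint",
]

_ALTITUDES = {0: -0.5, 1: 0.0, 2: 0.5}


@dataclass(frozen=True)
class TrainConfig:
    """Reference training procedure: momentum 0.9, batch 128, 80/20 split."""

    momentum: float = 0.9
    batch_size: int = 128
    learning_rate: float = 0.01
    epochs: int = 30
    seed: int = 0
    train_groups: int = 80
    test_groups: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.train_groups < 1 or self.test_groups < 0:
            raise ValueError("invalid group split")


@dataclass(frozen=True)
class AdjustmentLevel:
    """One of three grades, each mapped to a 0.5 mm adjustment altitude."""

    level: int
    altitude: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.level not in _ALTITUDES:
            raise ValueError("level must be one of {0, 1, 2}")
        if self.altitude != _ALTITUDES[self.level]:
            raise ValueError("altitude does not match level")


def altitude_of(level: int) -> float:
    """Adjustment altitude in millimetres: 0 -> -0.5, 1 -> 0, 2 -> +0.5."""
    try:
        return _ALTITUDES[level]
    except KeyError:
        raise ValueError(f"level must be one of {{0, 1, 2}}, got {level}") from None


def group_split(groups: np.ndarray, cfg: TrainConfig,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/test sample indices split at the group level.

    Groups are shuffled and allotted to the training side in the
    ``train_groups : test_groups`` ratio (at least one test group when
    ``test_groups`` > 0).
    """
    uniq = np.unique(groups)
    order = rng.permutation(uniq)
    frac = cfg.train_groups / (cfg.train_groups + cfg.test_groups)
    n_train = int(round(frac * len(uniq)))
    if cfg.test_groups > 0:
        n_train = min(n_train, len(uniq) - 1)
    train_g = set(order[:n_train].tolist())
    mask = np.array([g in train_g for g in groups])
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def _evaluate(network: Network, x: np.ndarray, y: np.ndarray,
              batch: int = 256) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = network.forward(x[i:i + batch], training=False)
        loss, _ = cross_entropy_with_grad(logits, y[i:i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(network: Network, x: np.ndarray, y: np.ndarray,
          cfg: TrainConfig | None = None,
          groups: np.ndarray | None = None) -> tuple[Network, list[dict]]:
    """Minimize cross-entropy with momentum SGD; deterministic given seed.

    ``groups`` assigns each sample to a collection group; the train/test
    split is drawn at the group level in the configured 80/20 ratio (one
    group per sample when omitted).  The learning rate decays by 10x at
    two-thirds of the epochs.  Returns the trained network and a per-epoch
    history of train/test loss and accuracy.
    """
    if cfg is None:
        cfg = TrainConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("dataset must contain more than one class")
    if groups is None:
        groups = np.arange(len(y))

    rng = np.random.default_rng(cfg.seed)
    tr_idx, te_idx = group_split(np.asarray(groups), cfg, rng)
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_te, y_te = x[te_idx], y[te_idx]

    params = network.model.parameters()
    grads = network.model.gradients()
    velocity = [np.zeros_like(p) for p in params]
    decay_epoch = max(1, (2 * cfg.epochs) // 3)

    history: list[dict] = []
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate * (0.1 if epoch >= decay_epoch else 1.0)
        order = rng.permutation(len(x_tr))
        epoch_loss, n_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            logits = network.forward(x_tr[sel], training=True)
            loss, glogits = cross_entropy_with_grad(logits, y_tr[sel])
            network.model.backward(glogits)
            for p, g, v in zip(params, grads, velocity):
                v *= cfg.momentum
                v -= lr * g
                p += v
            epoch_loss += loss * len(sel)
            n_correct += int((logits.argmax(axis=1) == y_tr[sel]).sum())
        rec = {"epoch": epoch,
               "train_loss": epoch_loss / len(x_tr),
               "train_acc": n_correct / len(x_tr)}
        if len(x_te):
            rec["test_loss"], rec["test_acc"] = _evaluate(network, x_te, y_te)
        history.append(rec)

    network.trained = True
    network.history = history
    return network, history


def predict_level(network: Network, block: np.ndarray) -> AdjustmentLevel:
    """Argmax over the three logits; ties break toward level 1 (no change)."""
    if not network.trained:
        warnings.warn("predicting with an untrained network", stacklevel=2)
    logits = network.forward(block, training=False)[0]
    probs = softmax(logits[None])[0]
    best = logits.max()
    tied = np.flatnonzero(logits == best)
    level = 1 if 1 in tied else int(tied[0])
    return AdjustmentLevel(level=level, altitude=altitude_of(level),
                           confidence=float(probs[level]))


def save_checkpoint(network: Network, path: str | Path,
                    standardizer: Standardizer | None = None) -> None:
    """Single-file checkpoint: weights plus embedded JSON configuration."""
    payload = network.state()
    if standardizer is not None:
        payload["standardizer"] = standardizer.to_dict()
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[Network, Standardizer | None]:
    payload = json.loads(Path(path).read_text())
    network = build_network(NetworkConfig.from_dict(payload["config"]))
    network.load_state(payload)
    std = None
    if "standardizer" in payload:
        std = Standardizer.from_dict(payload["standardizer"])
    return network, std
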