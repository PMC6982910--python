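"""The 1-D bottleneck-residual classification network.

Stage layout (channel widths row for row):

    Conv1d 16->32, MaxPool, Bottleneck(32->32) x6,
    Conv1d 32->64, MaxPool, Bottleneck(64->64) x6,
    Conv1d 64->128, MaxPool, Bottleneck(128->128) x6,
    Conv1d 128->256, MaxPool, GlobalAvgPool,
    FullyConnected 256->64, FullyConnected 64->3.

Each bottleneck is an inverted residual (pointwise expand, depthwise,
pointwise project, batch-normalized, ReLU6 on the first two stages) with an
identity shortcut.  A ``width_divisor`` shrinks every internal width for
desk-scale training while keeping the row structure intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm1d,
    Bottleneck1d,
    Conv1d,
    GlobalAvgPool1d,
    Linear,
    MaxPool1d,
    ReLU6,
    Sequential,
    softmax,
)

__all__ = ["NetworkConfig", "Network", "build_network", "REFERENCE_STAGES"]

# canonical (operator, in, out, repeats) rows
REFERENCE_STAGES: tuple[tuple[str, int, int, int], ...] = (
    ("conv", 16, 32, 1), ("maxpool", 32, 32, 1), ("bottleneck", 32, 32, 6),
    ("conv", 32, 64, 1), ("maxpool", 64, 64, 1), ("bottleneck", 64, 64, 6),
    ("conv", 64, 128, 1), ("maxpool", 128, 128, 1),
    ("bottleneck", 128, 128, 6),
    ("conv", 128, 256, 1), ("maxpool", 256, 256, 1), ("gap", 256, 256, 1),
    ("fc", 256, 64, 1), ("fc", 64, 3, 1),
)


@dataclass(frozen=True)
class NetworkConfig:
    """Layer configuration; widths must match the reference rows."""

    stages: tuple[tuple[str, int, int, int], ...] = REFERENCE_STAGES
    expansion: int = 4
    kernel_size: int = 3
    activation: str = "relu6"
    width_divisor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_divisor < 1:
            raise ValueError("width_divisor must be >= 1")
        if self.activation != "relu6":
            raise ValueError("only ReLU6 activation is supported")
        if self.expansion < 1 or self.kernel_size < 1:
            raise ValueError("expansion and kernel_size must be >= 1")
        for i, (row, ref) in enumerate(zip(self.stages, REFERENCE_STAGES)):
            if tuple(row) != ref:
                raise ValueError(
                    f"stage row {i} {row!r} deviates from the reference "
                    f"configuration {ref!r}")
        if len(self.stages) != len(REFERENCE_STAGES):
            raise ValueError("stage list must have exactly "
                             f"{len(REFERENCE_STAGES)} rows")

    def scaled(self, width: int, *, is_input: bool = False,
               is_output: bool = False) -> int:
        """Internal widths shrink by the divisor; I/O widths never do."""
        if is_input or is_output:
            return width
        return max(1, width // self.width_divisor)

    def to_dict(self) -> dict:
        return {"expansion": self.expansion, "kernel_size": self.kernel_size,
                "activation": self.activation,
                "width_divisor": self.width_divisor, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(expansion=d["expansion"], kernel_size=d["kernel_size"],
                   activation=d["activation"],
                   width_divisor=d["width_divisor"], seed=d["seed"])


@dataclass
class Network:
    """A built model: forward pass (batch, 16, length) -> (batch, 3) logits."""

    config: NetworkConfig
    model: Sequential
    trained: bool = False
    history: list = field(default_factory=list)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        self.model.set_training(training)
        return self.model.forward(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.model.parameters()))

    # -- persistence -------------------------------------------------------

    def state(self) -> dict:
        params = [p.tolist() for p in self.model.parameters()]
        bn = [{"mean": l.running_mean.tolist(), "var": l.running_var.tolist()}
              for l in self.model.iter_layers() if isinstance(l, BatchNorm1d)]
        return {"config": self.config.to_dict(), "params": params,
                "bn_state": bn, "trained": self.trained}

    def load_state(self, state: dict) -> None:
        for p, saved in zip(self.model.parameters(), state["params"],
                            strict=True):
            p[...] = np.asarray(saved, dtype=float)
        bns = [l for l in self.model.iter_layers()
               if isinstance(l, BatchNorm1d)]
        for layer, saved in zip(bns, state["bn_state"], strict=True):
            layer.running_mean = np.asarray(saved["mean"], dtype=float)
            layer.running_var = np.asarray(saved["var"], dtype=float)
        self.trained = bool(state.get("trained", True))


def build_network(cfg: NetworkConfig | None = None) -> Network:
    """Assemble the network row for row from its configuration."""
    if cfg is None:
        cfg = NetworkConfig()
    rng = np.random.default_rng(cfg.seed)
    layers = []
    n_rows = len(cfg.stages)
    for i, (op, c_in, c_out, repeats) in enumerate(cfg.stages):
        s_in = cfg.scaled(c_in, is_input=(i == 0))
        s_out = cfg.scaled(c_out, is_output=(i == n_rows - 1))
        if op == "conv":
            layers += [Conv1d(s_in, s_out, cfg.kernel_size, rng, bias=False),
                       BatchNorm1d(s_out), ReLU6()]
        elif op == "maxpool":
            layers.append(MaxPool1d())
        elif op == "bottleneck":
            for _ in range(repeats):
                layers.append(Bottleneck1d(s_in, s_out, rng,
                                           expansion=cfg.expansion,
                                           kernel=cfg.kernel_size))
        elif op == "gap":
            layers.append(GlobalAvgPool1d())
        elif op == "fc":
            layers.append(Linear(s_in, s_out, rng))
            if i < n_rows - 1:
                layers.append(ReLU6())
        else:  # pragma: no cover - guarded by NetworkConfig validation
            raise ValueError(f"unknown operator {op!r} in row {i}")
    return Network(config=cfg, model=Sequential(*layers))
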