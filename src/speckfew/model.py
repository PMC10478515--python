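"""Embedding network and the threshold-classifier baseline.

The embedder maps a single-channel speckle image to a point on the unit
hypersphere in d dimensions (d = 128 by default): two 5x5 valid
convolutions, each followed by ReLU, batch normalization and 2x2/stride-2
max pooling, then two fully connected layers and an explicit L2
normalization. On a 96x96 input the spatial chain is
96 -> 92 -> 46 -> 42 -> 21.

The baseline is the classic CNN-plus-MLP binary hit classifier: the same
convolutional trunk with a two-layer head producing P(single-hit), with a
decision threshold (0.9 in the reference protocol).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

__all__ = ["ModelConfig", "Embedder", "BinaryBaseline", "save_checkpoint",
           "load_checkpoint", "init_weights"]


@dataclass(frozen=True)
class ModelConfig:
    conv1_out_channels: int = 32
    conv2_out_channels: int = 32
    fc_hidden: int = 512
    embed_dim: int = 128
    input_size: int = 96
    init_mean: float = 0.0
    init_std: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("conv1_out_channels", "conv2_out_channels", "fc_hidden",
                     "embed_dim", "input_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")


def _spatial_chain(size: int) -> tuple[int, ...]:
    """Spatial sizes through conv(5, valid) -> pool(2) -> conv(5) -> pool(2)."""
    s1 = size - 4
    s2 = s1 // 2
    s3 = s2 - 4
    s4 = s3 // 2
    return size, s1, s2, s3, s4


def _check_input_size(size: int) -> int:
    chain = _spatial_chain(size)
    if chain[-1] < 1 or (size - 4) % 2 or (chain[2] - 4) % 2:
        # minimum even-pooling-compatible size: 16 -> 12 -> 6 -> 2 -> 1
        raise ValueError(
            f"input size {size} too small or pool-incompatible for two valid "
            f"5x5 convolutions with 2x2 pooling; minimum supported size is 16 "
            f"with (size-4) and (size-4)//2-4 both even"
        )
    return chain[-1]


def _conv_trunk(config: ModelConfig) -> list[nn.Layer]:
    return [
        nn.Conv2d(1, config.conv1_out_channels, 5),
        nn.ReLU(),
        nn.BatchNorm(config.conv1_out_channels),
        nn.MaxPool2x2(),
        nn.Conv2d(config.conv1_out_channels, config.conv2_out_channels, 5),
        nn.ReLU(),
        nn.BatchNorm(config.conv2_out_channels),
        nn.MaxPool2x2(),
        nn.Flatten(),
    ]


class _ImageNet:
    """Shared plumbing: batched forward over (N, H, W) image arrays."""

    config: ModelConfig
    net: nn.Sequential

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ValueError("expected (H, W) or (N, H, W) images")
        if x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected {self.config.input_size}x{self.config.input_size} "
                f"images, got {x.shape[1]}x{x.shape[2]}"
            )
        return x[:, None, :, :]

    def state(self) -> dict[str, np.ndarray]:
        return self.net.state()

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state(state)


class Embedder(_ImageNet):
    """Unit-hypersphere embedding network."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        final = _check_input_size(self.config.input_size)
        flat = self.config.conv2_out_channels * final * final
        self.net = nn.Sequential(
            _conv_trunk(self.config)
            + [
                nn.Linear(flat, self.config.fc_hidden),
                nn.ReLU(),
                nn.Linear(self.config.fc_hidden, self.config.embed_dim),
                nn.L2Normalize(),
            ]
        )
        init_weights(self, self.config.seed)

    def embed(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (N, H, W) images to (N, d) unit vectors (deterministic in
        inference mode)."""
        return self.net.forward(self._as_batch(images), train=train)

    def __call__(self, images: np.ndarray) -> np.ndarray:
        return self.embed(images, train=False)


class BinaryBaseline(_ImageNet):
    """CNN + two-FC-layer binary single-hit classifier with a probability
    threshold decision rule."""

    def __init__(self, config: ModelConfig | None = None, threshold: float = 0.9):
        self.config = config or ModelConfig()
        self.threshold = threshold
        final = _check_input_size(self.config.input_size)
        flat = self.config.conv2_out_channels * final * final
        self.net = nn.Sequential(
            _conv_trunk(self.config)
            + [
                nn.Linear(flat, self.config.fc_hidden),
                nn.ReLU(),
                nn.Linear(self.config.fc_hidden, 1),
            ]
        )
        init_weights(self, self.config.seed)

    def logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._as_batch(images), train=train)[:, 0]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """P(single-hit) per image, in [0, 1]."""
        z = np.clip(self.logits(images), -60, 60)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Boolean single-hit decision: P(single-hit) >= threshold."""
        return self.predict_proba(images) >= self.threshold


def init_weights(model: _ImageNet, seed: int) -> None:
    """Gaussian N(init_mean, init_std^2) initialization of all weight
    matrices, deterministic per seed; biases start at zero."""
    rng = np.random.default_rng(seed)
    nn.init_gaussian(model.net, rng, std=model.config.init_std,
                     mean=model.config.init_mean)


def save_checkpoint(path: str, model: _ImageNet, train_seed: int | None = None,
                    extra: dict | None = None) -> None:
    """Single-archive checkpoint: parameters + model config + training seed."""
    meta = {
        "config": asdict(model.config),
        "kind": type(model).__name__,
        "train_seed": train_seed,
        "extra": extra or {},
    }
    if isinstance(model, BinaryBaseline):
        meta["threshold"] = model.threshold
    np.savez(path, __meta__=json.dumps(meta), **model.state())


def load_checkpoint(path: str) -> Embedder | BinaryBaseline:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = ModelConfig(**meta["config"])
    if meta["kind"] == "BinaryBaseline":
        model: Embedder | BinaryBaseline = BinaryBaseline(
            config, threshold=meta.get("threshold", 0.9)
        )
    elif meta["kind"] == "Embedder":
        model = Embedder(config)
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    model.load_state(state)
    return model
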