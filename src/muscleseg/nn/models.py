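"""Network topologies used across pretext tasks and the target segmenter.

One residual encoder family is shared by every task so that weight transfer
by layer name is meaningful: the segmentation target and the auxiliary
segmentation proxy share the entire topology (including the 1-channel
head); the reconstruction autoencoder shares encoder and decoder; the
classifier and the jigsaw solver share only the encoder. Task-specific
heads with different shapes do not transfer.

Default width 8 gives ~35k parameters — trainable on one CPU core in
seconds to minutes at 48-128 px, while preserving the encoder/decoder split
the transfer scheme relies on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    Conv2d,
    GlobalAvgPool,
    Identity,
    InstanceNorm,
    Linear,
    Module,
    ReLU,
    ResBlock,
    Sequential,
    UpsampleNearest,
)

__all__ = [
    "NetConfig",
    "Encoder",
    "Decoder",
    "SegmentationNet",
    "AutoencoderNet",
    "ClassifierNet",
    "JigsawNet",
    "build_model",
]


@dataclass
class NetConfig:
    width: int = 8          # stem channels; stages use w, 2w, 4w
    in_channels: int = 3
    jigsaw_hidden: int = 64
    use_norm: bool = False  # optional instance normalization after convs

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        return cls(**d)


class Encoder(Module):
    """stem -> stride-2 stage (2w) -> stride-2 stage (4w); output H/4 x W/4."""

    def __init__(self, cfg: NetConfig, rng):
        w = cfg.width
        norm = lambda: InstanceNorm() if cfg.use_norm else Identity()
        self.stem = Conv2d(cfg.in_channels, w, 3, rng=rng)
        self.stem_norm = norm()
        self.stem_relu = ReLU()
        self.down1 = Conv2d(w, 2 * w, 3, stride=2, rng=rng)
        self.down1_norm = norm()
        self.down1_relu = ReLU()
        self.block1 = ResBlock(2 * w, rng=rng, use_norm=cfg.use_norm)
        self.down2 = Conv2d(2 * w, 4 * w, 3, stride=2, rng=rng)
        self.down2_norm = norm()
        self.down2_relu = ReLU()
        self.block2 = ResBlock(4 * w, rng=rng, use_norm=cfg.use_norm)

    def forward(self, x):
        x = self.stem_relu(self.stem_norm(self.stem(x)))
        x = self.block1(self.down1_relu(self.down1_norm(self.down1(x))))
        return self.block2(self.down2_relu(self.down2_norm(self.down2(x))))

    def backward(self, dy):
        dy = self.down2.backward(
            self.down2_norm.backward(self.down2_relu.backward(self.block2.backward(dy)))
        )
        dy = self.down1.backward(
            self.down1_norm.backward(self.down1_relu.backward(self.block1.backward(dy)))
        )
        return self.stem.backward(self.stem_norm.backward(self.stem_relu.backward(dy)))


class Decoder(Module):
    """Two nearest-upsample + conv stages back to full resolution, w channels."""

    def __init__(self, cfg: NetConfig, rng):
        w = cfg.width
        norm = lambda: InstanceNorm() if cfg.use_norm else Identity()
        self.up1 = UpsampleNearest(2)
        self.conv1 = Conv2d(4 * w, 2 * w, 3, rng=rng)
        self.norm1 = norm()
        self.relu1 = ReLU()
        self.up2 = UpsampleNearest(2)
        self.conv2 = Conv2d(2 * w, w, 3, rng=rng)
        self.norm2 = norm()
        self.relu2 = ReLU()

    def forward(self, x):
        x = self.relu1(self.norm1(self.conv1(self.up1(x))))
        return self.relu2(self.norm2(self.conv2(self.up2(x))))

    def backward(self, dy):
        dy = self.up2.backward(
            self.conv2.backward(self.norm2.backward(self.relu2.backward(dy)))
        )
        return self.up1.backward(
            self.conv1.backward(self.norm1.backward(self.relu1.backward(dy)))
        )


class SegmentationNet(Module):
    """Encoder-decoder with a 1-channel logit head; the transfer target."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.head = Conv2d(cfg.width, 1, 1, rng=rng)

    def forward(self, x):
        return self.head(self.decoder(self.encoder(x)))

    def backward(self, dy):
        return self.encoder.backward(self.decoder.backward(self.head.backward(dy)))


class AutoencoderNet(Module):
    """Same encoder/decoder topology, 3-channel reconstruction head."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.recon_head = Conv2d(cfg.width, cfg.in_channels, 1, rng=rng)

    def forward(self, x):
        return self.recon_head(self.decoder(self.encoder(x)))

    def backward(self, dy):
        return self.encoder.backward(
            self.decoder.backward(self.recon_head.backward(dy))
        )


class ClassifierNet(Module):
    """Encoder + global average pool + linear class head."""

    def __init__(self, cfg: NetConfig, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, rng)
        self.pool = GlobalAvgPool()
        self.fc = Linear(4 * cfg.width, n_classes, rng=rng)

    def forward(self, x):
        return self.fc(self.pool(self.encoder(x)))

    def backward(self, dy):
        return self.encoder.backward(self.pool.backward(self.fc.backward(dy)))


class JigsawNet(Module):
    """Siamese permutation solver: nine weight-shared encoder branches.

    Each patch passes through the single shared encoder; pooled features of
    the nine branches are concatenated and classified into the permutation
    index. Gradients from all branches accumulate into the shared weights.
    """

    def __init__(self, cfg: NetConfig, n_permutations: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, rng)
        self.fc1 = Linear(9 * 4 * cfg.width, cfg.jigsaw_hidden, rng=rng)
        self.fc_relu = ReLU()
        self.fc2 = Linear(cfg.jigsaw_hidden, n_permutations, rng=rng)
        self._feat_dim = 4 * cfg.width

    def forward(self, patches: np.ndarray) -> np.ndarray:
        """patches: (N, 9, C, h, w) -> logits (N, n_permutations)."""
        n = patches.shape[0]
        flat = patches.reshape(n * 9, *patches.shape[2:])
        feats = self.encoder(flat)  # one shared pass over all branches
        self._fshape = feats.shape
        pooled = feats.mean(axis=(2, 3)).reshape(n, 9 * self._feat_dim)
        return self.fc2(self.fc_relu(self.fc1(pooled)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dpooled = self.fc1.backward(self.fc_relu.backward(self.fc2.backward(dy)))
        n9, c, h, w = self._fshape
        dfeats = np.broadcast_to(
            dpooled.reshape(n9, c)[:, :, None, None], self._fshape
        ) / (h * w)
        return self.encoder.backward(np.ascontiguousarray(dfeats))


def build_model(task: str, cfg: NetConfig, seed: int = 0, n_classes: int = 2):
    """Factory keyed by pretext-task name."""
    if task in ("segmentation", "random_init", "target"):
        return SegmentationNet(cfg, seed)
    if task == "reconstruction":
        return AutoencoderNet(cfg, seed)
    if task == "classification":
        return ClassifierNet(cfg, n_classes, seed)
    if task == "jigsaw":
        return JigsawNet(cfg, n_classes, seed)
    raise ValueError(f"unknown task {task!r}")
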