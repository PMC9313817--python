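"""Weight transfer, the combined segmentation loss, fine-tuning, prediction.

Transfer copies a source parameter into the target network iff both the
layer name and the array shape match; every other target layer is freshly
initialized. The fine-tuning schedule follows the transfer outcome: initial
Adam learning rate 3e-3 when nothing was transferred (training from
scratch), 3e-4 when fine-tuning transferred features. The training loss is
the sum of binary cross-entropy and soft Dice, averaged over the batch, and
the checkpoint is taken at the epoch of minimum validation loss.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import RunDescriptor, derive_seed
from .nn import Adam, NetConfig, SegmentationNet, fan_in_uniform
from .preprocess import AugmentConfig, ModelInput, augment
from .types import BinaryMask
from .weights import NamedWeights

EPS = 1e-7

__all__ = [
    "TransferReport",
    "TrainConfig",
    "TrainingRun",
    "transfer_weights",
    "bce_loss",
    "dice_loss",
    "combined_loss",
    "bce_dice_logits",
    "fine_tune",
    "predict",
    "sigmoid",
]


# ---------------------------------------------------------------- losses


def bce_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Binary cross-entropy, normalized by pixel count (mean over H*W).

    Accepts a single (H, W) pair or batched (N, H, W) arrays; batched input
    returns the mean of the per-sample losses. Probabilities are clamped to
    [EPS, 1-EPS] so exact 0/1 predictions stay finite.
    """
    p = np.clip(np.asarray(predictions, dtype=float), EPS, 1 - EPS)
    y = np.asarray(targets, dtype=float)
    per_pixel = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    if per_pixel.ndim == 2:
        return float(per_pixel.mean())
    return float(per_pixel.mean(axis=(1, 2)).mean())


def dice_loss(prediction: np.ndarray, target: np.ndarray) -> float:
    """Soft Dice loss 1 - 2|P·Y| / (|P|+|Y|), with EPS guarding empty masks."""
    p = np.asarray(prediction, dtype=float)
    y = np.asarray(target, dtype=float)
    num = 2.0 * (p * y).sum()
    den = p.sum() + y.sum() + EPS
    return float(1.0 - num / den)


def combined_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Batch mean of per-sample (BCE + Dice)."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    if p.ndim == 2:
        p, y = p[None], y[None]
    vals = [bce_loss(pi, yi) + dice_loss(pi, yi) for pi, yi in zip(p, y)]
    return float(np.mean(vals))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_dice_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Combined loss and its gradient w.r.t. logits, for training.

    logits: (N, 1, H, W); targets: (N, H, W) in {0,1}. Returns the batch
    loss (mean over samples of BCE + Dice) and d(loss)/d(logits).
    """
    z = logits[:, 0]
    y = np.asarray(targets, dtype=float)
    n, h, w = z.shape
    p = sigmoid(z)
    pc = np.clip(p, EPS, 1 - EPS)

    bce = -(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean(axis=(1, 2))
    inter = (p * y).sum(axis=(1, 2))
    den = p.sum(axis=(1, 2)) + y.sum(axis=(1, 2)) + EPS
    dice = 1.0 - 2.0 * inter / den
    loss = float((bce + dice).mean())

    dbce = (p - y) / (h * w)
    # d dice/dp = -(2 y den - 2 inter) / den^2
    ddice_dp = -(2.0 * y * den[:, None, None] - 2.0 * inter[:, None, None]) / (
        den[:, None, None] ** 2
    )
    dz = (dbce + ddice_dp * p * (1 - p)) / n
    return loss, dz[:, None]


# ---------------------------------------------------------------- transfer


@dataclass
class TransferReport:
    matched: list[str]
    unmatched_target: list[str]
    unmatched_source: list[str]
    learning_rate: float = 0.0


def transfer_weights(
    source: NamedWeights | None,
    target_shapes: dict[str, tuple],
    seed: int = 0,
) -> tuple[NamedWeights, TransferReport]:
    """Initialize target parameters from a source by name-and-shape match.

    A target layer receives the source array iff the name exists in the
    source *and* the shapes agree; a name match with a shape mismatch is
    recorded as unmatched (not fatal). All unmatched target layers get fresh
    seeded initialization: fan-in-scaled uniform for weights, zeros for 1-D
    parameters (biases).
    """
    rng = np.random.default_rng(seed)
    src = source.entries if source is not None else {}
    entries: dict[str, np.ndarray] = {}
    matched, unmatched_t = [], []
    for name, shape in target_shapes.items():
        shape = tuple(shape)
        if name in src and tuple(src[name].shape) == shape:
            entries[name] = src[name].copy()
            matched.append(name)
        else:
            if len(shape) >= 2:
                entries[name] = fan_in_uniform(shape, rng)
            else:
                entries[name] = np.zeros(shape)
            unmatched_t.append(name)
    unmatched_s = [k for k in src if k not in matched]
    report = TransferReport(
        matched=matched, unmatched_target=unmatched_t, unmatched_source=unmatched_s
    )
    init = NamedWeights(
        entries=entries,
        source_task=source.source_task if source is not None else "random_init",
    )
    return init, report


# ---------------------------------------------------------------- fine-tune


@dataclass
class TrainConfig:
    net: NetConfig = field(default_factory=NetConfig)
    max_epochs: int = 150
    patience: int = 20
    batch_size: int = 8
    lr_scratch: float = 3e-3
    lr_transfer: float = 3e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.0
    use_augmentation: bool = True
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    freeze_transferred: bool = False

    def to_dict(self) -> dict:
        return {
            "net": self.net.to_dict(),
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "batch_size": self.batch_size,
            "lr_scratch": self.lr_scratch,
            "lr_transfer": self.lr_transfer,
            "betas": list(self.betas),
            "weight_decay": self.weight_decay,
            "use_augmentation": self.use_augmentation,
            "augment": self.augment.to_dict(),
            "freeze_transferred": self.freeze_transferred,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["net"] = NetConfig.from_dict(d["net"])
        d["augment"] = AugmentConfig.from_dict(d["augment"])
        d["betas"] = tuple(d["betas"])
        return cls(**d)


@dataclass
class TrainingRun:
    descriptor: RunDescriptor | None
    train_loss: list[float]
    val_loss: list[float]
    checkpoint: NamedWeights
    best_epoch: int
    converged: bool


class NonFiniteLossError(RuntimeError):
    pass


def _stack_batch(items, indices):
    xs = np.stack([items[i][0].channels for i in indices])
    ys = np.stack([items[i][1].labels.astype(float) for i in indices])
    return xs, ys


def fine_tune(
    init: NamedWeights,
    report: TransferReport,
    train_data: list[tuple[ModelInput, BinaryMask]],
    val_data: list[tuple[ModelInput, BinaryMask]],
    config: TrainConfig,
    seed: int,
    descriptor: RunDescriptor | None = None,
) -> TrainingRun:
    """Fine-tune the target segmenter on a training subset.

    Learning rate is selected by the transfer report (scratch vs transfer),
    augmentation is re-drawn every epoch, and training stops when the
    validation loss has not improved for ``patience`` epochs or at the
    epoch cap. The returned checkpoint is the state at minimum validation
    loss.
    """
    if not train_data or not val_data:
        raise ValueError("train and validation sets must be non-empty")
    net = SegmentationNet(config.net, seed=derive_seed(seed, "net"))
    net.load_state_dict(init.entries)
    params = net.named_parameters()
    if config.freeze_transferred and report.matched:
        params = {k: p for k, p in params.items() if k not in set(report.matched)}
    lr = config.lr_scratch if len(report.matched) == 0 else config.lr_transfer
    opt = Adam(params, lr=lr, betas=config.betas, weight_decay=config.weight_decay)
    report.learning_rate = lr

    rng = np.random.default_rng(derive_seed(seed, "loop"))
    val_x = np.stack([inp.channels for inp, _ in val_data])
    val_y = np.stack([m.labels.astype(float) for _, m in val_data])

    train_hist: list[float] = []
    val_hist: list[float] = []
    best_val = np.inf
    best_state = net.state_dict()
    best_epoch = -1
    converged = True

    for epoch in range(config.max_epochs):
        if config.use_augmentation:
            epoch_data = [
                augment(inp, m, derive_seed(seed, "aug", epoch, i), config.augment)
                for i, (inp, m) in enumerate(train_data)
            ]
        else:
            epoch_data = train_data
        order = rng.permutation(len(epoch_data))
        ep_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, ys = _stack_batch(epoch_data, idx)
            net.zero_grad()
            logits = net(xs)
            loss, dz = bce_dice_logits(logits, ys)
            if not np.isfinite(loss):
                raise NonFiniteLossError(
                    f"non-finite training loss at epoch {epoch} (lr={lr})"
                )
            net.backward(dz)
            opt.step()
            ep_losses.append(loss)
        train_hist.append(float(np.mean(ep_losses)))

        vloss, _ = bce_dice_logits(net(val_x), val_y)
        if not np.isfinite(vloss):
            raise NonFiniteLossError(f"non-finite validation loss at epoch {epoch}")
        val_hist.append(float(vloss))
        if vloss < best_val:
            best_val = vloss
            best_state = net.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    else:
        converged = best_epoch < config.max_epochs - config.patience

    checkpoint = NamedWeights(entries=best_state, source_task=init.source_task)
    return TrainingRun(
        descriptor=descriptor,
        train_loss=train_hist,
        val_loss=val_hist,
        checkpoint=checkpoint,
        best_epoch=best_epoch,
        converged=converged,
    )


def predict(
    checkpoint: NamedWeights,
    inp: ModelInput,
    net_config: NetConfig,
    spacing: tuple[float, float],
) -> BinaryMask:
    """Sigmoid of the network logits, thresholded at 0.5 (>= is foreground)."""
    net = SegmentationNet(net_config, seed=0)
    net.load_state_dict(checkpoint.entries)
    logits = net(inp.channels[None])[0, 0]
    labels = (sigmoid(logits) >= 0.5).astype(np.uint8)
    return BinaryMask(labels=labels, spacing=spacing, role="prediction")
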