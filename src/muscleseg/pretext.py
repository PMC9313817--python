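"""Pretext pre-training: reconstruction, jigsaw, classification, segmentation.

Four source tasks produce transferable weights for the target segmenter:

* reconstruction — an autoencoder reproducing the (3-channel, normalized)
  CT slices under mean-squared error;
* jigsaw — a Siamese solver predicting which of a fixed permutation set
  shuffled the 3x3 patch grid of a slice (self-supervised);
* classification — an encoder + linear head trained on image-level labels
  supplied by the phantom generator (a desk-scale stand-in for natural-image
  classification pre-training; externally trained weights can be loaded
  through the same NamedWeights interface);
* segmentation — an encoder-decoder segmenting a *different* structure
  (the fat compartment) on an auxiliary cohort, emulating a related-but-
  different dense source task.

The jigsaw permutation set keeps the ``count`` most mutually different
permutations: starting from the permutation farthest (by Hamming distance)
from the identity, candidates maximizing mean Hamming distance to the
already-selected set are added greedily, ties broken lexicographically.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .design import derive_seed
from .nn import Adam, AutoencoderNet, ClassifierNet, JigsawNet, NetConfig, SegmentationNet
from .preprocess import ModelInput
from .training import NonFiniteLossError, bce_dice_logits
from .types import BinaryMask
from .weights import NamedWeights

__all__ = [
    "PermutationSet",
    "JigsawSample",
    "build_permutation_set",
    "make_jigsaw_sample",
    "train_jigsaw",
    "train_autoencoder",
    "train_classification_proxy",
    "train_segmentation_proxy",
]


# ------------------------------------------------------------- permutations


@dataclass
class PermutationSet:
    permutations: list[tuple[int, ...]]
    grid_shape: tuple[int, int] = (3, 3)
    selection_trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.grid_shape[0] * self.grid_shape[1]
        seen = set()
        for p in self.permutations:
            if sorted(p) != list(range(n)):
                raise ValueError(f"not a bijection on 0..{n-1}: {p}")
            if p in seen:
                raise ValueError(f"duplicate permutation {p}")
            seen.add(p)

    def __len__(self) -> int:
        return len(self.permutations)

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "permutations": [list(p) for p in self.permutations],
            "selection_trace": self.selection_trace,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PermutationSet":
        return cls(
            permutations=[tuple(p) for p in d["permutations"]],
            grid_shape=tuple(d["grid_shape"]),
            selection_trace=d.get("selection_trace", []),
        )


def build_permutation_set(
    grid: tuple[int, int] = (3, 3), count: int = 50, seed: int = 0
) -> PermutationSet:
    """Greedy max-mean-Hamming selection of patch permutations.

    Deterministic: the seed permutation is the lexicographically first one at
    maximum Hamming distance from the identity, and every later step adds the
    lexicographically first candidate among those maximizing the mean Hamming
    distance to the selected set. ``seed`` is accepted for interface symmetry
    but the selection itself is deterministic.
    """
    n = grid[0] * grid[1]
    if count <= 0:
        raise ValueError("count must be positive")
    total = math.factorial(n)
    if count > total:
        raise ValueError(f"count {count} exceeds {n}! = {total}")

    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
    identity = np.arange(n, dtype=np.int8)
    d_id = (perms != identity).sum(axis=1)
    first = int(np.flatnonzero(d_id == d_id.max())[0])  # lexicographically first

    selected = [first]
    dist_sum = (perms != perms[first]).sum(axis=1).astype(np.int64)
    available = np.ones(len(perms), dtype=bool)
    available[first] = False
    trace = [{"step": 0, "chosen": perms[first].tolist(), "mean_hamming": None}]

    for step in range(1, count):
        scores = np.where(available, dist_sum, -1)
        best = scores.max()
        cand = int(np.flatnonzero(scores == best)[0])  # lexicographic tie-break
        selected.append(cand)
        available[cand] = False
        trace.append(
            {
                "step": step,
                "chosen": perms[cand].tolist(),
                "mean_hamming": float(best / step),
            }
        )
        dist_sum += (perms != perms[cand]).sum(axis=1)

    return PermutationSet(
        permutations=[tuple(int(v) for v in perms[i]) for i in selected],
        grid_shape=grid,
        selection_trace=trace,
    )


# ------------------------------------------------------------- jigsaw data


@dataclass
class JigsawSample:
    patches: np.ndarray  # (9, C, h, w), in shuffled order
    label: int


def _tile(channels: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Split (C, H, W) into grid tiles, padding at the bottom/right if needed."""
    gr, gc = grid
    c, h, w = channels.shape
    ph, pw = -h % gr, -w % gc
    if ph or pw:
        channels = np.pad(channels, ((0, 0), (0, ph), (0, pw)), mode="edge")
    h2, w2 = channels.shape[1] // gr, channels.shape[2] // gc
    tiles = [
        channels[:, i * h2 : (i + 1) * h2, j * w2 : (j + 1) * w2]
        for i in range(gr)
        for j in range(gc)
    ]
    return np.stack(tiles)


def make_jigsaw_sample(inp: ModelInput, pset: PermutationSet, seed: int) -> JigsawSample:
    """Shuffle the patch grid by a uniformly drawn permutation from the set.

    ``patches[i] = tiles[perm[i]]``; applying the inverse permutation to the
    shuffled patches restores reading order.
    """
    rng = np.random.default_rng(seed)
    label = int(rng.integers(len(pset)))
    perm = pset.permutations[label]
    tiles = _tile(inp.channels, pset.grid_shape)
    patches = tiles[list(perm)]
    return JigsawSample(patches=patches, label=label)


def reassemble(sample: JigsawSample, pset: PermutationSet) -> np.ndarray:
    """Invert the shuffle: returns tiles back in reading order."""
    perm = pset.permutations[sample.label]
    inv = np.empty(len(perm), dtype=int)
    inv[list(perm)] = np.arange(len(perm))
    return sample.patches[inv]


# ------------------------------------------------------------- training loops


def _check_finite(loss: float, task: str, epoch: int) -> None:
    if not np.isfinite(loss):
        raise NonFiniteLossError(f"{task}: non-finite loss at epoch {epoch}")


def _softmax_ce(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dz = p.copy()
    dz[np.arange(n), labels] -= 1.0
    return loss, dz / n


@dataclass
class PretrainResult:
    weights: NamedWeights
    loss_history: list[float]
    final_metric: float  # task-dependent: accuracy or MSE


def _epoch_batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def train_jigsaw(
    cohort: list[ModelInput],
    pset: PermutationSet,
    net_config: NetConfig | None = None,
    seed: int = 0,
    epochs: int = 15,
    batch_size: int = 8,
    lr: float = 1e-3,
) -> PretrainResult:
    """Train the Siamese permutation solver; returns branch-encoder weights."""
    if len(pset) < 2:
        raise ValueError("need at least 2 permutation classes")
    cfg = net_config or NetConfig()
    samples = [
        make_jigsaw_sample(inp, pset, derive_seed(seed, "jig", i))
        for i, inp in enumerate(cohort)
    ]
    x = np.stack([s.patches for s in samples])
    y = np.array([s.label for s in samples])
    net = JigsawNet(cfg, n_permutations=len(pset), seed=derive_seed(seed, "net"))
    opt = Adam(net.named_parameters(), lr=lr)
    rng = np.random.default_rng(derive_seed(seed, "loop"))
    hist = []
    for epoch in range(epochs):
        losses = []
        for idx in _epoch_batches(len(x), batch_size, rng):
            net.zero_grad()
            loss, dz = _softmax_ce(net(x[idx]), y[idx])
            _check_finite(loss, "jigsaw", epoch)
            net.backward(dz)
            opt.step()
            losses.append(loss)
        hist.append(float(np.mean(losses)))
    acc = float((net(x).argmax(axis=1) == y).mean())
    enc = NamedWeights(
        entries={k: v for k, v in net.state_dict().items() if k.startswith("encoder.")},
        source_task="jigsaw",
    )
    return PretrainResult(weights=enc, loss_history=hist, final_metric=acc)


def train_autoencoder(
    cohort: list[ModelInput],
    net_config: NetConfig | None = None,
    seed: int = 0,
    epochs: int = 15,
    batch_size: int = 8,
    lr: float = 1e-3,
) -> PretrainResult:
    """Reconstruction autoencoder under MSE; returns encoder weights."""
    if not cohort:
        raise ValueError("empty cohort")
    cfg = net_config or NetConfig()
    x = np.stack([inp.channels for inp in cohort])
    net = AutoencoderNet(cfg, seed=derive_seed(seed, "net"))
    opt = Adam(net.named_parameters(), lr=lr)
    rng = np.random.default_rng(derive_seed(seed, "loop"))
    hist = []
    for epoch in range(epochs):
        losses = []
        for idx in _epoch_batches(len(x), batch_size, rng):
            xb = x[idx]
            net.zero_grad()
            out = net(xb)
            diff = out - xb
            loss = float((diff**2).mean())
            _check_finite(loss, "reconstruction", epoch)
            net.backward(2.0 * diff / diff.size)
            opt.step()
            losses.append(loss)
        hist.append(float(np.mean(losses)))
    final_mse = float(((net(x) - x) ** 2).mean())
    enc = NamedWeights(
        entries={k: v for k, v in net.state_dict().items() if k.startswith("encoder.")},
        source_task="reconstruction",
    )
    return PretrainResult(weights=enc, loss_history=hist, final_metric=final_mse)


def train_classification_proxy(
    cohort: list[ModelInput],
    labels: list[int],
    net_config: NetConfig | None = None,
    seed: int = 0,
    epochs: int = 15,
    batch_size: int = 8,
    lr: float = 1e-3,
) -> PretrainResult:
    """Image-level classification on generator-provided labels; encoder weights."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    remap = {c: i for i, c in enumerate(classes)}
    y = np.array([remap[v] for v in y])
    cfg = net_config or NetConfig()
    x = np.stack([inp.channels for inp in cohort])
    net = ClassifierNet(cfg, n_classes=len(classes), seed=derive_seed(seed, "net"))
    opt = Adam(net.named_parameters(), lr=lr)
    rng = np.random.default_rng(derive_seed(seed, "loop"))
    hist = []
    for epoch in range(epochs):
        losses = []
        for idx in _epoch_batches(len(x), batch_size, rng):
            net.zero_grad()
            loss, dz = _softmax_ce(net(x[idx]), y[idx])
            _check_finite(loss, "classification", epoch)
            net.backward(dz)
            opt.step()
            losses.append(loss)
        hist.append(float(np.mean(losses)))
    acc = float((net(x).argmax(axis=1) == y).mean())
    enc = NamedWeights(
        entries={k: v for k, v in net.state_dict().items() if k.startswith("encoder.")},
        source_task="classification",
    )
    return PretrainResult(weights=enc, loss_history=hist, final_metric=acc)


def train_segmentation_proxy(
    aux_cohort: list[tuple[ModelInput, BinaryMask]],
    net_config: NetConfig | None = None,
    seed: int = 0,
    epochs: int = 15,
    batch_size: int = 8,
    lr: float = 1e-3,
    target_ids: set[str] | None = None,
) -> PretrainResult:
    """Dense segmentation of an auxiliary structure; full encoder-decoder weights.

    The auxiliary cohort must be disjoint from the experiment's cohort;
    passing ``target_ids`` enables the overlap check.
    """
    if not aux_cohort:
        raise ValueError("empty auxiliary cohort")
    if target_ids is not None:
        overlap = {inp.provenance for inp, _ in aux_cohort} & set(target_ids)
        if overlap:
            raise ValueError(f"auxiliary cohort overlaps target cohort: {sorted(overlap)[:5]}")
    cfg = net_config or NetConfig()
    x = np.stack([inp.channels for inp, _ in aux_cohort])
    y = np.stack([m.labels.astype(float) for _, m in aux_cohort])
    net = SegmentationNet(cfg, seed=derive_seed(seed, "net"))
    opt = Adam(net.named_parameters(), lr=lr)
    rng = np.random.default_rng(derive_seed(seed, "loop"))
    hist = []
    for epoch in range(epochs):
        losses = []
        for idx in _epoch_batches(len(x), batch_size, rng):
            net.zero_grad()
            loss, dz = bce_dice_logits(net(x[idx]), y[idx])
            _check_finite(loss, "segmentation-proxy", epoch)
            net.backward(dz)
            opt.step()
            losses.append(loss)
        hist.append(float(np.mean(losses)))
    final_loss, _ = bce_dice_logits(net(x), y)
    # the full network is returned: the target segmenter shares the whole
    # topology (including the 1-channel head), and every layer present in
    # both source and target transfers
    weights = NamedWeights(entries=net.state_dict(), source_task="segmentation")
    return PretrainResult(weights=weights, loss_history=hist, final_metric=float(final_loss))
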