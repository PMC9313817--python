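"""HU windowing, three-channel conversion, and training-time augmentation.

The CT slice is clipped to a soft-tissue window (full width 400 HU centred at
level 50 HU), rescaled to [0, 1], replicated across three channels, and each
channel standardised — by default with the ImageNet per-channel statistics,
matching the convention of networks pre-trained on natural images.
Augmentation applies the same geometric transform to image and mask:
horizontal flips, rotations up to ±20°, elastic deformation, and scaling,
each independently with probability 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import BinaryMask, CTSlice

IMAGENET_MEANS = (0.485, 0.456, 0.406)
IMAGENET_SDS = (0.229, 0.224, 0.225)

__all__ = [
    "ModelInput",
    "AugmentConfig",
    "window_level",
    "to_model_input",
    "from_model_input",
    "augment",
    "IMAGENET_MEANS",
    "IMAGENET_SDS",
]


@dataclass
class ModelInput:
    """Three-channel normalized network input derived from one windowed slice."""

    channels: np.ndarray  # (3, H, W)
    provenance: str = ""
    applied_transforms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.float64)
        if ch.ndim != 3 or ch.shape[0] != 3:
            raise ValueError(f"channels must be (3, H, W), got {ch.shape}")
        if not np.all(np.isfinite(ch)):
            raise ValueError("non-finite channel values")
        self.channels = ch

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


def window_level(ct: CTSlice | np.ndarray, window: float = 400.0, level: float = 50.0) -> np.ndarray:
    """Clip HU to [level - window/2, level + window/2] and rescale to [0, 1]."""
    if window <= 0:
        raise ValueError("window must be > 0")
    hu = ct.pixels if isinstance(ct, CTSlice) else np.asarray(ct, dtype=float)
    lo = level - window / 2.0
    return np.clip((hu - lo) / window, 0.0, 1.0)


def to_model_input(
    windowed: np.ndarray,
    channel_means=IMAGENET_MEANS,
    channel_sds=IMAGENET_SDS,
    provenance: str = "",
) -> ModelInput:
    """Replicate a windowed image over 3 channels and standardise each channel."""
    windowed = np.asarray(windowed, dtype=float)
    means = np.asarray(channel_means, dtype=float)
    sds = np.asarray(channel_sds, dtype=float)
    if np.any(sds <= 0):
        raise ValueError("channel SDs must be > 0")
    channels = (windowed[None, :, :] - means[:, None, None]) / sds[:, None, None]
    return ModelInput(channels=channels, provenance=provenance)


def from_model_input(
    inp: ModelInput, channel_means=IMAGENET_MEANS, channel_sds=IMAGENET_SDS
) -> np.ndarray:
    """Invert :func:`to_model_input`; returns the windowed image (channel 0)."""
    means = np.asarray(channel_means, dtype=float)
    sds = np.asarray(channel_sds, dtype=float)
    return inp.channels[0] * sds[0] + means[0]


@dataclass
class AugmentConfig:
    p_flip: float = 0.5
    p_rotate: float = 0.5
    max_rotation_deg: float = 20.0
    p_elastic: float = 0.5
    elastic_grid_px: int = 16
    elastic_sd_px: float = 2.0
    p_scale: float = 0.5
    scale_range: tuple[float, float] = (0.9, 1.1)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["scale_range"] = list(self.scale_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        d = dict(d)
        if "scale_range" in d:
            d["scale_range"] = tuple(d["scale_range"])
        return cls(**d)


def _elastic_field(shape, grid_px: int, sd_px: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random displacement field from a coarse control grid."""
    h, w = shape
    gh = max(2, h // grid_px + 1)
    gw = max(2, w // grid_px + 1)
    coarse = rng.normal(scale=sd_px, size=(2, gh, gw))
    zoom = (h / gh, w / gw)
    dy = ndimage.zoom(coarse[0], zoom, order=3)[:h, :w]
    dx = ndimage.zoom(coarse[1], zoom, order=3)[:h, :w]
    return dy, dx


def _warp(img: np.ndarray, dy: np.ndarray, dx: np.ndarray, order: int) -> np.ndarray:
    h, w = img.shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([yy + dy, xx + dx])
    return ndimage.map_coordinates(img, coords, order=order, mode="nearest")


def augment(
    inp: ModelInput,
    mask: BinaryMask,
    seed: int,
    config: AugmentConfig | None = None,
) -> tuple[ModelInput, BinaryMask]:
    """Apply one random geometric transform pipeline to an image-mask pair.

    Images are resampled bilinearly, masks nearest-neighbour so they remain
    binary. The same draw drives both, keeping image and mask aligned.
    """
    cfg = config or AugmentConfig()
    if inp.shape != mask.shape:
        raise ValueError(f"shape mismatch: {inp.shape} vs {mask.shape}")
    rng = np.random.default_rng(seed)
    img = inp.channels.copy()
    lab = mask.labels.astype(float)
    applied: list[str] = []

    if rng.random() < cfg.p_flip:
        img = img[:, :, ::-1].copy()
        lab = lab[:, ::-1].copy()
        applied.append("hflip")

    if rng.random() < cfg.p_rotate:
        angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        img = np.stack(
            [ndimage.rotate(c, angle, reshape=False, order=1, mode="nearest") for c in img]
        )
        lab = ndimage.rotate(lab, angle, reshape=False, order=0, mode="nearest")
        applied.append(f"rotate:{angle:.2f}")

    if rng.random() < cfg.p_elastic:
        dy, dx = _elastic_field(lab.shape, cfg.elastic_grid_px, cfg.elastic_sd_px, rng)
        img = np.stack([_warp(c, dy, dx, order=1) for c in img])
        lab = _warp(lab, dy, dx, order=0)
        applied.append("elastic")

    if rng.random() < cfg.p_scale:
        s = rng.uniform(*cfg.scale_range)
        h, w = lab.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.stack([(yy - cy) / s + cy, (xx - cx) / s + cx])
        img = np.stack(
            [ndimage.map_coordinates(c, coords, order=1, mode="nearest") for c in img]
        )
        lab = ndimage.map_coordinates(lab, coords, order=0, mode="nearest")
        applied.append(f"scale:{s:.3f}")

    out_inp = ModelInput(
        channels=img,
        provenance=inp.provenance,
        applied_transforms=inp.applied_transforms + applied,
    )
    out_mask = BinaryMask(
        labels=(lab > 0.5).astype(np.uint8), spacing=mask.spacing, role=mask.role
    )
    return out_inp, out_mask
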