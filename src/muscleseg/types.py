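"""Core domain containers shared by every stage of the pipeline.

All images are 2-D axial CT slices with per-pixel Hounsfield units (HU) and
physical pixel spacing in mm; masks are binary label grids aligned to a slice.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

MaskRole = Literal["ground_truth", "prediction", "observer", "bone"]


@dataclass(frozen=True)
class CTSlice:
    """A single axial CT slice in Hounsfield units.

    Parameters
    ----------
    pixels : (H, W) float array of HU values (water = 0, air ~ -1000).
    spacing : (row, col) pixel size in mm.
    slice_id : opaque identifier used for manifests and fold assignment.
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    slice_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if len(self.spacing) != 2 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", (float(self.spacing[0]), float(self.spacing[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel foreground labels aligned to a :class:`CTSlice`."""

    labels: np.ndarray
    spacing: tuple[float, float]
    role: MaskRole = "ground_truth"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {lab.shape}")
        uniq = np.unique(lab)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask labels must be 0/1")
        object.__setattr__(self, "labels", lab.astype(np.uint8))
        object.__setattr__(self, "spacing", (float(self.spacing[0]), float(self.spacing[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def area_px(self) -> int:
        return int(self.labels.sum())

    def bool(self) -> np.ndarray:
        return self.labels.astype(bool)


@dataclass
class PhantomParams:
    """Generator settings for the synthetic abdominal phantom cohort.

    HU means/SDs describe the per-compartment intensity distributions; the
    invariant ``bone_hu_mean - 2*bone_hu_sd > 175`` keeps bone thresholding
    well posed on average. ``shape_variability`` scales the low-frequency
    radial deformation applied per patient.
    """

    cohort_size: int = 204
    image_side: int = 128
    spacing_mm: float = 3.0
    muscle_hu_mean: float = 45.0
    muscle_hu_sd: float = 10.0
    bone_hu_mean: float = 450.0
    bone_hu_sd: float = 60.0
    fat_hu_mean: float = -100.0
    fat_hu_sd: float = 15.0
    hu_patient_sd: float = 12.0
    shape_variability: float = 0.14
    noise_sd: float = 12.0

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.bone_hu_mean - 2 * self.bone_hu_sd <= 175:
            raise ValueError("bone_hu_mean - 2*bone_hu_sd must exceed 175 HU")
        lo, hi = 50 - 400 / 2, 50 + 400 / 2  # window/level 400/50
        if not (lo < self.muscle_hu_mean < hi):
            raise ValueError("muscle_hu_mean outside the 400/50 soft-tissue window")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        return cls(**d)


@dataclass
class ObserverModel:
    """Boundary-perturbation model of a human delineator.

    The truth boundary is displaced by smooth correlated noise of the given
    amplitude (mm, RMS) and correlation length (mm along the image), plus a
    signed systematic bias (mm; positive = outward).
    """

    boundary_perturbation_amplitude: float = 2.0
    correlation_length: float = 20.0
    systematic_bias: float = 0.0
    observer_id: str = "observer"

    def __post_init__(self) -> None:
        if self.boundary_perturbation_amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverModel":
        return cls(**d)


@dataclass
class MetricRecord:
    """Per-prediction metrics plus the experiment coordinates they belong to."""

    pretext: str
    size: int
    fold: int
    chain: int
    repeat: int
    slice_id: str
    dsc: float
    rms_dta_cm: float
    smd_hu: float
    sma_cm2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError(f"dsc out of [0,1]: {self.dsc}")
        if self.rms_dta_cm < 0:
            raise ValueError("rms_dta must be >= 0")
        if self.sma_cm2 < 0:
            raise ValueError("sma must be >= 0")
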