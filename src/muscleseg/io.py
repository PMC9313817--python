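"""File formats: 2-D NIfTI images/masks, CSV manifests, JSON configs."""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BinaryMask, CTSlice

__all__ = [
    "save_slice",
    "load_slice",
    "save_mask",
    "load_mask",
    "save_cohort",
    "load_cohort",
    "save_json",
    "load_json",
]


def _affine(spacing: tuple[float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], 1.0, 1.0])


def save_slice(ct: CTSlice, path: str | Path) -> None:
    img = nib.Nifti1Image(ct.pixels.astype(np.float32), _affine(ct.spacing))
    nib.save(img, str(path))


def load_slice(path: str | Path, slice_id: str | None = None) -> CTSlice:
    img = nib.load(str(path))
    spacing = (float(img.affine[0, 0]), float(img.affine[1, 1]))
    return CTSlice(
        pixels=np.asarray(img.dataobj, dtype=float),
        spacing=spacing,
        slice_id=slice_id or Path(path).stem.replace(".nii", ""),
    )


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), _affine(mask.spacing))
    nib.save(img, str(path))


def load_mask(path: str | Path, role: str = "ground_truth") -> BinaryMask:
    img = nib.load(str(path))
    spacing = (float(img.affine[0, 0]), float(img.affine[1, 1]))
    return BinaryMask(
        labels=np.asarray(img.dataobj).astype(np.uint8), spacing=spacing, role=role
    )


def save_cohort(cohort, out_dir: str | Path) -> Path:
    """Write (ct, muscle, bone) triplets as NIfTI plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ct, muscle, bone in cohort:
        base = ct.slice_id
        for obj, role, saver in (
            (ct, "ct", save_slice),
            (muscle, "muscle", save_mask),
            (bone, "bone", save_mask),
        ):
            p = out / f"{base}_{role}.nii"
            saver(obj, p)
            rows.append({"slice_id": base, "role": role, "path": p.name})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str | Path):
    manifest = pd.read_csv(manifest_path)
    root = Path(manifest_path).parent
    cohort = []
    for slice_id, grp in manifest.groupby("slice_id", sort=True):
        files = dict(zip(grp["role"], grp["path"]))
        ct = load_slice(root / files["ct"], slice_id=slice_id)
        muscle = load_mask(root / files["muscle"], role="ground_truth")
        bone = load_mask(root / files["bone"], role="bone")
        cohort.append((ct, muscle, bone))
    return cohort


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
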