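"""NIfTI read/write helpers (thin wrappers around nibabel)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_nifti", "load_nifti", "load_mask"]


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (boolean mask, affine)."""
    data, affine = load_nifti(path)
    return data > 0.5, affine


def spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(v) for v in np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0)))
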