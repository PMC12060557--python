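"""NIfTI reading/writing for label and intensity volumes."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np

from .volumetry import STANDARD_LABELS, IntensityVolume, LabelVolume

__all__ = [
    "save_label_volume",
    "load_label_volume",
    "save_intensity_volume",
    "load_intensity_volume",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = voxel_size_mm
    return a


def save_label_volume(labels: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.grid.astype(np.int16), _affine(labels.voxel_size_mm))
    nib.save(img, str(path))


def load_label_volume(
    path: str | Path, label_table: Optional[Mapping[str, int]] = None
) -> LabelVolume:
    img = nib.load(str(path))
    vox = float(img.header.get_zooms()[0])
    grid = np.asarray(img.get_fdata()).round().astype(np.int16)
    return LabelVolume(grid, vox, dict(label_table or STANDARD_LABELS))


def save_intensity_volume(vol: IntensityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.grid.astype(np.float32), _affine(vol.voxel_size_mm))
    nib.save(img, str(path))


def load_intensity_volume(path: str | Path) -> IntensityVolume:
    img = nib.load(str(path))
    vox = float(img.header.get_zooms()[0])
    return IntensityVolume(np.asarray(img.get_fdata(), dtype=float), vox)
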