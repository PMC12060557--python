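"""Structure volumetry from label volumes.

Volumes are voxel counts converted to millilitres; normalized volumes are
structure volume divided by intracranial volume (ICV).  ICV is defined here
as the volume of all labelled (nonzero) voxels — brain tissue plus ventricular
CSF — which is exact on phantoms and reproducible on any externally supplied
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "LabelVolume",
    "IntensityVolume",
    "SubjectVolumes",
    "structure_volume",
    "normalize_to_icv",
    "subject_volumes",
    "STANDARD_LABELS",
]

#: canonical label integers used by the phantom generator; real-data label
#: volumes may use any table as long as the structure names below appear.
STANDARD_LABELS: dict[str, int] = {
    "ventricle_left": 1,
    "ventricle_right": 2,
    "chp_left": 3,
    "chp_right": 4,
    "wm": 5,
    "cortex_gm": 6,
    "lesion": 7,
}


@dataclass
class LabelVolume:
    """3D integer grid assigning each voxel one anatomical label.

    Parameters
    ----------
    grid : ndarray of int
        Label image; 0 is background (extracranial).
    voxel_size_mm : float
        Isotropic voxel edge length in mm.
    label_table : mapping of str -> int
        Structure name (suffixed ``_left``/``_right`` where lateralized) to
        label integer.
    """

    grid: np.ndarray
    voxel_size_mm: float = 1.0
    label_table: Mapping[str, int] = field(default_factory=lambda: dict(STANDARD_LABELS))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"label grid must be 3D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must be an integer array")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        present = set(np.unique(self.grid)) - {0}
        known = set(self.label_table.values())
        unknown = present - known
        if unknown:
            raise ValueError(f"grid contains labels not in label_table: {sorted(unknown)}")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def names(self, structure: str, hemisphere: Optional[str] = None) -> list[str]:
        """Resolve a structure (+ optional hemisphere) to label-table keys."""
        if hemisphere is not None:
            key = f"{structure}_{hemisphere}"
            if key not in self.label_table:
                raise KeyError(
                    f"unknown structure {key!r}; known: {sorted(self.label_table)}"
                )
            return [key]
        if structure in self.label_table:
            return [structure]
        lateral = [f"{structure}_{h}" for h in ("left", "right")]
        if all(k in self.label_table for k in lateral):
            return lateral
        raise KeyError(
            f"unknown structure {structure!r}; known: {sorted(self.label_table)}"
        )

    def mask(self, structure: str, hemisphere: Optional[str] = None) -> np.ndarray:
        """Binary mask of a structure (both hemispheres if lateralized)."""
        keys = self.names(structure, hemisphere)
        out = np.zeros(self.grid.shape, dtype=bool)
        for k in keys:
            out |= self.grid == self.label_table[k]
        return out

    def intracranial_mask(self) -> np.ndarray:
        return self.grid != 0


@dataclass
class IntensityVolume:
    """3D non-negative scalar grid (T1w, FLAIR, calibrated, or ratio)."""

    grid: np.ndarray
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"intensity grid must be 3D, got shape {self.grid.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")


@dataclass
class SubjectVolumes:
    """Per-subject structure volumes (ml) and ICV-normalized fractions."""

    chp_left_ml: float
    chp_right_ml: float
    chp_bilateral_ml: float
    cortex_gm_ml: float
    wm_ml: float
    lesion_ml: float
    lvv_ml: float
    icv_ml: float
    chp_norm: float
    cortex_norm: float
    wm_norm: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def structure_volume(
    labels: LabelVolume, structure: str, hemisphere: Optional[str] = None
) -> float:
    """Volume of a structure in ml (0 ml if the label has no voxels)."""
    m = labels.mask(structure, hemisphere)
    return float(m.sum()) * labels.voxel_volume_ml


def normalize_to_icv(volume_ml: float, icv_ml: float) -> float:
    """Dimensionless structure fraction, volume / ICV."""
    if icv_ml <= 0:
        raise ValueError(f"icv_ml must be positive, got {icv_ml}")
    return volume_ml / icv_ml


_REQUIRED = (
    "chp_left",
    "chp_right",
    "cortex_gm",
    "wm",
    "lesion",
    "ventricle_left",
    "ventricle_right",
)


def subject_volumes(labels: LabelVolume) -> SubjectVolumes:
    """All per-subject volumes used by the cohort statistics.

    Bilateral ChP is the sum of both hemispheres; LVV is the bilateral
    lateral-ventricle volume; ICV is the volume of all labelled voxels.
    """
    missing = [k for k in _REQUIRED if k not in labels.label_table]
    if missing:
        raise KeyError(f"label_table missing required structures: {missing}")
    icv_vox = int(labels.intracranial_mask().sum())
    if icv_vox == 0:
        raise ValueError("no intracranial voxels: all-background label grid")
    vv = labels.voxel_volume_ml
    icv_ml = icv_vox * vv
    chp_l = structure_volume(labels, "chp", "left")
    chp_r = structure_volume(labels, "chp", "right")
    chp = chp_l + chp_r
    cortex = structure_volume(labels, "cortex_gm")
    wm = structure_volume(labels, "wm")
    lesion = structure_volume(labels, "lesion")
    lvv = structure_volume(labels, "ventricle")
    return SubjectVolumes(
        chp_left_ml=chp_l,
        chp_right_ml=chp_r,
        chp_bilateral_ml=chp,
        cortex_gm_ml=cortex,
        wm_ml=wm,
        lesion_ml=lesion,
        lvv_ml=lvv,
        icv_ml=icv_ml,
        chp_norm=normalize_to_icv(chp, icv_ml),
        cortex_norm=normalize_to_icv(cortex, icv_ml),
        wm_norm=normalize_to_icv(wm, icv_ml),
    )
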