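"""T1w/FLAIR ratio images with nonlinear histogram calibration.

Between-subject and between-scanner intensity scales of T1w and FLAIR images
are arbitrary, so raw voxelwise ratios are not comparable across subjects.
Each modality is therefore calibrated to a study template by monotone
piecewise-linear quantile matching inside a lesion-excluded brain-tissue
mask: the subject's within-mask empirical quantiles are mapped onto the
template's quantiles at the same probability levels, and the resulting
monotone transfer function is applied to the whole image (end segments
clamped).  The template itself is the mean of the subjects' quantile
functions over a reference set.  The calibrated T1w image is then divided
voxelwise by the calibrated FLAIR image, with a denominator floor guarding
against division blow-ups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .volumetry import IntensityVolume, LabelVolume

__all__ = [
    "TemplateHistogram",
    "CalibrationMap",
    "RatioVolume",
    "default_quantile_levels",
    "calibration_mask",
    "build_template",
    "calibrate",
    "compute_ratio",
]


def default_quantile_levels(n_levels: int = 101) -> np.ndarray:
    """Evenly spaced probabilities 0, 1/(n-1), ..., 1 (default 0, 0.01, ..., 1)."""
    if n_levels < 2:
        raise ValueError("need at least 2 quantile levels")
    return np.linspace(0.0, 1.0, n_levels)


@dataclass
class TemplateHistogram:
    """Study template for one modality: intensity quantiles at fixed levels."""

    modality: str
    quantile_levels: np.ndarray
    quantile_values: np.ndarray

    def __post_init__(self) -> None:
        self.quantile_levels = np.asarray(self.quantile_levels, dtype=float)
        self.quantile_values = np.asarray(self.quantile_values, dtype=float)
        if self.quantile_levels.ndim != 1 or self.quantile_levels.shape != self.quantile_values.shape:
            raise ValueError("quantile_levels and quantile_values must be matching 1D arrays")
        if not np.all(np.diff(self.quantile_levels) > 0):
            raise ValueError("quantile_levels must be strictly increasing")
        if np.any((self.quantile_levels < 0) | (self.quantile_levels > 1)):
            raise ValueError("quantile_levels must lie in [0, 1]")
        if np.any(np.diff(self.quantile_values) < 0):
            raise ValueError("quantile_values must be non-decreasing")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "modality": self.modality,
            "quantile_levels": self.quantile_levels.tolist(),
            "quantile_values": self.quantile_values.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TemplateHistogram":
        d = json.loads(Path(path).read_text())
        return cls(d["modality"], np.asarray(d["quantile_levels"]), np.asarray(d["quantile_values"]))


@dataclass
class CalibrationMap:
    """Monotone piecewise-linear transfer from subject to template intensity.

    Knots map the subject's quantile at level q exactly to the template's
    quantile at q; outside the knot range the map clamps to the end values.
    """

    subject_knots: np.ndarray
    template_knots: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.subject_knots, dtype=float)
        t = np.asarray(self.template_knots, dtype=float)
        if s.shape != t.shape or s.ndim != 1:
            raise ValueError("knot arrays must be matching 1D arrays")
        if np.any(np.diff(s) < 0) or np.any(np.diff(t) < 0):
            raise ValueError("knots must be non-decreasing")
        # collapse duplicate subject knots so the transfer is a function
        keep = np.concatenate([[True], np.diff(s) > 0])
        self.subject_knots = s[keep]
        self.template_knots = t[keep]
        if self.subject_knots.size < 2:
            raise ValueError("degenerate calibration: subject intensities constant in mask")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.subject_knots, self.template_knots)


@dataclass
class RatioVolume:
    """Voxelwise calibrated-T1w / calibrated-FLAIR ratio with a validity mask.

    Voxels where the FLAIR denominator does not exceed the floor are NaN in
    ``grid`` and False in ``valid`` — flagged, never silently zero.
    """

    grid: np.ndarray
    valid: np.ndarray
    voxel_size_mm: float = 1.0
    denominator_floor: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.grid.shape != self.valid.shape:
            raise ValueError("ratio grid and validity mask must share the shape")


def calibration_mask(labels: LabelVolume) -> np.ndarray:
    """Brain-tissue calibration mask: (WM ∪ cortical GM) minus lesion voxels.

    Ventricles and CSF/background are excluded; lesions are removed so that
    their altered intensities do not distort the histogram matching.
    """
    mask = labels.mask("wm") | labels.mask("cortex_gm")
    if "lesion" in labels.label_table:
        mask &= ~labels.mask("lesion")
    if not mask.any():
        raise ValueError("calibration mask is empty (no non-lesional WM/GM voxels)")
    return mask


def build_template(
    images: Sequence[IntensityVolume],
    masks: Sequence[np.ndarray],
    quantile_levels: Optional[np.ndarray] = None,
    modality: str = "unknown",
) -> TemplateHistogram:
    """Study template: per-level mean of the subjects' within-mask quantiles.

    Order-independent (a plain mean over subjects) and deterministic.
    """
    if len(images) != len(masks):
        raise ValueError(f"{len(images)} images but {len(masks)} masks")
    if len(images) == 0:
        raise ValueError("need at least one image to build a template")
    levels = default_quantile_levels() if quantile_levels is None else np.asarray(quantile_levels, float)
    acc = np.zeros_like(levels)
    for img, m in zip(images, masks):
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise ValueError("empty calibration mask for a template subject")
        acc += np.quantile(img.grid[m], levels)
    return TemplateHistogram(modality, levels, acc / len(images))


def calibrate(
    image: IntensityVolume,
    mask: np.ndarray,
    template: TemplateHistogram,
) -> IntensityVolume:
    """Monotone quantile-matching calibration of an image to the template.

    The transfer function is estimated from within-mask voxels and applied to
    every voxel (end-segment clamping outside the mask's intensity range).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("calibration mask is empty")
    subj_q = np.quantile(image.grid[mask], template.quantile_levels)
    cmap = CalibrationMap(subj_q, template.quantile_values)
    return IntensityVolume(cmap(image.grid), voxel_size_mm=image.voxel_size_mm)


def compute_ratio(
    t1_cal: IntensityVolume,
    flair_cal: IntensityVolume,
    denominator_floor: Optional[float] = None,
) -> RatioVolume:
    """Voxelwise T1w/FLAIR ratio where FLAIR exceeds the denominator floor.

    The default floor is 1e-6 times the median positive FLAIR intensity,
    small enough not to bias valid voxels while catching near-zero
    denominators.
    """
    if t1_cal.grid.shape != flair_cal.grid.shape:
        raise ValueError(
            f"grid mismatch: {t1_cal.grid.shape} vs {flair_cal.grid.shape}"
        )
    if t1_cal.voxel_size_mm != flair_cal.voxel_size_mm:
        raise ValueError("voxel size mismatch between T1w and FLAIR")
    f = flair_cal.grid
    if denominator_floor is None:
        pos = f[f > 0]
        denominator_floor = 1e-6 * float(np.median(pos)) if pos.size else 0.0
    valid = f > denominator_floor
    grid = np.full(f.shape, np.nan)
    np.divide(t1_cal.grid, f, out=grid, where=valid)
    return RatioVolume(grid, valid, t1_cal.voxel_size_mm, float(denominator_floor))
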