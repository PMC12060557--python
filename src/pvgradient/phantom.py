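"""Synthetic brain phantoms and cohorts with known ground truth.

The phantom is a miniature brain on a small isotropic grid: two axis-aligned
ellipsoidal lateral ventricles, a curved choroid plexus (ChP) strip on the
posterior inner wall of each ventricle, a white-matter shell surrounding the
ventricles, spherical lesions placed fully inside the white matter, and a
cortical grey-matter shell outside the WM.  Absolute volumes are scaled down
(ICV around 50 ml) but the *normalized* volumes — ChP/ICV around 1e-3, LVV a
few percent of ICV — are in the range seen in adult brains, and every
downstream statistic operates on normalized values.

The injected T1w/FLAIR ratio in white matter follows

    ratio(d) = ratio_baseline + gradient_slope * min(d, gradient_range_mm)

where d is the Chebyshev (L-inf) distance in mm from the ventricle margin.
Because the band module's default 26-connected dilation produces shells of
constant Chebyshev distance, the noise-free expected mean in band k is exact:
ratio_baseline + gradient_slope * min(k * voxel, range).  FLAIR white matter
is fixed at an arbitrary reference intensity and T1w is set to realize the
target ratio; per-subject global affine intensity distortions (gain, offset)
are applied to both images so the histogram calibration has real work to do.

Cohort generation layers a generative statistical model on top: group-specific
ChP shifts, a ChP-duration slope in RRMS, a logarithmic LVV term in ChP, a
ChP-lesion-count coupling, and a plateau-preserving coupling of ChP to the
periventricular gradient (the ratio depression at the ventricle margin decays
linearly to zero at the gradient range, so band-wise ChP-ratio association
slopes shrink with distance from the ventricles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumetry import STANDARD_LABELS, IntensityVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "PhantomTruth",
    "SubjectPhantom",
    "CohortResult",
    "PhantomSizingError",
    "LesionPlacementError",
    "generate_phantom",
    "sample_cohort_table",
    "generate_cohort",
    "GROUPS",
]

GROUPS = ("CS", "RRMS", "PPMS")

# reference tissue intensities (arbitrary units) before affine distortion
FLAIR_WM = 100.0
FLAIR_GM = 110.0
FLAIR_CSF = 25.0
FLAIR_LESION = 160.0
RATIO_GM = 0.7
RATIO_CSF = 1.2
RATIO_LESION = 0.55


class PhantomSizingError(ValueError):
    """Requested geometry does not fit inside the grid."""


class LesionPlacementError(RuntimeError):
    """Lesion placement failed after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``ratio_baseline`` is the ratio value at the ventricle margin (d = 0);
    the far-field plateau is ``ratio_baseline + gradient_slope *
    gradient_range_mm``.  ``noise_sd`` is the additive Gaussian intensity
    noise SD expressed as a fraction of the white-matter FLAIR reference
    intensity (applied to both modalities, scaled by each image's gain).
    If ``chp_norm`` is set it overrides ``chp_volume_ml`` with a target
    bilateral ChP/ICV fraction.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    ventricle_halfwidths_mm: tuple[float, float, float] = (4.0, 10.0, 6.0)
    ventricle_offset_mm: float = 8.0
    chp_volume_ml: float = 0.06
    chp_norm: Optional[float] = None
    lesion_count: int = 3
    lesion_radius_mm: float = 3.0
    wm_shell_thickness_mm: float = 14.0
    cortex_thickness_mm: float = 3.0
    ratio_baseline: float = 1.0
    gradient_slope: float = -0.01
    gradient_range_mm: float = 6.0
    noise_sd: float = 0.05
    t1_gain: float = 1.0
    t1_offset: float = 0.0
    flair_gain: float = 1.0
    flair_offset: float = 0.0
    connectivity: int = 26
    seed: int = 0

    def validate(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.ratio_baseline <= 0:
            raise ValueError("ratio_baseline must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be non-negative")
        if min(self.ventricle_halfwidths_mm) < self.voxel_size_mm:
            raise PhantomSizingError("ventricle halfwidths below one voxel")
        if self.wm_shell_thickness_mm <= 0 or self.cortex_thickness_mm < 0:
            raise ValueError("shell thicknesses must be positive")
        if self.gradient_range_mm <= 0:
            raise ValueError("gradient_range_mm must be positive")
        vox = self.voxel_size_mm
        reach = self.wm_shell_thickness_mm + self.cortex_thickness_mm
        for ax in range(3):
            half = self.ventricle_halfwidths_mm[ax] + reach
            if ax == 0:
                half += self.ventricle_offset_mm
            extent_vox = half / vox
            center = (self.grid_shape[ax] - 1) / 2.0
            if center - extent_vox < 1 or center + extent_vox > self.grid_shape[ax] - 2:
                raise PhantomSizingError(
                    f"geometry does not fit grid axis {ax}: needs ±{extent_vox:.1f} "
                    f"voxels around center {center:.1f} in {self.grid_shape[ax]} "
                    "(leave a ≥1 voxel margin)"
                )


@dataclass
class PhantomTruth:
    """Ground truth emitted with every phantom."""

    spec: PhantomSpec
    ventricle_left_ml: float
    ventricle_right_ml: float
    lvv_ml: float
    chp_left_ml: float
    chp_right_ml: float
    wm_ml: float
    cortex_gm_ml: float
    lesion_ml: float
    icv_ml: float
    chp_norm: float
    band_expected_ratio: dict[int, float]
    band_voxel_counts: dict[int, int]

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "spec"}
        d["band_expected_ratio"] = {str(k): v for k, v in self.band_expected_ratio.items()}
        d["band_voxel_counts"] = {str(k): v for k, v in self.band_voxel_counts.items()}
        return d


def expected_band_ratio(spec: PhantomSpec, band: int) -> float:
    """Noise-free expected mean ratio in band k (exact under Chebyshev bands)."""
    d = band * spec.voxel_size_mm
    return spec.ratio_baseline + spec.gradient_slope * min(d, spec.gradient_range_mm)


def _ellipsoid(shape, center_vox, halfwidths_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, h in zip(grids, center_vox, halfwidths_vox):
        acc = acc + ((g - c) / h) ** 2
    return acc <= 1.0


def _select_chp(vent: np.ndarray, interior_depth: np.ndarray, center_y: float, n: int) -> np.ndarray:
    """Pick n ChP voxels inside one ventricle: posterior wall voxels first
    (a curved strip along the inner boundary), then deeper posterior voxels,
    then anterior ones.  Deterministic lexicographic tie-break."""
    idx = np.argwhere(vent)
    if n > len(idx):
        raise ValueError(
            f"requested ChP volume ({n} voxels) exceeds ventricle volume ({len(idx)} voxels)"
        )
    posterior = idx[:, 1] > center_y
    depth = interior_depth[tuple(idx.T)]
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], depth, ~posterior))
    chosen = idx[order[:n]]
    out = np.zeros(vent.shape, dtype=bool)
    out[tuple(chosen.T)] = True
    return out


def _place_lesions(
    wm: np.ndarray, radius_vox: float, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Spherical lesions fully inside WM, mutually non-overlapping."""
    lesions = np.zeros(wm.shape, dtype=bool)
    if count == 0:
        return lesions
    interior = ndimage.distance_transform_edt(wm)
    eligible = np.argwhere(interior > radius_vox)
    if len(eligible) == 0:
        raise LesionPlacementError(
            f"no WM voxel can host a lesion of radius {radius_vox} voxels"
        )
    r_int = int(math.floor(radius_vox))
    span = np.arange(-r_int, r_int + 1)
    zz, yy, xx = np.meshgrid(span, span, span, indexing="ij")
    ball = (zz**2 + yy**2 + xx**2) <= radius_vox**2
    placed = 0
    attempts = 0
    max_attempts = 100 * count
    while placed < count:
        attempts += 1
        if attempts > max_attempts:
            raise LesionPlacementError(
                f"failed to place lesion {placed + 1}/{count} after {max_attempts} "
                "attempts: non-overlapping spheres inside WM do not fit"
            )
        c = eligible[rng.integers(len(eligible))]
        sl = tuple(slice(ci - r_int, ci + r_int + 1) for ci in c)
        region = lesions[sl]
        if (region & ball).any():
            continue
        region |= ball
        placed += 1
    return lesions


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[LabelVolume, IntensityVolume, IntensityVolume, PhantomTruth]:
    """Generate one synthetic subject: labels, T1w, FLAIR and ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    vox = spec.voxel_size_mm
    vv_ml = vox**3 / 1000.0
    center = tuple((s - 1) / 2.0 for s in shape)
    hw_vox = tuple(h / vox for h in spec.ventricle_halfwidths_mm)
    off = spec.ventricle_offset_mm / vox

    vent_l = _ellipsoid(shape, (center[0] - off, center[1], center[2]), hw_vox)
    vent_r = _ellipsoid(shape, (center[0] + off, center[1], center[2]), hw_vox)
    vent = vent_l | vent_r

    # Chebyshev distance (voxels) from the ventricle margin; 0 inside
    cdt = ndimage.distance_transform_cdt(~vent, metric="chessboard")
    t_vox = int(round(spec.wm_shell_thickness_mm / vox))
    c_vox = int(round(spec.cortex_thickness_mm / vox))
    wm = (cdt >= 1) & (cdt <= t_vox)
    cortex = (cdt > t_vox) & (cdt <= t_vox + c_vox)

    icv_ml = float((vent | wm | cortex).sum()) * vv_ml
    if spec.chp_norm is not None:
        chp_target_ml = spec.chp_norm * icv_ml / 2.0
    else:
        chp_target_ml = spec.chp_volume_ml
    n_chp = int(round(chp_target_ml / vv_ml))
    depth = ndimage.distance_transform_cdt(vent, metric="chessboard")
    chp_l = _select_chp(vent_l, depth, center[1], n_chp)
    chp_r = _select_chp(vent_r, depth, center[1], n_chp)

    lesions = _place_lesions(wm, spec.lesion_radius_mm / vox, spec.lesion_count, rng)

    grid = np.zeros(shape, dtype=np.int16)
    grid[vent_l] = STANDARD_LABELS["ventricle_left"]
    grid[vent_r] = STANDARD_LABELS["ventricle_right"]
    grid[chp_l] = STANDARD_LABELS["chp_left"]
    grid[chp_r] = STANDARD_LABELS["chp_right"]
    grid[wm] = STANDARD_LABELS["wm"]
    grid[cortex] = STANDARD_LABELS["cortex_gm"]
    grid[lesions] = STANDARD_LABELS["lesion"]
    labels = LabelVolume(grid, vox, dict(STANDARD_LABELS))

    # noise-free ratio field and modality intensities
    d_mm = cdt.astype(float) * vox
    ratio_map = np.zeros(shape)
    wm_only = wm & ~lesions
    ratio_map[wm_only] = spec.ratio_baseline + spec.gradient_slope * np.minimum(
        d_mm[wm_only], spec.gradient_range_mm
    )
    ratio_map[cortex] = RATIO_GM
    ratio_map[vent] = RATIO_CSF
    ratio_map[lesions] = RATIO_LESION
    flair_clean = np.zeros(shape)
    flair_clean[wm_only] = FLAIR_WM
    flair_clean[cortex] = FLAIR_GM
    flair_clean[vent] = FLAIR_CSF
    flair_clean[lesions] = FLAIR_LESION
    t1_clean = ratio_map * flair_clean

    noise_abs = spec.noise_sd * FLAIR_WM
    t1 = spec.t1_gain * t1_clean + spec.t1_offset
    flair = spec.flair_gain * flair_clean + spec.flair_offset
    if noise_abs > 0:
        t1 = t1 + rng.normal(0.0, noise_abs * spec.t1_gain, shape)
        flair = flair + rng.normal(0.0, noise_abs * spec.flair_gain, shape)
    np.maximum(t1, 0.0, out=t1)
    np.maximum(flair, 0.0, out=flair)

    chp_ml = n_chp * vv_ml
    band_exp = {k: expected_band_ratio(spec, k) for k in range(1, 11)}
    band_counts = {
        k: int(((cdt == k) & wm_only).sum()) for k in range(1, 11)
    }
    truth = PhantomTruth(
        spec=spec,
        ventricle_left_ml=float(vent_l.sum()) * vv_ml,
        ventricle_right_ml=float(vent_r.sum()) * vv_ml,
        lvv_ml=float(vent.sum()) * vv_ml,
        chp_left_ml=chp_ml,
        chp_right_ml=chp_ml,
        wm_ml=float(wm_only.sum()) * vv_ml,
        cortex_gm_ml=float(cortex.sum()) * vv_ml,
        lesion_ml=float(lesions.sum()) * vv_ml,
        icv_ml=icv_ml,
        chp_norm=2 * chp_ml / icv_ml,
        band_expected_ratio=band_exp,
        band_voxel_counts=band_counts,
    )
    return labels, IntensityVolume(t1, vox), IntensityVolume(flair, vox), truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _default_n():
    return {"CS": 75, "RRMS": 141, "PPMS": 64}


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a three-group study cohort.

    Covariates (age, sex, center, disease duration) are sampled per group;
    normalized ChP volume is built from a base level plus a group shift, a
    disease-duration slope (RRMS only), a logarithmic LVV term (group-centred
    so group contrasts stay analytic) and Gaussian noise.  ``chp_ratio_coupling``
    is the change of the ratio at the ventricle margin per unit normalized ChP,
    decaying linearly to zero at ``gradient_range_mm`` (plateau preserving):
    the implied true band-wise regression slope in band k is
    ``chp_ratio_coupling * (1 - min(k, R)/R)``.
    """

    n_per_group: dict = field(default_factory=_default_n)
    age_mean_sd: dict = field(
        default_factory=lambda: {"CS": (45.0, 13.0), "RRMS": (42.0, 11.0), "PPMS": (51.0, 10.0)}
    )
    female_proportion: dict = field(
        default_factory=lambda: {"CS": 0.60, "RRMS": 0.70, "PPMS": 0.45}
    )
    center_proportions: dict = field(
        default_factory=lambda: {"site_a": 0.5, "site_b": 0.5}
    )
    duration_gamma: dict = field(
        default_factory=lambda: {"RRMS": (2.0, 4.5), "PPMS": (2.2, 5.0)}
    )
    age_chp_slope: float = 2.0e-6
    chp_base: float = 9.0e-4
    chp_sd: float = 2.0e-4
    chp_group_shift: dict = field(
        default_factory=lambda: {"CS": 0.0, "RRMS": 1.5e-4, "PPMS": 0.5e-4}
    )
    chp_duration_slope: float = 8.0e-6
    lvv_lognormal: dict = field(
        default_factory=lambda: {
            "CS": (math.log(1.8), 0.35),
            "RRMS": (math.log(2.4), 0.35),
            "PPMS": (math.log(2.8), 0.35),
        }
    )
    lvv_log_coupling: float = 1.5e-4
    chp_lesion_coupling: float = 4000.0
    lesion_rate_base: dict = field(
        default_factory=lambda: {"CS": 0.0, "RRMS": 5.0, "PPMS": 4.0}
    )
    ratio_baseline: float = 1.05
    gradient_slope: float = -0.01
    gradient_range_mm: float = 6.0
    group_gradient_depth: dict = field(
        default_factory=lambda: {"CS": 0.0, "RRMS": -0.04, "PPMS": -0.07}
    )
    chp_ratio_coupling: float = -45.0
    subject_intercept_sd: float = 0.02
    band_noise_sd: float = 0.01
    noise_sd: float = 0.05
    gain_log_sd: float = 0.15
    offset_sd: float = 3.0
    n_bands: int = 10
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group sizes must be non-negative")
        total = sum(self.center_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("center_proportions must sum to 1")
        for g, p in self.female_proportion.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError("female proportions must lie in [0, 1]")
        self.phantom.validate()


def true_bandwise_slope(spec: CohortSpec, band: int) -> float:
    """Implied true regression slope of band-k mean ratio on normalized ChP."""
    r = spec.gradient_range_mm
    d = min(band * spec.phantom.voxel_size_mm, r)
    return spec.chp_ratio_coupling * (1.0 - d / r)


def sample_cohort_table(
    spec: CohortSpec,
    seed: Optional[int] = None,
    band_noise: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Sample the per-subject covariate/outcome table from the generative model.

    This is the fast, image-free path used for statistical simulation: band
    means are produced directly from each subject's injected ratio profile
    (plus independent per-band noise when ``band_noise``).  ``generate_cohort``
    uses the same draw to build per-subject phantom volumes.

    Returns the table and a truth record holding every coupling coefficient,
    the per-group expected ChP means and the implied band-wise slopes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    centers = sorted(spec.center_proportions)
    center_p = np.array([spec.center_proportions[c] for c in centers])
    rows = []
    sid = 0
    r_mm = spec.gradient_range_mm
    for g in GROUPS:
        mu_age, sd_age = spec.age_mean_sd[g]
        mu_lvv, sd_lvv = spec.lvv_lognormal[g]
        for _ in range(int(spec.n_per_group.get(g, 0))):
            sid += 1
            age = float(np.clip(rng.normal(mu_age, sd_age), 18.0, 85.0))
            sex = "F" if rng.random() < spec.female_proportion[g] else "M"
            center = centers[rng.choice(len(centers), p=center_p)]
            if g in spec.duration_gamma:
                shp, scl = spec.duration_gamma[g]
                duration = float(rng.gamma(shp) * scl)
            else:
                duration = math.nan
            lvv = float(rng.lognormal(mu_lvv, sd_lvv))
            chp = (
                spec.chp_base
                + spec.chp_group_shift[g]
                + spec.age_chp_slope * (age - 45.0)
                + spec.lvv_log_coupling * (math.log(lvv) - mu_lvv)
                + rng.normal(0.0, spec.chp_sd)
            )
            if g == "RRMS" and not math.isnan(duration):
                chp += spec.chp_duration_slope * duration
            chp = max(chp, 1e-5)
            if g == "CS":
                lesion_count = 0
            else:
                rate = max(
                    0.0,
                    spec.lesion_rate_base[g]
                    + spec.chp_lesion_coupling * (chp - spec.chp_base),
                )
                lesion_count = int(rng.poisson(rate))
            lesion_ml = lesion_count * (4.0 / 3.0) * math.pi * spec.phantom.lesion_radius_mm**3 / 1000.0
            if math.isnan(duration):
                edss = math.nan
            else:
                edss = float(np.clip(round(2 * rng.normal(2.5 + 0.12 * duration, 1.2)) / 2, 0, 10))
            delta = spec.group_gradient_depth[g] + spec.chp_ratio_coupling * (chp - spec.chp_base)
            intercept = rng.normal(0.0, spec.subject_intercept_sd)
            baseline_i = spec.ratio_baseline + delta + intercept
            slope_i = spec.gradient_slope - delta / r_mm
            row = {
                "subject": f"sub-{sid:04d}",
                "group": g,
                "age": age,
                "sex": sex,
                "center": center,
                "disease_duration": duration,
                "edss": edss,
                "lvv_ml": lvv,
                "chp_norm": chp,
                "lesion_count": lesion_count,
                "lesion_ml": lesion_ml,
                "ratio_baseline": baseline_i,
                "gradient_slope": slope_i,
            }
            vox = spec.phantom.voxel_size_mm
            for k in range(1, spec.n_bands + 1):
                m = baseline_i + slope_i * min(k * vox, r_mm)
                if band_noise and spec.band_noise_sd > 0:
                    m += rng.normal(0.0, spec.band_noise_sd)
                row[f"band_{k}"] = m
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "chp_base": spec.chp_base,
        "chp_group_shift": dict(spec.chp_group_shift),
        "chp_duration_slope": spec.chp_duration_slope,
        "lvv_log_coupling": spec.lvv_log_coupling,
        "chp_lesion_coupling": spec.chp_lesion_coupling,
        "chp_ratio_coupling": spec.chp_ratio_coupling,
        "gradient_range_mm": spec.gradient_range_mm,
        "expected_group_chp": {
            g: spec.chp_base
            + spec.chp_group_shift[g]
            + (
                spec.chp_duration_slope
                * spec.duration_gamma[g][0]
                * spec.duration_gamma[g][1]
                if g == "RRMS" and g in spec.duration_gamma
                else 0.0
            )
            for g in GROUPS
        },
        "true_bandwise_slope": {
            k: true_bandwise_slope(spec, k) for k in range(1, spec.n_bands + 1)
        },
    }
    return table, truth


@dataclass
class SubjectPhantom:
    subject_id: str
    covariates: dict
    labels: LabelVolume
    t1w: IntensityVolume
    flair: IntensityVolume
    truth: PhantomTruth


@dataclass
class CohortResult:
    subjects: list[SubjectPhantom]
    table: pd.DataFrame
    truth: dict


def _reference_lvv_ml(spec: PhantomSpec) -> float:
    a, b, c = spec.ventricle_halfwidths_mm
    return 2.0 * (4.0 / 3.0) * math.pi * a * b * c / 1000.0


def _max_ventricle_scale(spec: PhantomSpec) -> float:
    """Largest halfwidth scale factor whose geometry still fits the grid."""
    reach = spec.wm_shell_thickness_mm + spec.cortex_thickness_mm
    s_max = math.inf
    for ax in range(3):
        center = (spec.grid_shape[ax] - 1) / 2.0
        # mirror of PhantomSpec.validate: keep a >=1 voxel margin
        limit_vox = min(center - 1.0, spec.grid_shape[ax] - 2 - center)
        budget = limit_vox * spec.voxel_size_mm - reach
        if ax == 0:
            budget -= spec.ventricle_offset_mm
        s_max = min(s_max, budget / spec.ventricle_halfwidths_mm[ax])
    return s_max


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> CohortResult:
    """Generate per-subject phantom volumes realizing a sampled cohort table.

    Each subject's ventricle halfwidths are scaled to hit the sampled LVV,
    the ChP voxel count targets the sampled normalized ChP, and the injected
    ratio profile uses the subject's baseline/slope from the generative model.
    Per-subject affine intensity distortions (log-normal gain, Gaussian
    offset) are sampled for both modalities.  Re-running with the same seed
    reproduces the cohort bit-identically.
    """
    table, truth = sample_cohort_table(spec, seed=seed, band_noise=False)
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 0x5EED)
    lvv_ref = _reference_lvv_ml(spec.phantom)
    subjects = []
    s_max = 0.98 * _max_ventricle_scale(spec.phantom)
    for _, row in table.iterrows():
        # LVV draws are truncated to what the grid geometry supports
        scale = min((row["lvv_ml"] / lvv_ref) ** (1.0 / 3.0), s_max)
        hws = tuple(h * scale for h in spec.phantom.ventricle_halfwidths_mm)
        sub_spec = replace(
            spec.phantom,
            ventricle_halfwidths_mm=hws,
            chp_norm=float(row["chp_norm"]),
            lesion_count=int(row["lesion_count"]),
            ratio_baseline=float(row["ratio_baseline"]),
            gradient_slope=float(row["gradient_slope"]),
            gradient_range_mm=spec.gradient_range_mm,
            noise_sd=spec.noise_sd,
            t1_gain=float(np.exp(rng.normal(0.0, spec.gain_log_sd))),
            t1_offset=float(rng.normal(0.0, spec.offset_sd)),
            flair_gain=float(np.exp(rng.normal(0.0, spec.gain_log_sd))),
            flair_offset=float(rng.normal(0.0, spec.offset_sd)),
            seed=int(rng.integers(2**31)),
        )
        labels, t1w, flair, sub_truth = generate_phantom(sub_spec)
        subjects.append(
            SubjectPhantom(
                subject_id=row["subject"],
                covariates=row.to_dict(),
                labels=labels,
                t1w=t1w,
                flair=flair,
                truth=sub_truth,
            )
        )
    return CohortResult(subjects=subjects, table=table, truth=truth)
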