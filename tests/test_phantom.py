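"""Phantom generator: geometry, injected gradient, ground truth, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from pvgradient.bands import band_means, build_bands
from pvgradient.phantom import (
    CohortSpec,
    PhantomSizingError,
    expected_band_ratio,
    generate_cohort,
    generate_phantom,
    sample_cohort_table,
)
from pvgradient.ratio import compute_ratio
from pvgradient.volumetry import subject_volumes

from conftest import small_spec


def test_flat_field_without_gradient_or_noise():
    spec = small_spec(gradient_slope=0.0, noise_sd=0.0, ratio_baseline=1.1, seed=1)
    labels, t1, fl, _ = generate_phantom(spec)
    wm = labels.mask("wm")
    ratio = t1.grid[wm] / fl.grid[wm]
    assert np.allclose(ratio, 1.1, atol=1e-12)


def test_zero_lesions_means_no_lesion_label():
    labels, *_ , truth = generate_phantom(small_spec(lesion_count=0, seed=2))
    assert not labels.mask("lesion").any()
    assert truth.lesion_ml == 0.0


def test_band_means_match_bruteforce_distance_oracle(noise_free_phantom):
    """Injected gradient: mean ratio in band k equals baseline + slope*k,
    verified against an independent Chebyshev distance transform."""
    spec, labels, t1, fl, truth = noise_free_phantom
    vent = labels.mask("ventricle") | labels.mask("chp")
    nawm = labels.mask("wm")
    dist = ndimage.distance_transform_cdt(~vent, metric="chessboard")
    ratio = np.zeros(labels.grid.shape)
    np.divide(t1.grid, fl.grid, out=ratio, where=fl.grid > 0)
    for k in range(1, 11):
        sel = (dist == k) & nawm
        expected = 1.0 - 0.01 * k
        assert sel.any()
        assert np.allclose(ratio[sel].mean(), expected, rtol=1e-12)
        assert expected_band_ratio(spec, k) == pytest.approx(expected)


def test_truth_band_means_match_bands_module(noise_free_phantom):
    spec, labels, t1, fl, truth = noise_free_phantom
    rat = compute_ratio(t1, fl)
    bset = build_bands(labels.mask("ventricle") | labels.mask("chp"), labels.mask("wm"),
                       labels.mask("lesion"))
    bm = band_means(rat, bset)
    for k in range(1, 11):
        exp = truth.band_expected_ratio[k]
        got = float(bm.loc[bm["band"] == k, "mean"].iloc[0])
        assert abs(got - exp) / exp < 1e-9
        assert bm.loc[bm["band"] == k, "n_voxels"].iloc[0] == truth.band_voxel_counts[k]


def test_structure_masks_disjoint_and_cover_icv(noise_free_phantom):
    _, labels, *_ = noise_free_phantom
    names = ["ventricle", "chp", "wm", "cortex_gm", "lesion"]
    total = np.zeros(labels.grid.shape, dtype=int)
    for n in names:
        total += labels.mask(n).astype(int)
    assert total.max() == 1  # pairwise disjoint
    assert ((total == 1) == labels.intracranial_mask()).all()
    # lesions live strictly inside the WM shell, ChP inside the ventricles
    vent_lumen = labels.mask("ventricle") | labels.mask("chp")
    dist = ndimage.distance_transform_cdt(~vent_lumen, metric="chessboard")
    assert dist[labels.mask("lesion")].min() >= 1
    assert dist[labels.mask("chp")].max() == 0


def test_determinism_same_seed_bit_identical():
    spec = small_spec(seed=42, noise_sd=0.05)
    a = generate_phantom(spec)
    b = generate_phantom(spec)
    assert (a[0].grid == b[0].grid).all()
    assert (a[1].grid == b[1].grid).all()
    assert (a[2].grid == b[2].grid).all()


def test_oversized_geometry_raises_sizing_error():
    with pytest.raises(PhantomSizingError):
        generate_phantom(small_spec(ventricle_halfwidths_mm=(20.0, 20.0, 20.0)))


def test_chp_volume_hits_target_within_one_voxel():
    spec = small_spec(
        grid_shape=(64, 64, 64),
        ventricle_halfwidths_mm=(5.0, 14.0, 8.0),
        ventricle_offset_mm=8.0,
        chp_volume_ml=0.8,
        lesion_count=0,
        seed=3,
    )
    labels, *_ , truth = generate_phantom(spec)
    vols = subject_volumes(labels)
    assert abs(vols.chp_bilateral_ml - 1.6) <= labels.voxel_volume_ml
    assert vols.chp_left_ml == pytest.approx(vols.chp_right_ml)


def test_chp_norm_override_targets_normalized_volume():
    spec = small_spec(chp_norm=8e-4, lesion_count=0, seed=4)
    labels, *_ , truth = generate_phantom(spec)
    vols = subject_volumes(labels)
    assert vols.chp_norm == pytest.approx(8e-4, abs=2 * labels.voxel_volume_ml / vols.icv_ml)


class TestCohort:
    def test_null_cohort_truth_has_no_group_difference(self):
        spec = CohortSpec(
            n_per_group={"CS": 3, "RRMS": 3, "PPMS": 3},
            chp_group_shift={"CS": 0.0, "RRMS": 0.0, "PPMS": 0.0},
            chp_duration_slope=0.0,
            lvv_log_coupling=0.0,
            chp_ratio_coupling=0.0,
            seed=1,
        )
        _, truth = sample_cohort_table(spec)
        e = truth["expected_group_chp"]
        assert e["RRMS"] == e["CS"] == e["PPMS"]
        assert all(v == 0 for v in truth["true_bandwise_slope"].values())

    def test_configured_shift_appears_in_truth_contrast(self):
        spec = CohortSpec(
            n_per_group={"CS": 75, "RRMS": 64, "PPMS": 141},
            chp_group_shift={"CS": 0.0, "RRMS": 3e-4, "PPMS": 0.0},
            chp_duration_slope=0.0,
            seed=1,
        )
        tab, truth = sample_cohort_table(spec)
        assert len(tab) == 280
        assert truth["expected_group_chp"]["RRMS"] - truth["expected_group_chp"]["CS"] == pytest.approx(3e-4)

    def test_cohort_reproducible_and_consistent_with_phantoms(self):
        lvv = {g: (np.log(0.7), 0.15) for g in ("CS", "RRMS", "PPMS")}
        spec = CohortSpec(
            n_per_group={"CS": 2, "RRMS": 2, "PPMS": 0},
            phantom=small_spec(),
            lvv_lognormal=lvv,
            noise_sd=0.0,
            seed=9,
        )
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert a.table.equals(b.table)
        for sa, sb in zip(a.subjects, b.subjects):
            assert (sa.labels.grid == sb.labels.grid).all()
            assert (sa.t1w.grid == sb.t1w.grid).all()
        # measured normalized ChP tracks the sampled target
        for s in a.subjects:
            vols = subject_volumes(s.labels)
            assert vols.chp_norm == pytest.approx(
                s.covariates["chp_norm"], abs=3 * s.labels.voxel_volume_ml / vols.icv_ml
            )

    def test_bad_proportions_rejected(self):
        spec = CohortSpec(center_proportions={"a": 0.7, "b": 0.7})
        with pytest.raises(ValueError):
            spec.validate()
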