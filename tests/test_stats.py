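"""Statistical layer: ANCOVA/post-hoc, regressions, BH, stratification, mixed model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pvgradient.phantom import CohortSpec, sample_cohort_table
from pvgradient.stats import (
    ancova_groups,
    bandwise_chp_association,
    bh_adjust,
    cohort_to_long,
    linear_association,
    log_association_lvv,
    mixed_model_bands,
    stratify_duration,
)

from conftest import bh_bruteforce


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


class TestBH:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_single_test_identity(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20)
    )
    def test_matches_bruteforce_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_bruteforce(np.asarray(p)), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()
        # order invariance up to matching permutation
        perm = np.argsort(p)
        assert np.allclose(bh_adjust(np.asarray(p)[perm]), adj[perm], atol=1e-12)


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------


def _balanced_cohort(n=12, group_effect=(0.0, 0.0, 0.0), seed=0):
    """Exactly balanced design: identical covariate layout in every group."""
    rng = np.random.default_rng(seed)
    age = np.tile(np.linspace(30, 60, n), 3)
    sex = np.tile(np.array(["F", "M"] * (n // 2)), 3)
    center = np.tile(np.array(["a", "a", "b", "b"] * (n // 4)), 3)
    group = np.repeat(["CS", "RRMS", "PPMS"], n)
    eff = dict(zip(["CS", "RRMS", "PPMS"], group_effect))
    y = np.array([eff[g] for g in group]) + rng.normal(0, 1.0, 3 * n)
    return pd.DataFrame(
        {"group": group, "age": age, "sex": sex, "center": center, "chp_norm": y}
    )


class TestAncova:
    def test_balanced_adjusted_means_equal_raw_means(self):
        tab = _balanced_cohort()
        res = ancova_groups(tab, "chp_norm")
        raw = tab.groupby("group")["chp_norm"].mean()
        for g, m in res.adjusted_means.items():
            assert m == pytest.approx(raw[g], abs=1e-10)

    def test_adjusted_p_never_below_unadjusted(self):
        res = ancova_groups(_balanced_cohort(seed=3), "chp_norm")
        for c in res.comparisons:
            assert c.p_adjusted >= c.p_unadjusted - 1e-12

    def test_mvt_agrees_with_studentized_range_when_balanced(self):
        tab = _balanced_cohort(n=20, seed=4)
        mvt = ancova_groups(tab, "chp_norm", adjust="mvt")
        tuk = ancova_groups(tab, "chp_norm", adjust="tukey")
        for a, b in zip(mvt.comparisons, tuk.comparisons):
            assert a.p_adjusted == pytest.approx(b.p_adjusted, abs=0.01)

    def test_large_configured_shift_detected_and_estimated(self):
        tab = _balanced_cohort(n=48, group_effect=(0.0, 3.0, 0.0), seed=5)
        res = ancova_groups(tab, "chp_norm")
        c = {x.contrast: x for x in res.comparisons}["RRMS-CS"]
        assert c.p_adjusted < 0.001
        assert c.estimate - 2 * c.se < 3.0 < c.estimate + 2 * c.se

    def test_rank_deficient_design_names_aliased_term(self):
        tab = _balanced_cohort()
        tab["center"] = tab["group"]  # perfectly aliased with group
        with pytest.raises(ValueError, match="aliased"):
            ancova_groups(tab, "chp_norm")

    def test_too_small_groups_rejected(self):
        tab = _balanced_cohort().iloc[:13]  # second group has a single row
        with pytest.raises(ValueError, match="2 subjects"):
            ancova_groups(tab.iloc[[0, 1, 2, 12]], "chp_norm", covariates=("age",))


# ---------------------------------------------------------------------------
# association regressions
# ---------------------------------------------------------------------------


class TestLinearAssociation:
    def test_exact_linear_relation_recovered_to_machine_precision(self):
        rng = np.random.default_rng(7)
        n = 50
        x = rng.normal(10, 2, n)
        age = rng.normal(45, 10, n)
        tab = pd.DataFrame(
            {
                "x": x,
                "age": age,
                "sex": rng.choice(["F", "M"], n),
                "y": 2.5 * x - 0.5,
            }
        )
        res = linear_association(tab, "y", "x", ("age", "sex"))
        assert res.coef("x") == pytest.approx(2.5, rel=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)
        lo, hi = res.ci("x")
        assert lo <= 2.5 <= hi

    def test_listwise_deletion_reported(self):
        tab = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0, np.nan, 5.0, 6.0, 7.0],
                "x": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0],
                "age": [30.0] * 7,
            }
        )
        res = linear_association(tab, "y", "x", ())
        assert res.n == 5

    def test_underdetermined_rejected(self):
        tab = pd.DataFrame({"y": [1.0, 2.0], "x": [1.0, 2.0], "age": [3.0, 4.0]})
        with pytest.raises(ValueError, match="few"):
            linear_association(tab, "y", "x", ("age",))

    def test_permuted_predictor_p_values_uniform(self):
        rng = np.random.default_rng(11)
        n = 200
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        ps = []
        for _ in range(200):
            tab = pd.DataFrame({"x": rng.permutation(x), "y": y})
            ps.append(linear_association(tab, "y", "x", ()).p("x"))
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.005 <= frac <= 0.12  # binomial band around 0.05


class TestLvvModels:
    def _table(self, b, n=150, noise=1e-4, seed=0):
        rng = np.random.default_rng(seed)
        lvv = rng.lognormal(np.log(2.2), 0.4, n)
        age = rng.normal(45, 10, n)
        chp = 9e-4 + b * np.log(lvv) + rng.normal(0, noise, n)
        return pd.DataFrame(
            {"lvv_ml": lvv, "age": age, "sex": rng.choice(["F", "M"], n), "chp_norm": chp}
        )

    def test_log_model_wins_when_generative_model_is_logarithmic(self):
        cmp_ = log_association_lvv(self._table(b=4e-4))
        assert cmp_.log_better
        assert cmp_.log_model.adj_r2 > cmp_.linear_model.adj_r2

    def test_null_coupling_both_r2_near_zero(self):
        cmp_ = log_association_lvv(self._table(b=0.0, seed=1))
        assert abs(cmp_.log_model.adj_r2) < 0.05
        assert abs(cmp_.linear_model.adj_r2) < 0.05

    def test_unit_rescaling_shifts_intercept_not_slope(self):
        tab = self._table(b=4e-4, seed=2)
        a = log_association_lvv(tab)
        tab2 = tab.assign(lvv_ml=tab["lvv_ml"] * 1000.0)  # ml -> µl
        b_ = log_association_lvv(tab2)
        assert b_.log_model.coef("log_lvv") == pytest.approx(a.log_model.coef("log_lvv"), rel=1e-9)
        shift = a.log_model.coef("Intercept") - b_.log_model.coef("Intercept")
        assert shift == pytest.approx(a.log_model.coef("log_lvv") * np.log(1000.0), rel=1e-9)

    def test_nonpositive_lvv_rows_excluded_and_counted(self):
        tab = self._table(b=4e-4, seed=3)
        tab.loc[:4, "lvv_ml"] = 0.0
        cmp_ = log_association_lvv(tab)
        assert cmp_.n_excluded_nonpositive == 5
        assert cmp_.log_model.n == len(tab) - 5


class TestBandwise:
    def test_single_band_family_is_identity(self):
        rng = np.random.default_rng(4)
        n = 60
        tab = pd.DataFrame(
            {
                "chp_norm": rng.normal(9e-4, 2e-4, n),
                "age": rng.normal(45, 10, n),
                "sex": rng.choice(["F", "M"], n),
                "center": rng.choice(["a", "b"], n),
            }
        )
        tab["band_2"] = rng.normal(1.0, 0.01, n)
        res = bandwise_chp_association(tab)
        assert len(res) == 1 and res["m_bh"].iloc[0] == 1
        assert res["p_bh"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_slope_recovery_with_configured_coupling(self):
        spec = CohortSpec(
            n_per_group={"RRMS": 400},
            chp_ratio_coupling=-45.0,
            subject_intercept_sd=0.005,
            band_noise_sd=0.002,
            seed=8,
        )
        tab, truth = sample_cohort_table(spec)
        res = bandwise_chp_association(tab, group="RRMS").set_index("band")
        for k in (2, 3, 4, 5):
            true = truth["true_bandwise_slope"][k]
            assert res.loc[k, "slope"] == pytest.approx(true, abs=3 * res.loc[k, "se"])
        # beyond the gradient range the true association is zero
        for k in (7, 10):
            assert abs(res.loc[k, "slope"]) < 3 * res.loc[k, "se"]

    def test_missing_band_shrinks_bh_family(self):
        spec = CohortSpec(n_per_group={"RRMS": 40}, seed=9)
        tab, _ = sample_cohort_table(spec)
        tab["band_7"] = np.nan
        res = bandwise_chp_association(tab, group="RRMS")
        assert 7 not in set(res["band"])
        assert (res["m_bh"] == 8).all()


class TestStratify:
    def _table(self):
        spec = CohortSpec(n_per_group={"CS": 5, "RRMS": 20, "PPMS": 10}, seed=10)
        tab, _ = sample_cohort_table(spec)
        return tab

    def test_all_short_durations_leave_long_empty(self):
        tab = self._table()
        tab["disease_duration"] = 1.0
        prof, info = stratify_duration(tab)
        assert set(info["empty_strata"]) == {"RRMS_ld", "PPMS_ld"}
        assert set(prof["stratum"]) == {"RRMS_sd", "PPMS_sd"}

    def test_exact_cutoff_goes_to_long_group(self):
        tab = self._table()
        tab["disease_duration"] = 10.0
        prof, _ = stratify_duration(tab, cutoff_years=10.0)
        assert set(prof["stratum"]) == {"RRMS_ld", "PPMS_ld"}

    def test_missing_durations_counted(self):
        tab = self._table()
        tab.loc[tab.index[:3], "disease_duration"] = np.nan
        _, info = stratify_duration(tab)
        assert info["n_missing_duration"] == (tab["group"].iloc[:3] != "CS").sum()

    def test_duration_coupled_gradient_separates_strata_in_inner_bands(self):
        # stronger margin depression for long-duration RRMS via ChP-duration slope
        spec = CohortSpec(
            n_per_group={"RRMS": 200},
            chp_duration_slope=4e-5,
            chp_ratio_coupling=-60.0,
            subject_intercept_sd=0.005,
            band_noise_sd=0.005,
            seed=12,
        )
        tab, _ = sample_cohort_table(spec)
        prof, _ = stratify_duration(tab)
        prof = prof.set_index(["stratum", "band"])
        assert prof.loc[("RRMS_sd", 2), "mean"] > prof.loc[("RRMS_ld", 2), "mean"]


class TestMixedModel:
    def test_degenerate_random_effect_matches_ols(self):
        spec = CohortSpec(
            n_per_group={"CS": 15, "RRMS": 15, "PPMS": 15},
            subject_intercept_sd=0.0,
            band_noise_sd=0.01,
            seed=13,
        )
        tab, _ = sample_cohort_table(spec)
        long = cohort_to_long(tab)
        mm = mixed_model_bands(long)
        assert mm.random_intercept_sd < 5e-3
        import statsmodels.formula.api as smf

        ols = smf.ols(mm.formula, long).fit()
        common = [t for t in mm.fixed_effects.index if t in ols.params.index]
        assert len(common) > 10
        for t in common:
            assert mm.fixed_effects.loc[t, "coef"] == pytest.approx(
                ols.params[t], abs=5e-3
            )

    def test_too_few_subjects_rejected(self):
        spec = CohortSpec(n_per_group={"CS": 3, "RRMS": 3, "PPMS": 2}, seed=14)
        tab, _ = sample_cohort_table(spec)
        with pytest.raises(ValueError, match="10 subjects"):
            mixed_model_bands(cohort_to_long(tab))
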