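"""Cohort statistics: covariate-adjusted group comparisons and associations.

The statistical layer mirrors a standard cross-sectional neuroimaging
workflow: ANCOVA (linear model with group + covariates) with
estimated-marginal-mean pairwise contrasts under a Tukey-equivalent
multivariate-t adjustment; multivariable linear regression for associations
of normalized ChP volume with clinical and volumetric measures; a
logarithmic-vs-linear model comparison for the ChP-LVV relationship;
band-wise ChP-ratio regressions with Benjamini-Hochberg correction across
the nine analysed bands; disease-duration stratification of band profiles;
and a linear mixed model over the subject x band long table with a random
intercept per subject.

All models use listwise deletion of rows with missing values and report the
n actually used.  Tests are two-sided at alpha = 0.05 unless stated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelResult",
    "PairwiseComparison",
    "AncovaResult",
    "LvvModelComparison",
    "MixedModelResult",
    "bh_adjust",
    "ancova_groups",
    "linear_association",
    "log_association_lvv",
    "bandwise_chp_association",
    "stratify_duration",
    "mixed_model_bands",
    "cohort_to_long",
    "band_columns",
]

#: internal QMC stream for the multivariate-t integral; fixed so that adjusted
#: p-values are reproducible run to run.
_MVT_SEED = 20_240_101


@dataclass
class ModelResult:
    """OLS fit summary: coefficient table, adjusted R-squared, n, formula."""

    params: pd.DataFrame  # index: term; columns: coef, se, ci_low, ci_high, p
    adj_r2: float
    n: int
    formula: str

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, term: str) -> float:
        return float(self.params.loc[term, "p"])


@dataclass
class PairwiseComparison:
    contrast: str  # e.g. "RRMS-CS"
    estimate: float
    se: float
    t: float
    df: float
    p_unadjusted: float
    p_adjusted: float
    method: str


@dataclass
class AncovaResult:
    model: ModelResult
    comparisons: list[PairwiseComparison]
    adjusted_means: dict[str, float]
    group_counts: dict[str, int]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def _build_design(df: pd.DataFrame, terms: Sequence[str]):
    """Intercept + treatment-coded design; returns (X, factor level map)."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    levels: dict[str, list] = {}
    for t in terms:
        s = df[t]
        if _is_numeric(s):
            cols[t] = s.to_numpy(dtype=float)
        else:
            lv = sorted(s.astype(str).unique())
            levels[t] = lv
            for l in lv[1:]:
                cols[f"{t}[{l}]"] = (s.astype(str) == l).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    return X, levels


def _check_rank(X: pd.DataFrame) -> None:
    a = X.to_numpy(dtype=float)
    _, r = np.linalg.qr(a)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(a.shape) * np.finfo(float).eps * 1e3
    bad = [X.columns[i] for i in range(len(diag)) if diag[i] < tol]
    if bad:
        raise ValueError(f"rank-deficient design: aliased term(s) {bad}")


def _ols_result(y: np.ndarray, X: pd.DataFrame, formula: str, alpha: float = 0.05):
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha)
    params = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    return fit, ModelResult(params=params, adj_r2=float(fit.rsquared_adj), n=int(fit.nobs), formula=formula)


# ---------------------------------------------------------------------------
# ANCOVA with Tukey-equivalent pairwise contrasts
# ---------------------------------------------------------------------------


def _mvt_maxabs_sf(
    t_abs: np.ndarray, corr: np.ndarray, dof: float, draws: int = 40_000
) -> np.ndarray:
    """P(max_i |T_i| >= t) under a multivariate t with the given (possibly
    singular) correlation of the pairwise contrasts, by seeded Monte Carlo."""
    m = corr.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    L = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    rng = np.random.default_rng(_MVT_SEED)
    z = rng.standard_normal((draws, m)) @ L.T
    s = np.sqrt(rng.chisquare(dof, draws) / dof)
    maxabs = np.max(np.abs(z), axis=1) / s
    return np.array([np.mean(maxabs >= t) for t in t_abs])


def ancova_groups(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("age", "sex", "center"),
    group_col: str = "group",
    adjust: str = "tukey",
    alpha: float = 0.05,
) -> AncovaResult:
    """ANCOVA of ``outcome ~ group + covariates`` with pairwise post-hoc tests.

    Adjusted (estimated marginal) group means are model predictions at the
    numeric-covariate means with equal weights over the levels of each factor
    covariate.  Pairwise contrasts of adjusted means carry a Tukey-equivalent
    family adjustment: "tukey" (default) uses the studentized-range
    distribution (exact under balance, the Tukey-Kramer approximation
    otherwise); "mvt" integrates the multivariate t over the actual contrast
    correlation (seeded Monte Carlo, deterministic); "none" skips adjustment.
    """
    used = [outcome, group_col, *covariates]
    df = table.dropna(subset=used).copy()
    order = [g for g in ("CS", "RRMS", "PPMS") if g in df[group_col].unique()]
    extra = [g for g in df[group_col].unique() if g not in order]
    groups = order + sorted(extra)
    counts = {g: int((df[group_col] == g).sum()) for g in groups}
    if len(groups) < 2 or any(c < 2 for c in counts.values()):
        raise ValueError(
            f"need >= 2 groups with >= 2 subjects each, got counts {counts}"
        )

    X, _ = _build_design(df, [group_col, *covariates])
    _check_rank(X)
    y = df[outcome].to_numpy(dtype=float)
    formula = f"{outcome} ~ {group_col} + " + " + ".join(covariates)
    fit, model = _ols_result(y, X, formula, alpha)

    # reference grid: numeric covariates at their mean, factors equally weighted
    ref = pd.Series(0.0, index=X.columns)
    ref["Intercept"] = 1.0
    for c in covariates:
        if _is_numeric(df[c]):
            ref[c] = float(df[c].mean())
        else:
            lv = sorted(df[c].astype(str).unique())
            for l in lv[1:]:
                ref[f"{c}[{l}]"] = 1.0 / len(lv)
    rows = {}
    for g in groups:
        r = ref.copy()
        col = f"{group_col}[{g}]"
        if col in r.index:
            r[col] = 1.0
        rows[g] = r
    beta = fit.params
    cov = fit.cov_params()
    adjusted_means = {g: float(rows[g] @ beta) for g in groups}

    pairs = [(groups[i], groups[j]) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    C = np.stack([(rows[b] - rows[a]).to_numpy() for a, b in pairs])
    est = C @ beta.to_numpy()
    vc = C @ cov.to_numpy() @ C.T
    se = np.sqrt(np.diag(vc))
    tvals = est / se
    dof = float(fit.df_resid)
    p_raw = 2.0 * sps.t.sf(np.abs(tvals), dof)

    m = len(pairs)
    if adjust == "none":
        p_adj = p_raw.copy()
    elif adjust == "tukey":
        k = len(groups)
        p_adj = sps.studentized_range.sf(np.abs(tvals) * math.sqrt(2.0), k, dof)
    elif adjust == "mvt":
        corr = vc / np.outer(se, se)
        p_adj = _mvt_maxabs_sf(np.abs(tvals), corr, dof)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    # family adjustment can never make a test more significant
    p_adj = np.clip(np.maximum(p_adj, p_raw), 0.0, 1.0)

    comparisons = [
        PairwiseComparison(
            contrast=f"{b}-{a}",
            estimate=float(est[i]),
            se=float(se[i]),
            t=float(tvals[i]),
            df=dof,
            p_unadjusted=float(p_raw[i]),
            p_adjusted=float(p_adj[i]),
            method=adjust,
        )
        for i, (a, b) in enumerate(pairs)
    ]
    return AncovaResult(model=model, comparisons=comparisons, adjusted_means=adjusted_means, group_counts=counts)


# ---------------------------------------------------------------------------
# association regressions
# ---------------------------------------------------------------------------


def linear_association(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = ("age", "sex"),
    alpha: float = 0.05,
) -> ModelResult:
    """Multivariable linear regression of outcome on predictor + covariates."""
    used = [outcome, predictor, *covariates]
    df = table.dropna(subset=used)
    X, _ = _build_design(df, [predictor, *covariates])
    if len(df) <= X.shape[1]:
        raise ValueError(
            f"too few complete rows (n={len(df)}) for {X.shape[1]} parameters"
        )
    _check_rank(X)
    y = df[outcome].to_numpy(dtype=float)
    formula = f"{outcome} ~ {predictor} + " + " + ".join(covariates) if covariates else f"{outcome} ~ {predictor}"
    _, model = _ols_result(y, X, formula, alpha)
    return model


@dataclass
class LvvModelComparison:
    log_model: ModelResult
    linear_model: ModelResult
    n_excluded_nonpositive: int

    @property
    def log_better(self) -> bool:
        return self.log_model.adj_r2 > self.linear_model.adj_r2


def log_association_lvv(
    table: pd.DataFrame,
    outcome: str = "chp_norm",
    covariates: Sequence[str] = ("age", "sex"),
    lvv_col: str = "lvv_ml",
    alpha: float = 0.05,
) -> LvvModelComparison:
    """ChP-LVV association: logarithmic vs linear LVV, adjusted R-squared compared."""
    df = table.dropna(subset=[outcome, lvv_col, *covariates])
    bad = int((df[lvv_col] <= 0).sum())
    df = df[df[lvv_col] > 0].copy()
    df["log_lvv"] = np.log(df[lvv_col])
    log_model = linear_association(df, outcome, "log_lvv", covariates, alpha)
    lin_model = linear_association(df, outcome, lvv_col, covariates, alpha)
    return LvvModelComparison(log_model, lin_model, bad)


def band_columns(table: pd.DataFrame, include_first: bool = False) -> list[str]:
    """Band-mean columns present in the table, analysis set (b2..) by default."""
    cols = []
    for c in table.columns:
        if c.startswith("band_"):
            try:
                k = int(c.split("_", 1)[1])
            except ValueError:
                continue
            if k == 1 and not include_first:
                continue
            cols.append((k, c))
    return [c for _, c in sorted(cols)]


def bandwise_chp_association(
    table: pd.DataFrame,
    predictor: str = "chp_norm",
    covariates: Sequence[str] = ("age", "sex", "center"),
    group: Optional[str] = None,
    group_col: str = "group",
    include_first: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-band regression of mean ratio on normalized ChP, BH-corrected.

    One regression per analysed band (b2..b10 by default) with the given
    covariates; Benjamini-Hochberg correction applied across the bands
    actually fitted (all-missing bands are skipped and shrink the family,
    reported via the ``m_bh`` column).  When ``group`` is given the table is
    restricted to that patient group first (the BH family is per group).
    """
    df = table if group is None else table[table[group_col] == group]
    cols = band_columns(df, include_first)
    if not cols:
        raise ValueError("no band-mean columns present")
    rows = []
    for c in cols:
        k = int(c.split("_", 1)[1])
        sub = df.dropna(subset=[c, predictor, *covariates])
        if len(sub) == 0:
            continue
        res = linear_association(sub, c, predictor, covariates, alpha)
        rows.append(
            {
                "band": k,
                "slope": res.coef(predictor),
                "se": float(res.params.loc[predictor, "se"]),
                "ci_low": res.ci(predictor)[0],
                "ci_high": res.ci(predictor)[1],
                "p": res.p(predictor),
                "adj_r2": res.adj_r2,
                "n": res.n,
            }
        )
    if not rows:
        raise ValueError("band means are missing for every band")
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out["m_bh"] = len(out)
    return out


def stratify_duration(
    table: pd.DataFrame,
    cutoff_years: float = 10.0,
    group_col: str = "group",
    duration_col: str = "disease_duration",
    patient_groups: Sequence[str] = ("RRMS", "PPMS"),
    include_first: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Band profiles for short vs long disease duration per patient group.

    Duration >= cutoff is assigned to the long-duration subgroup (the cutoff
    itself counts as long).  Rows with missing duration are excluded and
    counted.  Returns (profile frame: stratum x band with mean, se, n) and an
    info dict (missing counts, empty strata).
    """
    cols = band_columns(table, include_first)
    rows = []
    info: dict = {"n_missing_duration": 0, "empty_strata": []}
    for g in patient_groups:
        sub = table[table[group_col] == g]
        miss = int(sub[duration_col].isna().sum())
        info["n_missing_duration"] += miss
        sub = sub.dropna(subset=[duration_col])
        for tag, sel in (
            ("sd", sub[sub[duration_col] < cutoff_years]),
            ("ld", sub[sub[duration_col] >= cutoff_years]),
        ):
            stratum = f"{g}_{tag}"
            if len(sel) == 0:
                info["empty_strata"].append(stratum)
                continue
            for c in cols:
                vals = sel[c].dropna()
                n = len(vals)
                rows.append(
                    {
                        "stratum": stratum,
                        "band": int(c.split("_", 1)[1]),
                        "mean": float(vals.mean()) if n else math.nan,
                        "se": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows), info


# ---------------------------------------------------------------------------
# mixed model over bands
# ---------------------------------------------------------------------------


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame  # coef, se, ci_low, ci_high, p
    random_intercept_sd: float
    residual_sd: float
    converged: bool
    n_subjects: int
    n_obs: int
    formula: str
    diagnostics: str = ""


def cohort_to_long(
    table: pd.DataFrame,
    id_cols: Sequence[str] = ("subject", "group", "age", "sex", "center"),
    include_first: bool = False,
) -> pd.DataFrame:
    """Melt the wide cohort table into a subject x band long table."""
    cols = band_columns(table, include_first)
    long = table.melt(
        id_vars=[c for c in id_cols if c in table.columns],
        value_vars=cols,
        var_name="band",
        value_name="ratio",
    )
    long["band"] = long["band"].str.split("_").str[1].astype(int)
    return long.dropna(subset=["ratio"])


def mixed_model_bands(
    long: pd.DataFrame,
    outcome: str = "ratio",
    subject_col: str = "subject",
    band_col: str = "band",
    group_col: str = "group",
    covariates: Sequence[str] = ("age", "sex", "center"),
    reml: bool = True,
    alpha: float = 0.05,
) -> MixedModelResult:
    """Linear mixed model: ratio ~ group x band + covariates + (1 | subject).

    Band enters as a categorical factor; group-by-band interaction terms are
    the band-specific group contrasts.  Fitted by REML.  Non-convergence is
    flagged in the result (with diagnostics), never silently replaced.
    """
    df = long.dropna(subset=[outcome, subject_col, band_col, group_col, *covariates]).copy()
    per_subject = df.groupby(subject_col)[band_col].nunique()
    if (per_subject >= 2).sum() < 10:
        raise ValueError("need >= 2 bands per subject for >= 10 subjects")
    terms = [f"C({group_col})*C({band_col})"]
    for c in covariates:
        terms.append(c if _is_numeric(df[c]) else f"C({c})")
    formula = f"{outcome} ~ " + " + ".join(terms)
    model = smf.mixedlm(formula, df, groups=df[subject_col])
    diagnostics = ""
    try:
        try:
            fit = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            # boundary cases (near-zero random-effect variance) can break the
            # default optimizer; Powell is derivative-free and robust there
            fit = model.fit(reml=reml, method="powell")
        converged = bool(getattr(fit, "converged", True))
    except Exception as exc:  # keep the failure visible, not silent
        return MixedModelResult(
            fixed_effects=pd.DataFrame(),
            random_intercept_sd=math.nan,
            residual_sd=math.nan,
            converged=False,
            n_subjects=int(df[subject_col].nunique()),
            n_obs=len(df),
            formula=formula,
            diagnostics=f"fit failed: {exc}",
        )
    fe = fit.fe_params
    ci = fit.conf_int(alpha).loc[fe.index]
    fixed = pd.DataFrame(
        {
            "coef": fe,
            "se": fit.bse.loc[fe.index],
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues.loc[fe.index],
        }
    )
    if not converged:
        diagnostics = "optimizer reported non-convergence"
    return MixedModelResult(
        fixed_effects=fixed,
        random_intercept_sd=float(np.sqrt(fit.cov_re.iloc[0, 0])),
        residual_sd=float(np.sqrt(fit.scale)),
        converged=converged,
        n_subjects=int(df[subject_col].nunique()),
        n_obs=len(df),
        formula=formula,
        diagnostics=diagnostics,
    )
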