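"""End-to-end orchestration: phantom/real cohorts -> ratio -> bands -> stats.

A run takes a serializable :class:`RunConfig`, processes every subject
(volumetry, calibration-mask construction, template building, per-subject
calibration, ratio formation, band construction and band statistics), then
runs the cohort statistical layer and writes a results bundle:

* ``config.yaml``   — the exact configuration of the run (provenance)
* ``cohort.csv``    — one row per subject: covariates, volumes, band means
* ``bands_long.csv``— subject x band long table
* ``results.json``  — statistics keyed by analysis name (fig1_ancova,
  fig2_duration, fig3_volumes, fig4_profiles, fig5_bandwise, fig6_stratified,
  supp_mixed)
* ``run.log``       — versions, seed, per-subject exclusions

Subjects failing any stage are excluded from statistics with a logged
reason; the run aborts only if fewer than two usable subjects remain.
Re-running the same config and seed reproduces the tables and JSON
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BandSet, band_means, build_bands
from .phantom import CohortSpec, PhantomSpec, generate_cohort
from .ratio import build_template, calibrate, calibration_mask, compute_ratio, default_quantile_levels
from .stats import (
    AncovaResult,
    LvvModelComparison,
    MixedModelResult,
    ModelResult,
    ancova_groups,
    bandwise_chp_association,
    cohort_to_long,
    log_association_lvv,
    linear_association,
    mixed_model_bands,
    stratify_duration,
)
from .volumetry import subject_volumes

__all__ = ["RunConfig", "ResultBundle", "run", "report"]


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "real"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    manifest: Optional[str] = None  # real mode: CSV with subject, labels, t1w, flair
    covariates_table: Optional[str] = None  # real mode: delimited covariate table
    n_bands: int = 10
    connectivity: int = 26
    quantile_count: int = 101
    reference_set: str = "all"  # "all" | "CS"
    denominator_floor: Optional[float] = None
    duration_cutoff_years: float = 10.0
    alpha: float = 0.05
    include_first_band: bool = False
    save_volumes: bool = False
    seed: int = 0
    out_dir: str = "pvgradient_run"

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("cohort"), dict):
            c = dict(d["cohort"])
            if isinstance(c.get("phantom"), dict):
                p = dict(c["phantom"])
                for key in ("grid_shape", "ventricle_halfwidths_mm"):
                    if key in p and isinstance(p[key], list):
                        p[key] = tuple(p[key])
                c["phantom"] = PhantomSpec(**p)
            for key in ("age_mean_sd", "duration_gamma", "lvv_lognormal"):
                if key in c and isinstance(c[key], dict):
                    c[key] = {g: tuple(v) for g, v in c[key].items()}
            d["cohort"] = CohortSpec(**c)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ResultBundle:
    out_dir: Path
    cohort: pd.DataFrame
    bands_long: pd.DataFrame
    results: dict
    log_lines: list[str]


# ---------------------------------------------------------------------------
# serialization of stats results
# ---------------------------------------------------------------------------


def _clean(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def _model_dict(m: ModelResult) -> dict:
    return {
        "formula": m.formula,
        "n": m.n,
        "adj_r2": _clean(m.adj_r2),
        "terms": {
            str(t): {k: _clean(v) for k, v in row.items()}
            for t, row in m.params.to_dict(orient="index").items()
        },
    }


def _ancova_dict(a: AncovaResult) -> dict:
    return {
        "model": _model_dict(a.model),
        "adjusted_means": {k: _clean(v) for k, v in a.adjusted_means.items()},
        "group_counts": a.group_counts,
        "comparisons": [
            {k: _clean(v) for k, v in dataclasses.asdict(c).items()} for c in a.comparisons
        ],
    }


def _mixed_dict(m: MixedModelResult) -> dict:
    return {
        "formula": m.formula,
        "converged": m.converged,
        "diagnostics": m.diagnostics,
        "n_subjects": m.n_subjects,
        "n_obs": m.n_obs,
        "random_intercept_sd": _clean(m.random_intercept_sd),
        "residual_sd": _clean(m.residual_sd),
        "fixed_effects": {
            str(t): {k: _clean(v) for k, v in row.items()}
            for t, row in m.fixed_effects.to_dict(orient="index").items()
        },
    }


def _frame_records(df: pd.DataFrame) -> list[dict]:
    return [
        {k: _clean(v) for k, v in rec.items()} for rec in df.to_dict(orient="records")
    ]


# ---------------------------------------------------------------------------
# per-subject processing
# ---------------------------------------------------------------------------


def _load_real_subjects(config: RunConfig):
    from .io import load_intensity_volume, load_label_volume

    if not config.manifest or not config.covariates_table:
        raise ValueError("real mode requires manifest and covariates_table paths")
    manifest = pd.read_csv(config.manifest)
    covs = pd.read_csv(config.covariates_table).set_index("subject")
    for _, row in manifest.iterrows():
        sid = row["subject"]
        yield (
            sid,
            load_label_volume(row["labels"]),
            load_intensity_volume(row["t1w"]),
            load_intensity_volume(row["flair"]),
            covs.loc[sid].to_dict() if sid in covs.index else {},
        )


def run(config: RunConfig) -> ResultBundle:
    """Execute the full pipeline and write the results bundle to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"pvgradient {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"mode={config.mode} seed={config.seed} n_bands={config.n_bands} "
        f"connectivity={config.connectivity}",
    ]
    failures: list[dict] = []

    if config.mode == "synthetic":
        cohort = generate_cohort(config.cohort, seed=config.seed)
        subject_iter = [
            (s.subject_id, s.labels, s.t1w, s.flair, s.covariates) for s in cohort.subjects
        ]
        truth = cohort.truth
    elif config.mode == "real":
        subject_iter = list(_load_real_subjects(config))
        truth = None
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # stage 1: volumetry + calibration masks
    staged = []
    for sid, labels, t1w, flair, covs in subject_iter:
        try:
            vols = subject_volumes(labels)
            mask = calibration_mask(labels)
            staged.append((sid, labels, t1w, flair, covs, vols, mask))
        except Exception as exc:
            failures.append({"subject": sid, "stage": "volumetry", "reason": str(exc)})
            log.append(f"EXCLUDED {sid} at volumetry: {exc}")
    if len(staged) < 2:
        raise RuntimeError(
            f"fewer than 2 usable subjects remain ({len(staged)}); aborting"
        )

    # stage 2: study templates from the reference set
    levels = default_quantile_levels(config.quantile_count)
    if config.reference_set == "all":
        ref = staged
    else:
        ref = [s for s in staged if s[4].get("group") == config.reference_set]
        if not ref:
            raise ValueError(
                f"reference_set={config.reference_set!r} matches no usable subject"
            )
    t1_template = build_template([s[2] for s in ref], [s[6] for s in ref], levels, "T1w")
    flair_template = build_template([s[3] for s in ref], [s[6] for s in ref], levels, "FLAIR")
    t1_template.to_json(out / "template_t1w.json")
    flair_template.to_json(out / "template_flair.json")

    # stage 3: calibration, ratio, bands, band statistics
    rows = []
    long_rows = []
    for sid, labels, t1w, flair, covs, vols, mask in staged:
        try:
            t1c = calibrate(t1w, mask, t1_template)
            flc = calibrate(flair, mask, flair_template)
            ratio = compute_ratio(t1c, flc, config.denominator_floor)
            # dilation source is the full ventricle lumen (ChP lies inside it)
            bset = build_bands(
                labels.mask("ventricle") | labels.mask("chp"),
                labels.mask("wm"),
                labels.mask("lesion") if "lesion" in labels.label_table else None,
                n_bands=config.n_bands,
                connectivity=config.connectivity,
                exclude_first=not config.include_first_band,
            )
            bm = band_means(ratio, bset)
        except Exception as exc:
            failures.append({"subject": sid, "stage": "ratio/bands", "reason": str(exc)})
            log.append(f"EXCLUDED {sid} at ratio/bands: {exc}")
            continue
        row = {"subject": sid}
        for key in ("group", "age", "sex", "center", "disease_duration", "edss", "lesion_count"):
            if key in covs:
                row[key] = covs[key]
        row.update(vols.as_dict())
        for rec in bm.to_dict(orient="records"):
            row[f"band_{rec['band']}"] = rec["mean"]
            long_rows.append(
                {
                    "subject": sid,
                    "group": covs.get("group"),
                    "age": covs.get("age"),
                    "sex": covs.get("sex"),
                    "center": covs.get("center"),
                    "band": rec["band"],
                    "ratio": rec["mean"],
                    "sd": rec["sd"],
                    "n_voxels": rec["n_voxels"],
                    "excluded": rec["excluded"],
                }
            )
        rows.append(row)
        if config.save_volumes:
            from .io import save_intensity_volume, save_label_volume

            vdir = out / "volumes"
            vdir.mkdir(exist_ok=True)
            save_label_volume(labels, vdir / f"{sid}_labels.nii.gz")
            save_intensity_volume(ratio_to_intensity(ratio), vdir / f"{sid}_ratio.nii.gz")

    if len(rows) < 2:
        raise RuntimeError(f"fewer than 2 usable subjects remain ({len(rows)}); aborting")
    cohort_df = pd.DataFrame(rows)
    bands_long = pd.DataFrame(long_rows)
    log.append(f"usable subjects: {len(rows)}; excluded: {len(failures)}")

    results = _run_statistics(cohort_df, config, truth)
    results["exclusions"] = failures

    cohort_df.to_csv(out / "cohort.csv", index=False)
    bands_long.to_csv(out / "bands_long.csv", index=False)
    (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return ResultBundle(out, cohort_df, bands_long, results, log)


def ratio_to_intensity(ratio):
    from .volumetry import IntensityVolume

    grid = np.where(ratio.valid, ratio.grid, 0.0)
    return IntensityVolume(grid, ratio.voxel_size_mm)


def _run_statistics(cohort_df: pd.DataFrame, config: RunConfig, truth) -> dict:
    results: dict = {}
    patient_groups = [g for g in ("RRMS", "PPMS") if (cohort_df["group"] == g).any()]

    def attempt(key, fn):
        try:
            results[key] = fn()
        except Exception as exc:
            results[key] = {"error": str(exc)}

    attempt(
        "fig1_ancova",
        lambda: _ancova_dict(
            ancova_groups(cohort_df, "chp_norm", ("age", "sex", "center"), alpha=config.alpha)
        ),
    )
    attempt(
        "fig2_duration",
        lambda: {
            g: _model_dict(
                linear_association(
                    cohort_df[cohort_df["group"] == g],
                    "chp_norm",
                    "disease_duration",
                    ("age", "sex"),
                    config.alpha,
                )
            )
            for g in patient_groups
        },
    )

    def fig3():
        outd = {}
        for g in patient_groups:
            sub = cohort_df[cohort_df["group"] == g]
            gd = {}
            for pred in ("cortex_norm", "wm_norm", "lesion_ml"):
                gd[pred] = _model_dict(
                    linear_association(sub, "chp_norm", pred, ("age", "sex"), config.alpha)
                )
            cmp_ = log_association_lvv(sub, "chp_norm", ("age", "sex"), "lvv_ml", config.alpha)
            gd["lvv"] = {
                "log_model": _model_dict(cmp_.log_model),
                "linear_model": _model_dict(cmp_.linear_model),
                "log_better": cmp_.log_better,
                "n_excluded_nonpositive": cmp_.n_excluded_nonpositive,
            }
            outd[g] = gd
        return outd

    attempt("fig3_volumes", fig3)

    def fig4():
        profiles = []
        from .stats import band_columns

        cols = band_columns(cohort_df, config.include_first_band)
        for g, sub in cohort_df.groupby("group"):
            for c in cols:
                vals = sub[c].dropna()
                if len(vals) == 0:
                    continue
                profiles.append(
                    {
                        "group": g,
                        "band": int(c.split("_", 1)[1]),
                        "mean": float(vals.mean()),
                        "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else None,
                        "n": int(len(vals)),
                    }
                )
        return profiles

    attempt("fig4_profiles", fig4)
    attempt(
        "fig5_bandwise",
        lambda: {
            g: _frame_records(
                bandwise_chp_association(
                    cohort_df,
                    group=g,
                    include_first=config.include_first_band,
                    alpha=config.alpha,
                )
            )
            for g in patient_groups
        },
    )

    def fig6():
        prof, info = stratify_duration(
            cohort_df,
            cutoff_years=config.duration_cutoff_years,
            include_first=config.include_first_band,
        )
        return {"profiles": _frame_records(prof), "info": info}

    attempt("fig6_stratified", fig6)
    attempt(
        "supp_mixed",
        lambda: _mixed_dict(
            mixed_model_bands(
                cohort_to_long(cohort_df, include_first=config.include_first_band),
                alpha=config.alpha,
            )
        ),
    )
    if truth is not None:
        results["truth"] = json.loads(json.dumps(truth, default=_clean))
    return results


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

_ANALYSES = (
    "fig1_ancova",
    "fig2_duration",
    "fig3_volumes",
    "fig4_profiles",
    "fig5_bandwise",
    "fig6_stratified",
    "supp_mixed",
)


def report(bundle: ResultBundle | dict | str | Path) -> str:
    """Human-readable summary of a results bundle (tables as plain text)."""
    if isinstance(bundle, ResultBundle):
        results = bundle.results
    elif isinstance(bundle, dict):
        results = bundle
    else:
        results = json.loads((Path(bundle) / "results.json").read_text())

    lines: list[str] = ["periventricular gradient analysis - summary", "=" * 44]
    absent = [k for k in _ANALYSES if k not in results]
    if absent:
        lines.append("absent analyses: " + ", ".join(absent))

    a = results.get("fig1_ancova")
    if a and "error" not in a:
        lines.append("")
        lines.append("Group comparison of normalized ChP (ANCOVA, adjusted means):")
        for g, m in sorted(a["adjusted_means"].items()):
            lines.append(f"  {g:6s} adjusted mean {m:.6g} (n={a['group_counts'].get(g)})")
        for c in a["comparisons"]:
            lines.append(
                f"  {c['contrast']:12s} diff {c['estimate']:+.6g}  "
                f"p_adj={c['p_adjusted']:.4g} ({c['method']})"
            )

    prof = results.get("fig4_profiles")
    if isinstance(prof, list) and prof:
        lines.append("")
        lines.append("Band-profile means (group x band):")
        groups = sorted({p["group"] for p in prof})
        bands = sorted({p["band"] for p in prof})
        lines.append("  band  " + "  ".join(f"{g:>8s}" for g in groups))
        for b in bands:
            vals = []
            for g in groups:
                hit = [p for p in prof if p["group"] == g and p["band"] == b]
                vals.append(f"{hit[0]['mean']:8.4f}" if hit else " " * 8)
            lines.append(f"  b{b:<4d}" + "  ".join(vals))

    bw = results.get("fig5_bandwise")
    if isinstance(bw, dict):
        lines.append("")
        lines.append("Band-wise ChP-ratio association (slope per band, BH-adjusted p):")
        for g, recs in sorted(bw.items()):
            if not isinstance(recs, list):
                continue
            lines.append(f"  {g}:")
            for r in recs:
                flag = "*" if (r["p_bh"] is not None and r["p_bh"] < 0.05) else " "
                lines.append(
                    f"    b{r['band']:<3d} slope {r['slope']:+.4g}  p_bh={r['p_bh']:.4g}{flag}"
                )

    strat = results.get("fig6_stratified")
    if isinstance(strat, dict) and "profiles" in strat:
        lines.append("")
        lines.append("Duration-stratified band means:")
        for r in strat["profiles"]:
            lines.append(
                f"  {r['stratum']:9s} b{r['band']:<3d} mean {r['mean']:.4f} (n={r['n']})"
            )
        if strat.get("info", {}).get("empty_strata"):
            lines.append("  empty strata: " + ", ".join(strat["info"]["empty_strata"]))

    mm = results.get("supp_mixed")
    if isinstance(mm, dict) and "error" not in mm:
        lines.append("")
        lines.append(
            f"Mixed model: random-intercept SD {mm.get('random_intercept_sd'):.4g}, "
            f"residual SD {mm.get('residual_sd'):.4g}, converged={mm.get('converged')}"
        )

    exc = results.get("exclusions")
    if exc:
        lines.append("")
        lines.append(f"Excluded subjects: {len(exc)}")
        for e in exc:
            lines.append(f"  {e['subject']} at {e['stage']}: {e['reason']}")
    lines.append("")
    return "\n".join(lines)
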