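"""End-to-end study pipeline: cohort assembly through tables and regressions.

Stages: lesion-atlas intersection for every subject, PV-weighted regional
metrics, HC reference fit and Z-scoring, subject summaries, cognitive
phenotyping, then the four analysis blocks — demographics, lesion
topography, integrity comparisons (global + network) and the regression
battery — each with explicit Bonferroni family bookkeeping. Every number
in the report is recomputable from the shipped intermediate tables by
calling the corresponding statistical primitive directly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lesions, phenotype, regional, stats
from .atlas import ParcellationAtlas
from .config import DOMAINS, MS_PHENOTYPES, SimulationConfig
from .errors import PipelineError
from .simulate import SyntheticStudy, simulate_study

#: Networks whose non-lesional MD Z enters the cognition regression.
CANDIDATE_NETWORKS = ("FPN", "SMN", "DMN")

COVARIATES = ("age", "sex_female", "educ_high")


@dataclass
class AnalysisPlan:
    """Explicit, serializable statement of the statistical workflow."""

    families: dict[str, int] = field(
        default_factory=lambda: {
            "demographics": 1,       # descriptive table, raw p reported
            "global_cl": 2,          # CL count + volume
            "network_cl": 14,        # 7 networks x (presence, fraction)
            "integrity_global": 2,   # MD + FA per analysis block
            "integrity_network": 7,  # 7 networks, non-lesional MD Z
            "regression_primary": 1,
            "regression_domains": 7,
        }
    )
    covariates: tuple[str, ...] = COVARIATES
    #: Table-1-style subgroup tests run unadjusted; integrity analyses adjust
    adjust_demographics: bool = False
    #: force demographic covariates into the cognition regressions
    force_covariates_in_regression: bool = True
    alpha_stay: float = 0.05
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AnalysisPlan":
        with open(path) as fh:
            d = json.load(fh)
        d["covariates"] = tuple(d["covariates"])
        return cls(**d)


@dataclass
class StudyTables:
    """Intermediate per-subject tables feeding every analysis block."""

    atlas: ParcellationAtlas
    cohort: pd.DataFrame
    summaries: pd.DataFrame
    region_long: pd.DataFrame
    reference: regional.ReferenceModel
    topographies: dict[str, lesions.LesionTopography]


@dataclass
class StudyReport:
    demographics: pd.DataFrame
    lesion_topography: pd.DataFrame
    integrity: pd.DataFrame
    networks: pd.DataFrame
    regressions: pd.DataFrame
    run_log: list[str]
    meta: dict


# ----------------------------------------------------------------------
def extract_study_tables(study: SyntheticStudy, log: list[str] | None = None) -> StudyTables:
    """Lesion intersection, regional metrics, reference fit, phenotyping."""
    log = log if log is not None else []
    atlas = study.atlas
    topographies: dict[str, lesions.LesionTopography] = {}
    region_tables: dict[str, pd.DataFrame] = {}
    for subj, img in study.images.items():
        topo = lesions.intersect_lesions(atlas, img.cl_mask, subject=subj)
        topographies[subj] = topo
        lesional, _ = lesions.lesional_region_split(topo)
        region_tables[subj] = regional.region_metric_table(
            atlas, img.fa, img.md, img.pv, lesional_regions=lesional
        )

    hc = study.hc_subjects
    reference = regional.fit_reference([region_tables[s] for s in hc])
    log.append(f"reference fitted on {len(hc)} HC subjects")

    rows = {}
    long_parts = []
    for subj, tab in region_tables.items():
        tab = regional.add_zscores(tab, reference)
        rows[subj] = regional.summarize_subject(tab)
        part = tab.reset_index()
        part.insert(0, "subject", subj)
        long_parts.append(part)
    summaries = pd.DataFrame(rows).T
    summaries.index.name = "subject"
    region_long = pd.concat(long_parts, ignore_index=True)

    dom_ref = phenotype.fit_domain_reference(study.cohort.loc[hc])
    cohort = phenotype.label_cohort(study.cohort, dom_ref)

    # lesion-derived subject columns
    topo_rows = {}
    for subj, topo in topographies.items():
        row = {
            "cl_count": topo.total_cl_count,
            "cl_volume_ml": topo.total_cl_volume_ml,
            "has_cl": int(topo.total_cl_count > 0),
            "n_lesional_regions": topo.n_lesional_regions,
        }
        for net, r in topo.network_table.iterrows():
            row[f"cl_presence_{net}"] = int(r["has_cl"])
            row[f"cl_fraction_{net}"] = r["cl_fraction_e3pct"]
            row[f"cl_volume_{net}_ml"] = r["cl_volume_mm3"] / 1000.0
        topo_rows[subj] = row
    cohort = pd.concat(
        [cohort, pd.DataFrame.from_dict(topo_rows, orient="index").reindex(cohort.index)],
        axis=1,
    )
    summary_cols = summaries.drop(columns=["n_lesional_regions"], errors="ignore")
    cohort = pd.concat([cohort, summary_cols.reindex(cohort.index)], axis=1)
    n_unclassified = int(cohort.loc[cohort["group"] == "MS", "phenotype"].isna().sum())
    if n_unclassified:
        log.append(f"{n_unclassified} MS subjects unclassifiable (too few domains)")
    return StudyTables(atlas, cohort, summaries, region_long, reference, topographies)


# ----------------------------------------------------------------------
def _fmt_mean_sd(x: pd.Series) -> str:
    x = x.dropna()
    return f"{x.mean():.2f} ({x.std(ddof=1):.2f})" if len(x) > 1 else ""


def _fmt_median_range(x: pd.Series) -> str:
    x = x.dropna()
    if not len(x):
        return ""
    return f"{x.median():.2f} [{x.min():.2f}-{x.max():.2f}]"


def _fmt_n_pct(x: pd.Series) -> str:
    x = x.dropna()
    if not len(x):
        return ""
    return f"{int(x.sum())} ({100 * x.mean():.1f}%)"


def _row(variable, comparison, res: stats.StatResult, family: str, m: int, **desc):
    res.correct(m)
    df = res.df
    if isinstance(df, tuple):
        df = f"{df[0]:g},{df[1]:g}"
    return {
        "variable": variable,
        "comparison": comparison,
        "test": res.test_name,
        "statistic": res.statistic,
        "df": df,
        "p_raw": res.p_raw,
        "p_corrected": res.p_corrected,
        "family": family,
        "family_size": m,
        "n_used": res.n_used,
        "effect_name": res.effect_name,
        "effect_size": res.effect_size,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        **desc,
    }


def _append(rows, log, variable, comparison, family, m, fn, **desc):
    """Run one comparison; degenerate inputs are skipped with a log line."""
    from .errors import DegenerateDataError

    try:
        rows.append(_row(variable, comparison, fn(), family, m, **desc))
    except DegenerateDataError as exc:
        log.append(f"skipped {variable} ({comparison}): {exc}")


def _subgroup_frames(cohort: pd.DataFrame):
    ms = cohort[cohort["group"] == "MS"].dropna(subset=["phenotype"])
    return ms, {g: ms[ms["phenotype"] == g] for g in MS_PHENOTYPES}


# ----------------------------------------------------------------------
def run_demographics(tables: StudyTables, plan: AnalysisPlan, log: list[str]) -> pd.DataFrame:
    """Table-1 analogue: HC vs MS and three-subgroup comparisons."""
    cohort = tables.cohort
    hc = cohort[cohort["group"] == "HC"]
    ms, sub = _subgroup_frames(cohort)
    m = plan.families["demographics"]
    rows = []
    if ms["phenotype"].nunique() < 2:
        log.append("demographics: <2 MS subgroups present; subgroup tests skipped")

    def both(variable, col, kind="continuous"):
        desc = {}
        fmt = _fmt_mean_sd if kind == "continuous" else _fmt_n_pct
        desc["desc_HC"] = fmt(hc[col]) if col in hc else ""
        desc["desc_MS"] = fmt(ms[col])
        for g in MS_PHENOTYPES:
            desc[f"desc_{g}"] = fmt(sub[g][col])
        if kind == "continuous":
            if col in hc and hc[col].notna().any():
                _append(rows, log, variable, "HC_vs_MS", "demographics", m,
                        lambda: stats.choose_t(hc[col], ms[col]), **desc)
            if ms["phenotype"].nunique() >= 2:
                cov = ms[list(plan.covariates)] if plan.adjust_demographics else None
                _append(rows, log, variable, "subgroups", "demographics", m,
                        lambda: stats.glm_group_f(ms[col], ms["phenotype"], cov),
                        **desc)
        else:  # binary categorical
            if col in hc and hc[col].notna().any():
                tab = [
                    [int(hc[col].sum()), int((1 - hc[col]).sum())],
                    [int(ms[col].sum()), int((1 - ms[col]).sum())],
                ]
                _append(rows, log, variable, "HC_vs_MS", "demographics", m,
                        lambda: stats.pearson_chi_square(tab), **desc)
            if ms["phenotype"].nunique() >= 2:
                tab = [
                    [int(sub[g][col].sum()), int((1 - sub[g][col]).sum())]
                    for g in MS_PHENOTYPES
                ]
                _append(rows, log, variable, "subgroups", "demographics", m,
                        lambda: stats.pearson_chi_square(tab), **desc)

    both("age", "age")
    both("sex_female", "sex_female", "binary")
    both("educ_high", "educ_high", "binary")

    # MS-only ordinal / categorical characteristics
    if ms["phenotype"].nunique() >= 2:
        _append(rows, log, "edss", "subgroups", "demographics", m,
                lambda: stats.kruskal_wallis(
                    *[sub[g]["edss"] for g in MS_PHENOTYPES]),
                desc_MS=_fmt_median_range(ms["edss"]),
                **{f"desc_{g}": _fmt_median_range(sub[g]["edss"])
                   for g in MS_PHENOTYPES})
        tab = pd.crosstab(ms["phenotype"], ms["ms_subtype"])
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            _append(rows, log, "ms_subtype", "subgroups", "demographics", m,
                    lambda: stats.pearson_chi_square(tab.to_numpy()))

    both("avg_cog_z", "avg_cog_z")
    for d in DOMAINS:
        both(f"domain_{d}", f"domain_z_{d}")
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def run_lesion_topography(tables: StudyTables, plan: AnalysisPlan, log: list[str]) -> pd.DataFrame:
    """Table-2 analogue: CL presence/count/volume globally and per network."""
    cohort = tables.cohort
    ms, sub = _subgroup_frames(cohort)
    cov = ms[list(plan.covariates)]
    rows = []

    def multinomial_rows(variable, predictor, family, m, **desc):
        if predictor.nunique() <= 1:
            log.append(f"lesion_topography: {variable} constant; OR undefined")
            return
        try:
            fits = stats.multinomial_logistic(
                ms["phenotype"], predictor, cov, reference_level="CP"
            )
        except stats.ConvergenceError as exc:  # pragma: no cover - data dependent
            log.append(f"lesion_topography: {variable}: {exc}")
            return
        for lvl in ("mildly_CI", "CI"):
            if lvl in fits:
                rows.append(_row(variable, f"{lvl}_vs_CP", fits[lvl], family, m, **desc))

    def fraction_rows(variable, col, family, m, **desc):
        if ms[col].fillna(0.0).nunique() <= 1:
            log.append(f"lesion_topography: {variable} constant; comparison skipped")
            return
        vals = stats.log1p_transform(ms[col].fillna(0.0))
        screen = stats.normality_screen(vals)
        if screen.extra["normal"]:
            multinomial_rows(variable, pd.Series(vals, index=ms.index), family, m, **desc)
        else:
            for lvl in ("mildly_CI", "CI"):
                x = stats.log1p_transform(sub["CP"][col].fillna(0.0))
                y = stats.log1p_transform(sub[lvl][col].fillna(0.0))
                res = stats.mann_whitney_u(y, x)
                rows.append(_row(variable, f"{lvl}_vs_CP", res, family, m, **desc))

    m_g = plan.families["global_cl"]
    desc = {"desc_MS": _fmt_n_pct(ms["has_cl"]),
            **{f"desc_{g}": _fmt_n_pct(sub[g]["has_cl"]) for g in MS_PHENOTYPES}}
    multinomial_rows("cl_presence", ms["has_cl"].astype(float), "global_cl", m_g, **desc)
    for variable, col in (("cl_count", "cl_count"), ("cl_volume_ml", "cl_volume_ml")):
        desc = {"desc_MS": _fmt_median_range(ms[col]),
                **{f"desc_{g}": _fmt_median_range(sub[g][col]) for g in MS_PHENOTYPES}}
        multinomial_rows(
            variable, pd.Series(stats.log1p_transform(ms[col]), index=ms.index),
            "global_cl", m_g, **desc,
        )

    m_n = plan.families["network_cl"]
    for net in tables.atlas.networks:
        pcol, fcol = f"cl_presence_{net}", f"cl_fraction_{net}"
        desc = {"desc_MS": _fmt_n_pct(ms[pcol]),
                **{f"desc_{g}": _fmt_n_pct(sub[g][pcol]) for g in MS_PHENOTYPES}}
        multinomial_rows(f"presence_{net}", ms[pcol].astype(float),
                         "network_cl", m_n, **desc)
        desc = {"desc_MS": _fmt_median_range(ms[fcol]),
                **{f"desc_{g}": _fmt_median_range(sub[g][fcol]) for g in MS_PHENOTYPES}}
        fraction_rows(f"fraction_{net}", fcol, "network_cl", m_n, **desc)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def run_integrity_comparisons(
    tables: StudyTables, plan: AnalysisPlan, log: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Table-3 + network analogues.

    Returns ``(integrity, networks)``: global raw-value comparisons (HC vs
    MS adjusted GLM, within-MS paired lesional vs non-lesional, subgroup
    GLMs) and per-network CP-vs-CI comparisons on non-lesional MD Z.
    """
    cohort = tables.cohort
    ms, sub = _subgroup_frames(cohort)
    cov_all = cohort[list(plan.covariates)]
    m2 = plan.families["integrity_global"]
    rows = []

    # HC vs MS on non-lesional raw metrics, covariate-adjusted
    for metric in ("md", "fa"):
        col = f"{metric}_raw_nonlesional"
        _append(rows, log, col, "HC_vs_MS", "integrity_global", m2,
                lambda col=col: stats.glm_group_f(
                    cohort[col], cohort["group"], cov_all),
                desc_HC=_fmt_mean_sd(cohort.loc[cohort["group"] == "HC", col]),
                desc_MS=_fmt_mean_sd(ms[col]))

    # within-subject lesional vs non-lesional (subjects with >= 1 lesional region)
    with_cl = ms[ms["n_lesional_regions"] > 0]
    excluded = len(ms) - len(with_cl)
    log.append(
        f"integrity: paired analyses on {len(with_cl)} MS subjects with CLs "
        f"({excluded} lesion-free excluded)"
    )
    for metric in ("md", "fa"):
        _append(rows, log, f"{metric}_raw", "lesional_vs_nonlesional_paired",
                "integrity_global", m2,
                lambda metric=metric: stats.paired_t(
                    with_cl[f"{metric}_raw_lesional"],
                    with_cl[f"{metric}_raw_nonlesional"]))

    # three-subgroup comparison on overall raw metrics, adjusted
    cov_ms = ms[list(plan.covariates)]
    for metric in ("md", "fa"):
        col = f"{metric}_raw_all"
        _append(rows, log, col, "subgroups", "integrity_global", m2,
                lambda col=col: stats.glm_group_f(ms[col], ms["phenotype"], cov_ms),
                **{f"desc_{g}": _fmt_mean_sd(sub[g][col]) for g in MS_PHENOTYPES})

    # CP vs CI on NA / lesional raw MD, restricted to subjects with CLs
    two = with_cl[with_cl["phenotype"].isin(["CP", "CI"])]
    for tissue in ("nonlesional", "lesional"):
        col = f"md_raw_{tissue}"
        _append(rows, log, col, "CP_vs_CI_lesioned_subset", "integrity_global", m2,
                lambda col=col: stats.glm_group_f(
                    two[col], two["phenotype"], two[list(plan.covariates)]))

    # per-network CP vs CI on non-lesional MD Z
    networks = network_md_comparisons(tables, plan, group_col="phenotype", log=log)
    return pd.DataFrame(rows), networks


def network_md_comparisons(
    tables: StudyTables,
    plan: AnalysisPlan,
    group_col: str = "phenotype",
    groups: tuple[str, str] = ("CP", "CI"),
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Per-network two-group comparison on non-lesional MD Z-scores.

    Covariate-adjusted GLM per network with the network-family Bonferroni
    correction. ``group_col`` may be the classified ``phenotype`` (the
    realistic analysis) or the generator's latent ``phenotype_true``
    (effect-recovery checks).
    """
    log = log if log is not None else []
    cohort = tables.cohort
    ms = cohort[cohort["group"] == "MS"].dropna(subset=[group_col])
    two = ms[ms[group_col].isin(list(groups))]
    m7 = plan.families["integrity_network"]
    rows = []
    for net in tables.atlas.networks:
        col = f"md_z_nonlesional_{net}"
        avail = two.dropna(subset=[col])
        _append(rows, log, col, f"{groups[0]}_vs_{groups[1]}",
                "integrity_network", m7,
                lambda col=col, avail=avail: stats.glm_group_f(
                    avail[col], avail[group_col], avail[list(plan.covariates)]),
                **{f"desc_{g}": _fmt_mean_sd(two.loc[two[group_col] == g, col])
                   for g in groups})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def run_regressions(tables: StudyTables, plan: AnalysisPlan, log: list[str]) -> pd.DataFrame:
    """Regression battery for average cognition and per-domain scores."""
    cohort = tables.cohort
    ms = cohort[cohort["group"] == "MS"]
    cand_cols = [f"md_z_nonlesional_{n}" for n in CANDIDATE_NETWORKS]
    usable = ms.dropna(subset=cand_cols + ["avg_cog_z"])
    if not len(usable):
        raise PipelineError("regressions", "no subjects with complete candidate cells")
    cov = usable[list(plan.covariates)] if plan.force_covariates_in_regression else None
    rows = []

    def model_rows(model_name, model: stats.RegressionModel, m, all_candidates):
        for term in all_candidates:
            if term in model.terms:
                r = model.terms[term].correct(m)
                rows.append({
                    "model": model_name, "term": term, "retained": True,
                    "beta_std": r.effect_size, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "p_raw": r.p_raw,
                    "p_corrected": r.p_corrected, "family_size": m,
                    "adj_r2": model.adj_r2, "n_used": model.n_used,
                })
            else:
                rows.append({
                    "model": model_name, "term": term, "retained": False,
                    "beta_std": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_raw": np.nan, "p_corrected": np.nan, "family_size": m,
                    "adj_r2": model.adj_r2, "n_used": model.n_used,
                })

    m1 = plan.families["regression_primary"]
    primary = stats.backward_regression(
        usable["avg_cog_z"], usable[cand_cols], cov, alpha_stay=plan.alpha_stay
    )
    log.append(
        f"regressions: primary model retained {primary.retained} "
        f"(adj R2 = {primary.adj_r2:.3f}, n = {primary.n_used})"
    )
    model_rows("avg_cognition_backward", primary, m1, cand_cols)

    # joint model: DMN non-lesional MD Z + log(x+1) DMN CL volume
    joint_pred = pd.DataFrame({
        "md_z_nonlesional_DMN": usable["md_z_nonlesional_DMN"],
        "log1p_cl_volume_DMN": stats.log1p_transform(
            usable["cl_volume_DMN_ml"].fillna(0.0)
        ),
    })
    joint = stats.linear_model(usable["avg_cog_z"], joint_pred, cov)
    model_rows("avg_cognition_joint_cl_volume", joint, m1, list(joint_pred.columns))

    m7 = plan.families["regression_domains"]
    for d in DOMAINS:
        dcol = f"domain_z_{d}"
        avail = usable.dropna(subset=[dcol])
        dm = stats.linear_model(
            avail[dcol], avail[["md_z_nonlesional_DMN"]],
            avail[list(plan.covariates)] if plan.force_covariates_in_regression else None,
        )
        model_rows(f"domain_{d}", dm, m7, ["md_z_nonlesional_DMN"])
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def run_all(
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
    plan: AnalysisPlan | None = None,
) -> StudyReport:
    """Simulate a study and run every analysis block; optionally write a report."""
    config = config or SimulationConfig()
    if seed is not None:
        config.seed = seed
    plan = plan or AnalysisPlan(seed=config.seed)
    log: list[str] = [f"run started, seed={config.seed}"]
    t0 = time.time()

    stages = {}
    try:
        stage = "simulate"
        study = simulate_study(config)
        log.append(f"simulated {len(study.images)} subjects "
                   f"({config.n_hc} HC, {config.n_ms} MS)")
        stage = "extract"
        tables = extract_study_tables(study, log)
        stage = "demographics"
        stages["demographics"] = run_demographics(tables, plan, log)
        stage = "lesion_topography"
        stages["lesion_topography"] = run_lesion_topography(tables, plan, log)
        stage = "integrity"
        integrity, networks = run_integrity_comparisons(tables, plan, log)
        stages["integrity"], stages["networks"] = integrity, networks
        stage = "regressions"
        stages["regressions"] = run_regressions(tables, plan, log)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    ms = tables.cohort[tables.cohort["group"] == "MS"]
    meta = {
        "seed": int(config.seed),
        "n_hc": int(config.n_hc),
        "n_ms": int(config.n_ms),
        "cl_prevalence_pct": float(100 * ms["has_cl"].mean()),
        "median_lesional_regions": float(ms["n_lesional_regions"].median()),
        "median_lesional_regions_pct": float(
            100 * ms["n_lesional_regions"].median() / tables.atlas.n_regions
        ),
        "families": dict(plan.families),
        "n_comparisons": {k: int(len(v)) for k, v in stages.items()},
        "elapsed_s": round(time.time() - t0, 2),
    }
    log.append(f"run finished in {meta['elapsed_s']} s")

    report = StudyReport(
        demographics=stages["demographics"],
        lesion_topography=stages["lesion_topography"],
        integrity=stages["integrity"],
        networks=stages["networks"],
        regressions=stages["regressions"],
        run_log=log,
        meta=meta,
    )
    if outdir is not None:
        write_report(report, tables, plan, Path(outdir))
    return report


def write_report(
    report: StudyReport, tables: StudyTables, plan: AnalysisPlan, outdir: Path
) -> None:
    """Write report TSVs, intermediates, run.json and run.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.demographics.to_csv(outdir / "table1.tsv", sep="\t", index=False)
    report.lesion_topography.to_csv(outdir / "table2.tsv", sep="\t", index=False)
    report.integrity.to_csv(outdir / "table3.tsv", sep="\t", index=False)
    report.networks.to_csv(outdir / "networks.tsv", sep="\t", index=False)
    report.regressions.to_csv(outdir / "regressions.tsv", sep="\t", index=False)
    tables.cohort.to_csv(outdir / "cohort.tsv", sep="\t")
    tables.summaries.to_csv(outdir / "summaries.tsv", sep="\t")
    plan.to_json(outdir / "plan.json")
    with open(outdir / "run.json", "w") as fh:
        json.dump(report.meta, fh, indent=1)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(report.run_log) + "\n")
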