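"""End-to-end orchestration of the regional subplate analysis.

The stages mirror the analysis narrative: measurement validation and
covariate correction (ANCOVA), trimester growth comparison with homotopic
Z-tests, the asymmetry suite (AI, lateralization, paired tests, AI-change),
and trajectory clustering with cluster metrics and bilateral symmetry.
Every stage consumes the long-format measure table (subject x region x
hemisphere x metric) plus the subject table, so the same entry points serve
synthetic cohorts and user-supplied CSVs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, CohortResult, generate_cohort
from .regions import ANALYSIS_METRICS
from .residualize import fit_growth_model, residualize
from .stats import (ai_change_ztest, ancova, assign_trimester_group, asymmetry_index,
                    bh_fdr, homotopic_growth_ztest, lateralization_test,
                    paired_homotopic_test, percent_change)
from .trajectories import bilateral_symmetry, growth_profile, ward_cluster

__all__ = [
    "RunConfig",
    "covariate_adjust",
    "whole_brain_table",
    "whole_brain_ancova",
    "trimester_analysis",
    "asymmetry_analysis",
    "trajectory_analysis",
    "run_pipeline",
]

# a residual covariate whose spread is below this fraction of its parent
# measure's scale carries no information (noiseless degenerate) and is skipped
_COVARIATE_EPS = 1e-6


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    cohort: CohortConfig | None = None          # synthetic input
    subjects_csv: str | None = None             # or user tables
    measures_csv: str | None = None
    metrics: tuple[str, ...] = ANALYSIS_METRICS
    group_boundary: float = 27.0
    alpha: float = 0.05
    k_candidates: tuple[int, ...] = tuple(range(2, 9))
    override_k: dict[str, int] = field(default_factory=dict)
    seed: int = 42                              # RANSAC / residualization seed
    output_dir: str = "results/run"


def _aligned(subjects: pd.DataFrame, measures: pd.DataFrame) -> pd.DataFrame:
    sub = subjects.set_index("subject_id")
    df = measures.merge(
        sub[["ga_weeks", "brain_volume_mm3"]], left_on="subject_id",
        right_index=True, how="left", validate="many_to_one")
    if df["ga_weeks"].isna().any():
        missing = df.loc[df["ga_weeks"].isna(), "subject_id"].unique()
        raise ValueError(f"measures reference unknown subjects: {missing[:5]}")
    return df


def _usable(x: np.ndarray, reference_scale: float) -> bool:
    return np.ptp(x) > _COVARIATE_EPS * max(1.0, abs(reference_scale))


def covariate_adjust(subjects: pd.DataFrame, measures: pd.DataFrame,
                     seed: int = 42, metrics=ANALYSIS_METRICS,
                     remove_ga: bool = True, group_col: str | None = None
                     ) -> pd.DataFrame:
    """Level-preserving covariate correction of every region x hemisphere x
    metric cell.

    Covariates in order: GA (optional — trajectory modelling keeps the GA
    trend), residual brain volume (brain volume with its GA trend removed),
    and for thickness additionally the regional SP depth, itself
    pre-corrected for GA and residual brain volume. When ``group_col`` is
    given the correction runs within each group separately, so trimester
    group means keep their level. Returns the long table with an
    ``adjusted`` column.
    """
    df = _aligned(subjects, measures)
    if group_col is not None:
        scopes = [g.copy() for _, g in df.groupby(group_col, sort=True)]
    else:
        scopes = [df.copy()]

    out = []
    for scope in scopes:
        subj = scope.drop_duplicates("subject_id").set_index("subject_id")
        ga = subj["ga_weeks"]
        bv = subj["brain_volume_mm3"]
        rbv = pd.Series(
            residualize(bv.to_numpy(), [(ga.to_numpy(), None)], seed=seed).residuals
            if _usable(bv.to_numpy(), bv.mean()) else np.zeros(len(subj)),
            index=subj.index)
        rbv_ok = _usable(rbv.to_numpy(), bv.mean())

        # depth residuals per region x hemisphere (covariate for thickness)
        depth_resid: dict[tuple[str, str], pd.Series] = {}
        if "thickness" in metrics:
            dep = scope[scope["metric"] == "depth"]
            for (r, h), cell in dep.groupby(["region", "hemisphere"], sort=True):
                cell = cell.set_index("subject_id")
                covs = [(ga.loc[cell.index].to_numpy(), None)]
                if rbv_ok:
                    covs.append((rbv.loc[cell.index].to_numpy(), None))
                res = residualize(cell["value"].to_numpy(), covs, seed=seed)
                depth_resid[(r, h)] = pd.Series(res.residuals, index=cell.index)

        for metric in metrics:
            sub = scope[scope["metric"] == metric]
            for (r, h), cell in sub.groupby(["region", "hemisphere"], sort=True):
                cell = cell.set_index("subject_id")
                y = cell["value"].to_numpy()
                covs = []
                if remove_ga:
                    covs.append((ga.loc[cell.index].to_numpy(), None))
                if rbv_ok:
                    covs.append((rbv.loc[cell.index].to_numpy(), None))
                if metric == "thickness" and (r, h) in depth_resid:
                    d = depth_resid[(r, h)].loc[cell.index].to_numpy()
                    if _usable(d, scope.loc[scope["metric"] == "depth",
                                            "value"].mean()):
                        covs.append((d, None))
                adj = residualize(y, covs, seed=seed, preserve_mean=True).residuals \
                    if covs else y.astype(float)
                cell = cell.reset_index()
                cell["adjusted"] = adj
                out.append(cell[["subject_id", "region", "hemisphere",
                                 "metric", "adjusted"]
                                + ([group_col] if group_col else [])])
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# whole-brain validation ANCOVA

def whole_brain_table(subjects: pd.DataFrame, measures: pd.DataFrame
                      ) -> pd.DataFrame:
    """Per-subject whole-brain summaries: thickness/depth averaged over
    region x hemisphere cells, area and volume summed."""
    agg = {"thickness": "mean", "depth": "mean", "area": "sum", "volume": "sum"}
    wide = {}
    for metric, how in agg.items():
        sub = measures[measures["metric"] == metric]
        if sub.empty:
            continue
        wide[metric] = sub.groupby("subject_id")["value"].agg(how)
    out = subjects.set_index("subject_id").join(pd.DataFrame(wide))
    return out.reset_index()


def whole_brain_ancova(subjects: pd.DataFrame, measures: pd.DataFrame,
                       seed: int = 42, metrics=ANALYSIS_METRICS) -> dict:
    """ANCOVA of whole-brain measures on GA, sex, and residual brain volume
    (with GA x sex and residual-volume x sex interactions); unknown sex is
    treated as missing."""
    wb = whole_brain_table(subjects, measures)
    ga = wb["ga_weeks"].to_numpy()
    rbv = residualize(wb["brain_volume_mm3"].to_numpy(), [(ga, None)],
                      seed=seed).residuals
    wb = wb.assign(rbv=rbv,
                   sex=wb["sex"].where(wb["sex"].isin(["M", "F"])))
    results = {}
    for metric in metrics:
        results[metric] = ancova(
            wb.rename(columns={metric: "y"}), response="y",
            covariates=["ga_weeks", "rbv"], factors=["sex"],
            interactions=[("ga_weeks", "sex"), ("rbv", "sex")])
    return results


# --------------------------------------------------------------------------
# trimester growth

def trimester_analysis(subjects: pd.DataFrame, measures: pd.DataFrame,
                       seed: int = 42, alpha: float = 0.05,
                       metrics=ANALYSIS_METRICS
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent change of group means between trimester groups, per
    region x hemisphere x metric, plus homotopic growth Z-tests
    (BH-corrected across regions within metric).
    """
    subjects = subjects.copy()
    subjects["group"] = assign_trimester_group(subjects["ga_weeks"])
    measures = measures.merge(subjects[["subject_id", "group"]], on="subject_id")
    adj = covariate_adjust(subjects, measures, seed=seed, metrics=metrics,
                           remove_ga=True, group_col="group")

    pc_rows = []
    pcs: dict[tuple[str, str, str], object] = {}
    for (metric, r, h), cell in adj.groupby(["metric", "region", "hemisphere"],
                                            sort=True):
        v1 = cell.loc[cell["group"] == "late2", "adjusted"].to_numpy()
        v2 = cell.loc[cell["group"] == "early3", "adjusted"].to_numpy()
        pc = percent_change(v1, v2, region=r, hemisphere=h, metric=metric)
        pcs[(metric, r, h)] = pc
        pc_rows.append(dict(region=r, hemisphere=h, metric=metric, pc=pc.pc,
                            se=pc.se, ci_low=pc.ci95[0], ci_high=pc.ci95[1],
                            n_late2=pc.group_ns[0], n_early3=pc.group_ns[1],
                            defined=pc.defined))
    pc_table = pd.DataFrame(pc_rows)

    homo_rows = []
    for metric in metrics:
        regions = sorted({r for (m, r, _) in pcs if m == metric})
        zs, ps = [], []
        for r in regions:
            z, p = homotopic_growth_ztest(pcs[(metric, r, "L")],
                                          pcs[(metric, r, "R")])
            zs.append(z)
            ps.append(p)
        q, rej = bh_fdr(ps, alpha=alpha)
        for r, z, p, qq, rr in zip(regions, zs, ps, q, rej):
            homo_rows.append(dict(region=r, metric=metric, z=z, p=p, q=qq,
                                  significant=bool(rr)))
    return pc_table, pd.DataFrame(homo_rows)


# --------------------------------------------------------------------------
# asymmetry suite

def _subject_ais(adj: pd.DataFrame) -> pd.DataFrame:
    piv = adj.pivot_table(index=["metric", "region", "subject_id"],
                          columns="hemisphere", values="adjusted",
                          aggfunc="first").reset_index()
    piv["ai"] = asymmetry_index(piv["L"].to_numpy(), piv["R"].to_numpy())
    return piv


def asymmetry_analysis(subjects: pd.DataFrame, measures: pd.DataFrame,
                       seed: int = 42, alpha: float = 0.05,
                       metrics=ANALYSIS_METRICS,
                       per_group: bool = True) -> dict[str, pd.DataFrame]:
    """Whole-cohort lateralization, paired homotopic tests, and (with
    ``per_group``) per-trimester AIs and AI-change Z-tests; FDR across
    regions within metric (and within group where applicable)."""
    adj = covariate_adjust(subjects, measures, seed=seed, metrics=metrics,
                           remove_ga=True)
    ais = _subject_ais(adj)

    lat_rows, paired_rows = [], []
    for metric in metrics:
        sub = ais[ais["metric"] == metric]
        regions = sorted(sub["region"].unique())
        lat, pair = [], []
        for r in regions:
            cell = sub[sub["region"] == r]
            res = lateralization_test(cell["ai"].to_numpy(), region=r,
                                      metric=metric, alpha=alpha)
            lat.append(res)
            t, p, d = paired_homotopic_test(cell["L"].to_numpy(),
                                            cell["R"].to_numpy())
            pair.append((r, t, p, d))
        q, rej = bh_fdr([x.p for x in lat], alpha=alpha)
        for res, qq, rr in zip(lat, q, rej):
            direction = "none"
            if rr and res.mean_ai != 0:
                direction = "right" if res.mean_ai > 0 else "left"
            lat_rows.append(dict(region=res.region, metric=metric,
                                 mean_ai=res.mean_ai, t=res.t_stat, p=res.p,
                                 q=qq, cohens_d=res.cohens_d,
                                 direction=direction,
                                 degenerate=res.degenerate))
        q, rej = bh_fdr([x[2] for x in pair], alpha=alpha)
        for (r, t, p, d), qq, rr in zip(pair, q, rej):
            paired_rows.append(dict(region=r, metric=metric, t=t, p=p, q=qq,
                                    cohens_d=d, significant=bool(rr)))

    if not per_group:
        return {"lateralization": pd.DataFrame(lat_rows),
                "paired": pd.DataFrame(paired_rows),
                "by_group": pd.DataFrame(), "ai_change": pd.DataFrame(),
                "subject_ais": ais}

    # per-trimester AIs and their change
    subjects = subjects.copy()
    subjects["group"] = assign_trimester_group(subjects["ga_weeks"])
    measures_g = measures.merge(subjects[["subject_id", "group"]],
                                on="subject_id")
    adj_g = covariate_adjust(subjects, measures_g, seed=seed, metrics=metrics,
                             remove_ga=True, group_col="group")
    ais_g = _subject_ais(adj_g).merge(
        subjects[["subject_id", "group"]], on="subject_id")

    group_rows, change_rows = [], []
    for metric in metrics:
        sub = ais_g[ais_g["metric"] == metric]
        regions = sorted(sub["region"].unique())
        for gname in ("late2", "early3"):
            res_list = []
            for r in regions:
                cell = sub[(sub["region"] == r) & (sub["group"] == gname)]
                res_list.append(lateralization_test(
                    cell["ai"].to_numpy(), region=r, metric=metric,
                    group=gname, alpha=alpha))
            q, rej = bh_fdr([x.p for x in res_list], alpha=alpha)
            for res, qq in zip(res_list, q):
                group_rows.append(dict(region=res.region, metric=metric,
                                       group=gname, mean_ai=res.mean_ai,
                                       t=res.t_stat, p=res.p, q=qq,
                                       cohens_d=res.cohens_d))
        change = []
        for r in regions:
            a1 = sub[(sub["region"] == r) & (sub["group"] == "late2")]["ai"]
            a2 = sub[(sub["region"] == r) & (sub["group"] == "early3")]["ai"]
            delta, z, p = ai_change_ztest(a1.to_numpy(), a2.to_numpy())
            change.append((r, delta, z, p))
        q, rej = bh_fdr([x[3] for x in change], alpha=alpha)
        for (r, delta, z, p), qq, rr in zip(change, q, rej):
            change_rows.append(dict(region=r, metric=metric, delta_ai=delta,
                                    z=z, p=p, q=qq, significant=bool(rr)))
    return {
        "lateralization": pd.DataFrame(lat_rows),
        "paired": pd.DataFrame(paired_rows),
        "by_group": pd.DataFrame(group_rows),
        "ai_change": pd.DataFrame(change_rows),
        "subject_ais": ais,
    }


# --------------------------------------------------------------------------
# trajectories

def trajectory_analysis(subjects: pd.DataFrame, measures: pd.DataFrame,
                        seed: int = 42, metrics=ANALYSIS_METRICS,
                        k_candidates=tuple(range(2, 9)),
                        override_k: dict[str, int] | None = None) -> dict:
    """Fit regional growth models (GA kept, size covariates removed),
    sample dense growth profiles, Ward-cluster the rate curves per metric,
    and assess bilateral cluster symmetry."""
    override_k = override_k or {}
    adj = covariate_adjust(subjects, measures, seed=seed, metrics=metrics,
                           remove_ga=False)
    ga_by_subject = subjects.set_index("subject_id")["ga_weeks"]

    out = {}
    for metric in metrics:
        sub = adj[adj["metric"] == metric]
        profiles, keys = [], []
        for (r, h), cell in sub.groupby(["region", "hemisphere"], sort=True):
            ga = ga_by_subject.loc[cell["subject_id"]].to_numpy()
            model = fit_growth_model(ga, cell["adjusted"].to_numpy(), seed=seed)
            profiles.append(growth_profile(model, region=r, hemisphere=h,
                                           metric=metric))
            keys.append((r, h))
        rates = np.vstack([p.rate for p in profiles])
        sol = ward_cluster(rates, k_candidates=k_candidates,
                           override_k=override_k.get(metric))
        labels = pd.DataFrame(
            [dict(region=r, hemisphere=h, cluster=int(c))
             for (r, h), c in zip(keys, sol.labels)])
        out[metric] = dict(
            profiles=profiles,
            labels=labels,
            solution=sol,
            symmetry=bilateral_symmetry(labels),
        )
    return out


# --------------------------------------------------------------------------
# full run

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write CSV/JSON outputs plus a run log.

    Returns the in-memory report bundle (DataFrames and cluster solutions).
    Any stage failure raises with a stage tag; outputs of completed stages
    remain on disk.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "alpha": config.alpha,
                 "group_boundary": config.group_boundary,
                 "k_candidates": list(config.k_candidates),
                 "override_k": dict(config.override_k), "stages": []}

    def _stage(name, fn):
        t = time.time()
        try:
            result = fn()
        except Exception as err:  # annotate, keep partial outputs
            log["stages"].append({"name": name, "status": "failed",
                                  "error": str(err)})
            (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
            raise RuntimeError(f"stage '{name}' failed: {err}") from err
        log["stages"].append({"name": name, "status": "ok",
                              "seconds": round(time.time() - t, 3)})
        return result

    if config.cohort is not None:
        cohort: CohortResult = _stage(
            "simulate", lambda: generate_cohort(config.cohort))
        subjects, measures = cohort.subjects, cohort.measures
        log["cohort_seed"] = config.cohort.seed
        subjects.to_csv(outdir / "subjects.csv", index=False)
        measures.to_csv(outdir / "measures.csv", index=False)
    else:
        subjects = pd.read_csv(config.subjects_csv)
        measures = pd.read_csv(config.measures_csv)
        cohort = None

    anc = _stage("ancova", lambda: whole_brain_ancova(
        subjects, measures, seed=config.seed, metrics=config.metrics))
    for metric, res in anc.items():
        res.table.to_csv(outdir / f"ancova_whole_brain_{metric}.csv")

    pc_table, homo = _stage("trimester", lambda: trimester_analysis(
        subjects, measures, seed=config.seed, alpha=config.alpha,
        metrics=config.metrics))
    pc_table.to_csv(outdir / "percent_change.csv", index=False)
    homo.to_csv(outdir / "homotopic_growth.csv", index=False)

    asym = _stage("asymmetry", lambda: asymmetry_analysis(
        subjects, measures, seed=config.seed, alpha=config.alpha,
        metrics=config.metrics))
    for key in ("lateralization", "paired", "by_group", "ai_change"):
        asym[key].to_csv(outdir / f"asymmetry_{key}.csv", index=False)

    traj = _stage("trajectories", lambda: trajectory_analysis(
        subjects, measures, seed=config.seed, metrics=config.metrics,
        k_candidates=config.k_candidates, override_k=config.override_k))
    for metric, res in traj.items():
        res["labels"].to_csv(outdir / f"clusters_{metric}.csv", index=False)
        res["solution"].cluster_metrics.to_csv(
            outdir / f"cluster_metrics_{metric}.csv")
        res["symmetry"].to_csv(outdir / f"cluster_symmetry_{metric}.csv")
        with open(outdir / f"linkage_{metric}.json", "w") as fh:
            json.dump({"k": res["solution"].k,
                       "silhouette_by_k": res["solution"].silhouette_by_k,
                       "linkage": res["solution"].linkage_matrix.tolist()}, fh)

    log["total_seconds"] = round(time.time() - t0, 3)
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"cohort": cohort, "ancova": anc, "percent_change": pc_table,
            "homotopic": homo, "asymmetry": asym, "trajectories": traj,
            "log": log}
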