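"""End-to-end study orchestration.

Stage order: simulate -> average surfaces -> edge map + GVF -> FFD
registration -> closest-point correspondence -> vertex statistics ->
ROI statistics -> effect sizes -> correlations -> ROC.  Every stage's
outputs are written as CSV/JSON under the run directory and listed with a
checksum in the run manifest; identical configs give identical outputs.

Month-12 observations are generated but excluded from the default report
tables (only baseline and month 24 enter the cross-sectional and
longitudinal analyses).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (correspondence, discrimination, mesh_core, roi_stats,
               synthetic_data, template_registration, vertex_stats)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    # desk-scale resolutions preserve the 4:1 vertex-count ratio between
    # the two pipelines; the published ICO6/ICO7 pair is a flag away
    source_subdiv: int = 4
    target_subdiv: int = 5
    radius: float = 60.0
    n_average: int = 30          # subjects entering the average surfaces
    lattice_dims: int = 16
    grid_spacing: float = 3.0
    n_iterations: int = 15
    fdr_alpha: float = 0.01
    tukey_alpha_cross: float = 0.05
    tukey_alpha_long: float = 0.01
    gate_cross: float = 0.8
    gate_long: float = 0.6
    roc_folds: int = 5
    null_effects: bool = False   # zero all injected effects (null harness)
    out_dir: str = "corticompare_run"

    def __post_init__(self):
        for a in (self.fdr_alpha, self.tukey_alpha_cross, self.tukey_alpha_long):
            if not (0 < a < 1):
                raise ValueError("alphas must lie in (0, 1)")
        if self.gate_cross <= 0 or self.gate_long <= 0:
            raise ValueError("effect-size gates must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    config: dict
    config_hash: str
    outputs: dict = dataclasses.field(default_factory=dict)  # name -> checksum
    stages: list = dataclasses.field(default_factory=list)   # (stage, status, secs)
    error: str | None = None

    def record(self, out_dir: Path, name: str) -> None:
        path = out_dir / name
        self.outputs[name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]

    def save(self, out_dir: Path) -> None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _write_csv(df: pd.DataFrame, out_dir: Path, name: str,
               manifest: RunManifest) -> None:
    df.to_csv(out_dir / name, index=False, float_format="%.6g")
    manifest.record(out_dir, name)


def run_full_study(config: RunConfig) -> RunManifest:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(dataclasses.asdict(config), config.config_hash())
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("register", _stage_register),
        ("correspond", _stage_correspond),
        ("vertex_stats", _stage_vertex_stats),
        ("roi_stats", _stage_roi_stats),
        ("effect_sizes", _stage_effect_sizes),
        ("correlations", _stage_correlations),
        ("roc", _stage_roc),
    ]
    for name, fn in stages:
        t0 = time.time()
        try:
            fn(config, state, out_dir, manifest)
        except Exception as exc:   # fail the stage, skip the rest
            log.exception("stage %s failed", name)
            manifest.stages.append((name, "failed", round(time.time() - t0, 2)))
            manifest.error = f"{name}: {exc}"
            break
        manifest.stages.append((name, "ok", round(time.time() - t0, 2)))
    manifest.save(out_dir)
    return manifest


def _stage_simulate(cfg, state, out_dir, manifest):
    design = synthetic_data.CohortDesign(seed=cfg.seed)
    effect_cfg = (synthetic_data.null_effect_config() if cfg.null_effects
                  else None)
    cohort = synthetic_data.make_cohort(design, effect_cfg)
    registry = roi_stats.load_roi_registry()
    src_tmpl = mesh_core.build_cortex_template(cfg.source_subdiv, cfg.radius)
    tgt_tmpl = mesh_core.build_cortex_template(cfg.target_subdiv, cfg.radius)
    src_atlas = roi_stats.build_synthetic_atlas(src_tmpl, registry, seed=cfg.seed)
    tgt_atlas = roi_stats.build_synthetic_atlas(tgt_tmpl, registry, seed=cfg.seed)
    # 10 CTR + 10 sMCI + 10 AD subjects build the average surfaces
    avg_subjects = tuple(
        s for g, k in (("CTR", 10), ("sMCI", 10), ("AD", 10))
        for s in cohort.subjects[cohort.subjects.group == g]["subject"][:k])
    cv = synthetic_data.render_pipeline_observation(
        cohort, dataclasses.replace(
            synthetic_data.CIVET_PROFILE, resolution_subdiv=cfg.source_subdiv),
        src_atlas, src_tmpl, mesh_subjects=avg_subjects)
    fs = synthetic_data.render_pipeline_observation(
        cohort, dataclasses.replace(
            synthetic_data.FREESURFER_PROFILE,
            resolution_subdiv=cfg.target_subdiv),
        tgt_atlas, tgt_tmpl, mesh_subjects=avg_subjects)
    state.update(cohort=cohort, cv=cv, fs=fs, registry=registry,
                 avg_subjects=avg_subjects)
    _write_csv(cohort.subjects, out_dir, "subjects.csv", manifest)
    _write_csv(cohort.thickness, out_dir, "truth_thickness.csv", manifest)


def _stage_register(cfg, state, out_dir, manifest):
    cv, fs = state["cv"], state["fs"]
    avg = state["avg_subjects"]
    src_avg = template_registration.average_surface(
        [cv.meshes[(s, "BSL")] for s in avg])
    tgt_avg = template_registration.average_surface(
        [fs.meshes[(s, "BSL")] for s in avg])
    edge = template_registration.voxelize_and_edge_map(
        tgt_avg, spacing=cfg.grid_spacing)
    rcfg = template_registration.RegistrationConfig(
        n_iterations=cfg.n_iterations)
    gvf = template_registration.compute_gvf(edge, rcfg)
    lattice = template_registration.make_lattice(
        src_avg.vertices.min(0) - 5, src_avg.vertices.max(0) + 5,
        dims=(cfg.lattice_dims,) * 3)
    # directed source->target distance: the quantity registration drives
    # down (the symmetric variant is floored by the resolution mismatch
    # between the two tessellations of the same cortex)
    pre = float(np.mean(
        mesh_core.surface_distance(src_avg, tgt_avg).per_vertex_distances))
    hybrid, lattice = template_registration.ffd_register(
        src_avg, gvf, lattice, rcfg, edge=edge)
    post = float(np.mean(
        mesh_core.surface_distance(hybrid, tgt_avg).per_vertex_distances))
    state.update(hybrid=hybrid, tgt_avg=tgt_avg, lattice=lattice,
                 pre_distance=pre, post_distance=post)
    with open(out_dir / "registration.json", "w") as fh:
        json.dump({"pre_mean_distance_mm": pre, "post_mean_distance_mm": post,
                   "gvf_sweeps": int(gvf.iterations),
                   "hybrid_vertices": hybrid.n_vertices}, fh, indent=2)
    manifest.record(out_dir, "registration.json")


def _stage_correspond(cfg, state, out_dir, manifest):
    hybrid, tgt = state["hybrid"], state["tgt_avg"]
    corr = correspondence.closest_point_search(hybrid.vertices, tgt.vertices)
    groups = state["cohort"].group_of()
    records = correspondence.build_hybrid_dataset(
        state["cv"].maps, state["fs"].maps, corr, groups)
    state.update(corr=corr, records=records)
    df = pd.DataFrame({"source_index": np.arange(len(corr.match_index)),
                       "target_index": corr.match_index,
                       "distance_mm": corr.match_distance})
    _write_csv(df, out_dir, "correspondence.csv", manifest)


def _stage_vertex_stats(cfg, state, out_dir, manifest):
    records = state["records"]
    by = {}
    for r in records:
        by.setdefault((r.group, r.timepoint), []).append(r)
    summary = {}
    for pipe in ("cv", "fs"):
        get = (lambda r: r.thickness_cv) if pipe == "cv" else \
            (lambda r: r.thickness_fs)
        masks, deltas = {}, {}
        for grp in ("sMCI", "pMCI", "AD"):
            sm = vertex_stats.group_diff_map(
                [get(r) for r in by[("CTR", "BSL")]],
                [get(r) for r in by[(grp, "BSL")]],
                contrast=f"CTR_vs_{grp}")
            mask, _ = vertex_stats.fdr_correct(sm.p, alpha=cfg.fdr_alpha)
            masks[grp], deltas[grp] = mask, sm.delta
            summary[f"{pipe}_cross_{grp}_sig_vertices"] = int(mask.sum())
        for grp in ("CTR", "sMCI", "pMCI", "AD"):
            base = sorted(by[(grp, "BSL")], key=lambda r: r.subject)
            m24 = sorted(by[(grp, "M24")], key=lambda r: r.subject)
            sm = vertex_stats.paired_t_map([get(r) for r in base],
                                           [get(r) for r in m24],
                                           contrast=f"{grp}_BSL_vs_M24")
            mask, _ = vertex_stats.fdr_correct(sm.p, alpha=cfg.fdr_alpha)
            summary[f"{pipe}_long_{grp}_sig_vertices"] = int(mask.sum())
        state[f"masks_{pipe}"] = masks
        state[f"deltas_{pipe}"] = deltas
    for grp in ("sMCI", "pMCI", "AD"):
        de = vertex_stats.disease_effect_map(state["deltas_fs"][grp],
                                             state["deltas_cv"][grp],
                                             contrast=f"CTR_vs_{grp}")
        ov = vertex_stats.overlap_map(state["masks_cv"][grp],
                                      state["masks_fs"][grp])
        summary[f"disease_effect_mean_{grp}"] = float(de.values.mean())
        for k, v in ov.counts().items():
            summary[f"overlap_{grp}_{k}"] = v
    with open(out_dir / "vertex_stats.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest.record(out_dir, "vertex_stats.json")
    state["vertex_summary"] = summary


def _stage_roi_stats(cfg, state, out_dir, manifest):
    cohort = state["cohort"]
    groups = cohort.group_of()
    maps = {}
    for pipe, obs in (("CV", state["cv"]), ("FS", state["fs"])):
        for (subject, tp), smap in obs.maps.items():
            maps[(subject, pipe, tp)] = smap
    tables = []
    for pipe, obs in (("CV", state["cv"]), ("FS", state["fs"])):
        sub = {k: v for k, v in maps.items() if k[1] == pipe}
        t = roi_stats.roi_aggregate(
            {(s, p, tp): m for (s, p, tp), m in sub.items()},
            obs.atlas, groups)
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    # roi_aggregate keys are (subject, pipeline, timepoint); fix column name
    state["roi_table"] = table
    _write_csv(table, out_dir, "roi_table.csv", manifest)

    # longitudinal change per subject for Tukey at alpha_long
    rows = []
    for pipe in ("CV", "FS"):
        sub = table[table.pipeline == pipe]
        wide = sub.pivot_table(index=["subject", "group", "roi_id"],
                               columns="timepoint", values="thickness")
        chg = (wide["M24"] - wide["BSL"]).rename("change").reset_index()
        chg["pipeline"] = pipe
        rows.append(chg)
    change = pd.concat(rows, ignore_index=True)
    state["roi_change"] = change
    flag_rows = []
    for pipe in ("CV", "FS"):
        res = roi_stats.anova_tukey(
            change[change.pipeline == pipe].rename(columns={"change": "thickness"}),
            alpha=cfg.tukey_alpha_long)
        for roi, tr in res.items():
            flags = {f"{a}_vs_{b}": bool(s)
                     for (a, b), s in zip(tr.pairs, tr.significant)}
            flag_rows.append({"pipeline": pipe, "roi_id": roi,
                              "anova_p": tr.omnibus_p, **flags})
    _write_csv(pd.DataFrame(flag_rows), out_dir, "tukey_longitudinal.csv",
               manifest)
    state["tukey_long"] = pd.DataFrame(flag_rows)


def _stage_effect_sizes(cfg, state, out_dir, manifest):
    table = state["roi_table"]
    rows = []
    gmaps = {}
    for pipe in ("CV", "FS"):
        bsl = table[(table.pipeline == pipe) & (table.timepoint == "BSL")]
        for contrast in (("CTR", "pMCI"), ("CTR", "AD")):
            gdict = {}
            for roi, df in bsl.groupby("roi_id"):
                x1 = df[df.group == contrast[0]]["thickness"]
                x2 = df[df.group == contrast[1]]["thickness"]
                es = roi_stats.hedges_g_from_samples(x1, x2)
                gdict[int(roi)] = es.g
                rows.append({"pipeline": pipe, "mode": "cross",
                             "contrast": f"{contrast[0]}_vs_{contrast[1]}",
                             "roi_id": int(roi), "g": es.g, "se_g": es.se_g})
            gmaps[(pipe, "cross", contrast[1])] = gdict
        chg = state["roi_change"][state["roi_change"].pipeline == pipe]
        for grp in ("CTR", "pMCI", "AD"):
            gdict = {}
            for roi, df in chg.groupby("roi_id"):
                x = df[df.group == grp]["change"].to_numpy()
                # longitudinal effect: standardized mean change
                g = float(x.mean() / x.std(ddof=1)) if x.std(ddof=1) > 0 else 0.0
                gdict[int(roi)] = g
                rows.append({"pipeline": pipe, "mode": "long",
                             "contrast": f"{grp}_BSL_vs_M24",
                             "roi_id": int(roi), "g": g, "se_g": np.nan})
            gmaps[(pipe, "long", grp)] = gdict
    es_df = pd.DataFrame(rows)
    state["effect_sizes"] = es_df
    state["gmaps"] = gmaps
    _write_csv(es_df, out_dir, "effect_sizes.csv", manifest)


def _stage_correlations(cfg, state, out_dir, manifest):
    table = state["roi_table"]
    cohort = state["cohort"]
    cov = cohort.subjects.set_index("subject")[
        ["mmse_bsl", "hippocampal_volume"]]
    rows = []
    for pipe in ("CV", "FS"):
        for grp in ("CTR", "pMCI"):
            sub = table[(table.pipeline == pipe) & (table.timepoint == "BSL")
                        & (table.group == grp)]
            for covariate in ("mmse_bsl", "hippocampal_volume"):
                for res in roi_stats.pearson_by_roi(sub, cov, covariate):
                    rows.append({"pipeline": pipe, "group": grp,
                                 "covariate": covariate, "roi_id": res.roi_id,
                                 "r": res.r, "n": res.n})
    corr_df = pd.DataFrame(rows)
    # Steiger comparison between pipelines per ROI/covariate/group
    srows = []
    wide_cv = _scores_by_roi(table, "CV")
    wide_fs = _scores_by_roi(table, "FS")
    for (grp, covariate, roi), df in corr_df.groupby(
            ["group", "covariate", "roi_id"]):
        r = {p: df[df.pipeline == p]["r"].iloc[0] for p in ("CV", "FS")}
        subj = state["cohort"].subjects
        sel = subj[subj.group == grp]["subject"]
        a = wide_cv.loc[sel, roi]
        b = wide_fs.loc[sel, roi]
        r12 = float(np.corrcoef(a, b)[0, 1])
        n = len(sel)
        try:
            z, p = roi_stats.steiger_z(r["CV"], r["FS"], r12, n)
        except ValueError:
            z, p = np.nan, np.nan
        srows.append({"group": grp, "covariate": covariate, "roi_id": roi,
                      "r_cv": r["CV"], "r_fs": r["FS"], "r12": r12,
                      "z": z, "p": p})
    _write_csv(corr_df, out_dir, "correlations.csv", manifest)
    _write_csv(pd.DataFrame(srows), out_dir, "steiger.csv", manifest)
    state["correlations"] = corr_df


def _scores_by_roi(table, pipe):
    sub = table[(table.pipeline == pipe) & (table.timepoint == "BSL")]
    return sub.pivot_table(index="subject", columns="roi_id",
                           values="thickness")


def _stage_roc(cfg, state, out_dir, manifest):
    table = state["roi_table"]
    results = {}
    for contrast in (("CTR", "pMCI"), ("CTR", "AD")):
        per_pipe = {}
        for pipe in ("CV", "FS"):
            bsl = table[(table.pipeline == pipe) & (table.timepoint == "BSL")
                        & (table.group.isin(contrast))]
            labels = (bsl.groupby("subject")["group"].first() == contrast[1]) \
                .astype(int)
            g = state["gmaps"][(pipe, "cross", contrast[1])]
            cands = discrimination.gate_candidates(g, cfg.gate_cross)
            if not cands:
                cands = sorted(g, key=lambda r: -abs(g[r]))[:3]
            sel = discrimination.forward_select(bsl, labels, cands,
                                                n_folds=cfg.roc_folds,
                                                seed=cfg.seed)
            scores, cv_scores = discrimination.fit_logistic_score(
                bsl, labels, sel, return_cv=True, n_folds=cfg.roc_folds,
                seed=cfg.seed)
            roc = discrimination.roc_auc(scores, labels.to_numpy())
            roc.selected_rois = sel
            cv_auc = discrimination.roc_auc(cv_scores, labels.to_numpy()).auc
            per_pipe[pipe] = roc
            results[f"{pipe}_{contrast[0]}_vs_{contrast[1]}"] = {
                "auc_insample": roc.auc, "auc_cv": cv_auc,
                "se": roc.se_auc, "ci95": list(roc.ci95),
                "selected_rois": [int(r) for r in sel]}
        comp = discrimination.compare_auc(per_pipe["CV"], per_pipe["FS"])
        results[f"compare_{contrast[0]}_vs_{contrast[1]}"] = {
            "auc_cv_pipeline": comp.auc1, "auc_fs_pipeline": comp.auc2,
            "r": comp.r, "z": comp.z, "p": comp.p}
    with open(out_dir / "roc.json", "w") as fh:
        json.dump(results, fh, indent=2)
    manifest.record(out_dir, "roc.json")
    state["roc"] = results


SECTION_FILES = [
    ("ROI thickness table", "roi_table.csv"),
    ("Longitudinal Tukey-Kramer flags", "tukey_longitudinal.csv"),
    ("Effect sizes", "effect_sizes.csv"),
    ("Correlations", "correlations.csv"),
    ("ROC / AUC", "roc.json"),
]


def report(manifest: RunManifest, out_dir=None) -> str:
    """Markdown run report regenerated from the manifest's outputs only."""
    out_dir = Path(out_dir or manifest.config.get("out_dir", "."))
    lines = [f"# corticompare run report",
             f"", f"config hash: `{manifest.config_hash}`", ""]
    lines.append("## Stages")
    for name, status, secs in manifest.stages:
        lines.append(f"- {name}: {status} ({secs}s)")
    if manifest.error:
        lines.append(f"\n**Run incomplete**: {manifest.error}\n")
    for title, fname in SECTION_FILES:
        lines.append(f"\n## {title}\n")
        if fname not in manifest.outputs:
            lines.append("_missing (stage did not complete)_")
            continue
        path = out_dir / fname
        if fname.endswith(".json"):
            lines.append("```json")
            lines.append(path.read_text().strip())
            lines.append("```")
        else:
            df = pd.read_csv(path)
            lines.append(f"{len(df)} records; columns: "
                         f"{', '.join(df.columns)}")
            lines.append("")
            lines.append(df.head(10).to_markdown(index=False))
    text = "\n".join(lines) + "\n"
    (out_dir / "report.md").write_text(text)
    return text
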