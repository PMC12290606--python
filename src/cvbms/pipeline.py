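"""End-to-end pipeline: simulate -> first level -> group BMS -> group stats.

Stages are thin orchestration over the library modules; every random
operation is seeded from the configuration, and the report records the
configuration hash so a run can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import bms, cohort, designs, evidence, stats

__all__ = ["PipelineConfig", "FWEConfig", "CohortConfig", "run_pipeline",
           "FAMILY_COMPARISONS", "WITHIN_FAMILY"]

log = logging.getLogger("cvbms")

#: fixed roster of family comparisons, ordered as the analysis progresses:
#: event duration, novelty, scene split, memory-vs-baseline, parametric vs
#: categorical, empirical vs theoretical
FAMILY_COMPARISONS = [
    ("GLMs_TD", "GLMs_PE"),
    ("GLMs_0", "GLMs_00"),
    ("GLMs_x1", "GLMs_x2"),
    ("GLMs_12", "GLM_TD_0x1"),
    ("GLMs_1", "GLMs_2"),
    ("GLMs_1e", "GLMs_1t"),
]

#: within-family winner analyses (all members compete)
WITHIN_FAMILY = {
    "GLMs_2": ["GLM_2nf", "GLM_2nr", "GLM_2ns"],
    "GLMs_1t": ["GLM_1t-l", "GLM_1t-a", "GLM_1t-s"],
    "GLMs_1e": ["GLM_1e-cp", "GLM_1e-ip", "GLM_1e-lr"],
}


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    group_sizes: dict[str, int]
    grid_shape: tuple[int, int, int] = (12, 12, 4)
    n_scans: int = 206
    tr: float = 2.58
    n_novel: int = 88
    n_master: int = 44
    sigma: float = 1.0
    ar1: float = 0.3


class FWEConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "permutation"
    n_permutations: int = 2000
    alpha: float = 0.05
    cluster_k: int = 10


class PipelineConfig(BaseModel):
    """Validated configuration of a full pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    data_dir: str | None = None
    cohort: CohortConfig | None = None
    models: list[str] | str = "all"
    folds: int = Field(default=2, ge=2)
    mask_threshold: float = 0.5
    drift: bool = True
    thresholds: list[float] = [0.0, 1.10, 3.0, 5.01]
    lf_method: str = "beta-mode"
    fwe: FWEConfig = FWEConfig()
    svm_subsamples: int = 200
    save_evidence_maps: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _save_map(arr, grid_shape, affine, path):
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32).reshape(grid_shape),
                          affine)
    nib.save(img, path)


def _side_evidence(emap: evidence.EvidenceMap, side: str, fams: dict) -> np.ndarray:
    """Evidence of one comparison side: model LME or family LFE."""
    if side in emap.values:
        return np.asarray(emap.values[side], dtype=float)
    if side in fams:
        return emap.family_evidence(fams[side])
    raise KeyError(f"unknown model or family {side!r}")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and write a versioned report bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"config": config.model_dump(), "config_hash": config.hash()}
    try:
        return _run(config, out, report)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path, report: dict) -> dict:
    # ---- stage 0: data -----------------------------------------------------
    if config.cohort is not None:
        data_dir = Path(config.data_dir) if config.data_dir else out / "data"
        spec = cohort.CohortSpec(
            group_sizes=config.cohort.group_sizes,
            grid_shape=config.cohort.grid_shape,
            n_scans=config.cohort.n_scans, tr=config.cohort.tr,
            n_novel=config.cohort.n_novel, n_master=config.cohort.n_master,
            noise={"sigma": config.cohort.sigma, "ar1": config.cohort.ar1},
            seed=config.seed)
        log.info("simulating cohort with %d subjects into %s",
                 len(spec.subjects), data_dir)
        cohort.simulate_cohort(spec, data_dir)
    elif config.data_dir is None:
        raise ValueError("config needs either a cohort section or a data_dir")
    else:
        data_dir = Path(config.data_dir)
    ds = cohort.load_cohort(data_dir)
    participants = ds["participants"]
    subjects = list(participants["id"])
    tr = config.cohort.tr if config.cohort else json.loads(
        (data_dir / "cohort.json").read_text())["tr"] \
        if (data_dir / "cohort.json").exists() else 2.58

    # ---- stage 1: first-level evidence ------------------------------------
    space = designs.model_space()
    names = list(space) if config.models == "all" else list(config.models)
    loaded = {s: cohort.load_subject(ds["subject_dirs"][s]) for s in subjects}
    mask = evidence.intersection_mask([d["bold"] for d in loaded.values()],
                                      threshold=config.mask_threshold)
    emaps = {}
    ev_dir = out / "evidence"
    ev_dir.mkdir(exist_ok=True)
    grid_shape = affine = None
    for s in subjects:
        sub = dict(loaded[s], tr=tr)
        emaps[s] = evidence.run_first_level(sub, names, n_folds=config.folds,
                                            mask=mask, drift=config.drift,
                                            seed=config.seed)
        grid_shape, affine = emaps[s].grid_shape, loaded[s]["affine"]
        if config.save_evidence_maps:
            for m, vals in emaps[s].values.items():
                _save_map(vals, grid_shape, affine, ev_dir / f"{s}_{m}_cvLME.nii")
        log.info("first level done for %s (%d models)", s, len(names))
    _save_map(mask.astype(float), grid_shape, affine, out / "mask.nii")

    # ---- stage 2: group BMS -----------------------------------------------
    fams = designs.families()
    bms_dir = out / "bms"
    bms_dir.mkdir(exist_ok=True)
    midx = np.flatnonzero(mask)
    comparisons = {}

    def run_comparison(tag, candidates):
        lme = np.stack([np.stack([_side_evidence(emaps[s], c, fams)[midx]
                                  for c in candidates]) for s in subjects])
        keep = np.all(np.isfinite(lme), axis=(0, 1))
        if not keep.any():
            log.warning("comparison %s skipped: no voxels with complete "
                        "evidence", tag)
            comparisons[tag] = {"candidates": candidates, "skipped": True}
            return
        res = bms.GroupBMS(lme[:, :, keep], model_names=candidates).fit()
        smm = bms.selected_model_map(res, lf_method=config.lf_method)
        winner = np.full(mask.size, np.nan)
        lf = np.full(mask.size, np.nan)
        winner[midx[keep]] = smm.winner
        lf[midx[keep]] = smm.lf
        _save_map(winner, grid_shape, affine, bms_dir / f"{tag}_winner.nii")
        _save_map(lf, grid_shape, affine, bms_dir / f"{tag}_lf.nii")
        frac = {c: float(np.mean(smm.winner == i)) for i, c in enumerate(candidates)}
        sidecar = {"candidates": candidates, "alpha0": list(res.alpha0),
                   "n_iter": res.n_iter, "converged": res.converged,
                   "winner_fraction": frac,
                   "mean_lf": float(np.nanmean(smm.lf))}
        (bms_dir / f"{tag}.json").write_text(json.dumps(sidecar, indent=1))
        comparisons[tag] = sidecar
        log.info("comparison %s: winner fractions %s", tag, frac)

    for a, b in FAMILY_COMPARISONS:
        run_comparison(f"{a}_vs_{b}", [a, b])
    for fam, members in WITHIN_FAMILY.items():
        run_comparison(f"{fam}_winner", members)
    report["comparisons"] = comparisons

    # ---- stage 3: LBF maps, voxel counts, group statistics ----------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    lbf_maps = {}
    for s in subjects:
        nov = evidence.log_bayes_factor(
            _side_evidence(emaps[s], "GLMs_0", fams)[midx],
            _side_evidence(emaps[s], "GLMs_00", fams)[midx])
        mem = evidence.log_bayes_factor(
            _side_evidence(emaps[s], "GLMs_12", fams)[midx],
            np.asarray(emaps[s].values[designs.BASELINE_MODEL])[midx])
        lbf_maps[s] = {"novelty": nov, "memory": mem}
    counts = stats.voxel_count_table(lbf_maps, config.thresholds)
    counts.to_csv(stats_dir / "voxel_counts.tsv", sep="\t", index=False)

    group_stats: dict = {}
    groups = participants.groupby("group").size()
    eligible = groups[groups >= 2].index.tolist()
    wide = counts.pivot_table(index="subject", columns=["contrast", "lbf_threshold"],
                              values="count")
    main_thr = 3.0 if 3.0 in config.thresholds else config.thresholds[-1]
    if len(eligible) >= 2:
        merged = counts.merge(participants, left_on="subject", right_on="id")
        for contrast in ("novelty", "memory"):
            sel = merged[(merged["contrast"] == contrast)
                         & (merged["lbf_threshold"] == main_thr)
                         & merged["group"].isin(eligible)].copy()
            covs = [c for c in ("site", "gender", "age", "education_years",
                                "employment_years")
                    if sel[c].nunique() > 1]
            try:
                F, dfs, p = stats.ancova_group_effect(sel, "count", covariates=covs)
                group_stats[f"ancova_{contrast}"] = {"F": F, "df": dfs, "p": p}
            except ValueError as e:
                log.warning("ANCOVA skipped for %s: %s", contrast, e)
            if "HC" in eligible:
                hc = sel.loc[sel["group"] == "HC", "count"].to_numpy()
                for g in eligible:
                    if g == "HC":
                        continue
                    other = sel.loc[sel["group"] == g, "count"].to_numpy()
                    t, df, p = stats.two_sample_t_from_summaries(
                        len(hc), hc.mean(), hc.std(ddof=1),
                        len(other), other.mean(), other.std(ddof=1))
                    bfres = stats.jzs_ttest(hc, other)
                    group_stats[f"{contrast}_{g}_vs_HC"] = {
                        "t": t, "df": df, "p": p,
                        "bf01": bfres.bf01, "delta_med": bfres.delta_med}
        if "HC" in eligible:
            feats = wide.reindex(participants["id"]).to_numpy()
            for g in eligible:
                if g == "HC":
                    continue
                sel_idx = participants["group"].isin(["HC", g]).to_numpy()
                labels = participants.loc[sel_idx, "group"].to_numpy()
                n_min = min((labels == "HC").sum(), (labels == g).sum())
                k = min(10, n_min)
                if k < 2:
                    log.warning("SVM skipped for %s vs HC: too few subjects", g)
                    continue
                res = stats.svm_classify(feats[sel_idx], labels, k_folds=k,
                                         n_subsamples=config.svm_subsamples,
                                         seed=config.seed)
                group_stats[f"svm_{g}_vs_HC"] = {
                    "balanced_accuracy": res.balanced_accuracy, "ci90": res.ci90}
    else:
        log.info("group-difference stages skipped: fewer than two groups "
                 "with at least two subjects")
        group_stats["skipped"] = "fewer than two eligible groups"

    # ---- stage 4: second-level contrast tests per group --------------------
    second = {}
    winning = space["GLM_1t-a"]
    for g in eligible:
        members = participants.loc[participants["group"] == g, "id"]
        if len(members) < 2:
            continue
        con_nov, con_mem = [], []
        for s in members:
            sub = loaded[s]
            try:
                dm = designs.build_design(sub["events"], sub["motion"], winning,
                                          sub["bold"].shape[-1], tr,
                                          retrieval=sub["retrieval"],
                                          drift=config.drift, seed=config.seed)
            except designs.EstimabilityError:
                continue
            Y = sub["bold"].reshape(-1, sub["bold"].shape[-1]).T[:, midx]
            fit = evidence.BayesianGLM(Y, dm).fit()
            labels = list(dm.column_labels)
            beta = fit.params
            con_nov.append(beta[labels.index("novelty")]
                           - beta[labels.index("master")])
            con_mem.append(beta[labels.index("novelty_x_1t-a")])
        if len(con_nov) < 2:
            continue
        for cname, maps_ in (("novelty", np.array(con_nov)),
                             ("memory", np.array(con_mem))):
            res = stats.second_level_ftest(
                maps_, grid_shape=None, alpha=config.fwe.alpha,
                cluster_k=config.fwe.cluster_k, method=config.fwe.method,
                n_permutations=config.fwe.n_permutations, seed=config.seed)
            fmap = np.full(mask.size, np.nan)
            fmap[midx] = res.f
            _save_map(fmap, grid_shape, affine,
                      stats_dir / f"{g}_{cname}_F.nii")
            second[f"{g}_{cname}"] = {
                "n_significant": int(res.significant.sum()),
                "n_subjects": len(maps_)}
    report["group_stats"] = group_stats
    report["second_level"] = second
    report["n_subjects"] = len(subjects)
    report["mask_voxels"] = int(mask.sum())
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    log.info("pipeline complete; report at %s", out / "report.json")
    return report
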