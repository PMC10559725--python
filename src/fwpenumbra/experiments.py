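"""Cohort-level parameter-recovery experiments.

Each runner simulates a cohort under the configured study conditions,
pushes it through the corresponding analysis stages, and returns the
recovered quantities next to the generator's configured truth.  These
are the entry points used by the acceptance script and the recovery
tests.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import CohortConfig, ClusterConfig, brain_scale_config
from .freewater import FreeWaterModel
from .phantom import simulate_subject
from .progression import map_progression
from .rois import build_penumbra, classify_penumbra, annualized_growth
from .scheme import default_scheme
from .voxelstats import roi_longitudinal, roi_means_long_table, subject_design, assemble_design

ROI_ORDER = ("wmh", "progressing", "stable", "nawm")


def _subject_stage(subject, cluster_config: Optional[ClusterConfig] = None):
    """Penumbra, progression map and ROI partition for one subject."""
    t = subject.truth
    times = np.asarray(t.timepoints)
    seg = subject.seg_wmh_masks()
    flair = [subject.flair(x) for x in times]
    wm = t.wm_mask
    pen = build_penumbra(seg, seg[0], wm, t.exclusion_mask, t.voxel_size, 3.0)
    nawm = wm & ~seg[-1] & ~pen & ~t.exclusion_mask
    pm = map_progression(flair, times, t.gm_mask, nawm, wm,
                         cluster_config=cluster_config, voxel_size=t.voxel_size)
    part = classify_penumbra(pen, seg, pm.clusters.significant_increase_mask,
                             wm_mask=wm, exclusion_mask=t.exclusion_mask,
                             baseline_wmh=seg[0], voxel_size=t.voxel_size)
    return pen, nawm, pm, part


def _roi_masks(part):
    return {"wmh": part.baseline_wmh, "progressing": part.penumbra_progressing,
            "stable": part.penumbra_stable, "nawm": part.nawm}


def _covariate_terms(df: pd.DataFrame):
    """Subject-level covariate terms, greedily pruned so the
    subject-level design stays full rank (small cohorts can make
    site/sex/race patterns collinear by chance)."""
    subj = df.groupby("subject").first()
    kept = []
    design = [np.ones(len(subj))]
    for col, term in (("site", "C(site)"), ("age", "center(age)"), ("sex", "C(sex)"),
                      ("race", "C(race)"), ("baseline_wmh_ml", "center(baseline_wmh_ml)")):
        if col not in subj.columns or subj[col].nunique() < 2:
            continue
        if subj[col].dtype == object or subj[col].nunique() <= 4:
            cols = pd.get_dummies(subj[col], drop_first=True).to_numpy(float).T
        else:
            cols = [(subj[col] - subj[col].mean()).to_numpy(float)]
        cand = np.vstack([*design, *cols])
        if np.linalg.matrix_rank(cand, tol=1e-8) == cand.shape[0] and cand.shape[0] < len(subj):
            design = list(cand)
            kept.append(term)
    return kept


def run_fw_recovery(config: Optional[CohortConfig] = None, n_subjects: int = 8):
    """Baseline DWI fits: cohort-average fitted FW / FA_Tissue /
    MD_Tissue per analysis ROI, against the configured class means."""
    cfg = config or CohortConfig()
    scheme = default_scheme()
    sums = {m: {r: [] for r in ROI_ORDER} for m in ("fw", "fa_tissue", "md_tissue")}
    for sub in range(n_subjects):
        s = simulate_subject(cfg, sub)
        t = s.truth
        _, _, _, part = _subject_stage(s)
        dwi = s.dwi(0.0, scheme)
        res = FreeWaterModel(dwi, scheme, mask=t.wm_mask).fit(
            mode="anchored", csf_mask=t.tissue_labels == 1, voxel_size=t.voxel_size)
        for roi, mask in _roi_masks(part).items():
            if mask.sum() == 0:
                continue
            sums["fw"][roi].append(res.roi_mean(mask, "f"))
            sums["fa_tissue"][roi].append(res.roi_mean(mask, "fa_tissue"))
            sums["md_tissue"][roi].append(res.roi_mean(mask, "md_tissue"))
    out = {m: {r: float(np.mean(v)) for r, v in rois.items() if v}
           for m, rois in sums.items()}
    out["configured"] = {
        "fw": dict(zip(ROI_ORDER, cfg.roi_fw_means)),
        "fa_tissue": dict(zip(ROI_ORDER, cfg.roi_fa_means)),
        "md_tissue": dict(zip(ROI_ORDER, cfg.roi_md_means)),
    }
    return out


def run_flair_longitudinal(config: Optional[CohortConfig] = None):
    """Normalized-FLAIR ROI means per timepoint -> random-intercept
    model with ROI-by-time interaction.  Returns baseline ROI means, the
    progressing-ROI annual slope and its contrast vs NAWM."""
    cfg = config or CohortConfig()
    rows = []
    baseline_means = {r: [] for r in ROI_ORDER}
    for sub in range(cfg.n_subjects):
        s = simulate_subject(cfg, sub)
        t = s.truth
        _, _, pm, part = _subject_stage(s)
        masks = _roi_masks(part)
        entry = {"subject": sub, "times": t.timepoints, "volumes": pm.normalized,
                 "roi_masks": masks,
                 **{k: t.covariates.get(k) for k in ("age", "sex", "race", "site",
                                                     "baseline_wmh_ml")}}
        rows.append(entry)
        for r, m in masks.items():
            if m.sum():
                baseline_means[r].append(float(np.nanmean(pm.normalized[0][m])))
    long = roi_means_long_table(rows)
    fit = roi_longitudinal(long, covariates=_covariate_terms(long))
    return {
        "baseline_means": {r: float(np.mean(v)) for r, v in baseline_means.items() if v},
        "slope_progressing": float(fit.slopes.get("progressing", np.nan)),
        "contrast_progressing_vs_nawm": float(fit.contrasts.get("progressing", np.nan)),
        "slopes": {k: float(v) for k, v in fit.slopes.items()},
        "configured": {"baseline_means": dict(zip(ROI_ORDER, cfg.roi_flair_means)),
                       "slope_progressing": cfg.flair_slope_progressing},
    }


def run_fw_longitudinal(config: Optional[CohortConfig] = None):
    """Fit FW at every timepoint, model ROI means longitudinally, and
    report the progressing-vs-NAWM annual FW change contrast."""
    cfg = config or CohortConfig()
    scheme = default_scheme()
    rows = []
    for sub in range(cfg.n_subjects):
        s = simulate_subject(cfg, sub)
        t = s.truth
        _, _, _, part = _subject_stage(s)
        masks = _roi_masks(part)
        fw_vols = []
        for x in t.timepoints:
            res = FreeWaterModel(s.dwi(x, scheme), scheme, mask=t.wm_mask).fit(
                mode="anchored", csf_mask=t.tissue_labels == 1, voxel_size=t.voxel_size)
            fw_vols.append(res.f)
        rows.append({"subject": sub, "times": t.timepoints, "volumes": fw_vols,
                     "roi_masks": masks,
                     **{k: t.covariates.get(k) for k in ("age", "sex", "race", "site",
                                                         "baseline_wmh_ml")}})
    long = roi_means_long_table(rows)
    fit = roi_longitudinal(long, covariates=_covariate_terms(long))
    return {
        "contrast_progressing_vs_nawm": float(fit.contrasts.get("progressing", np.nan)),
        "slope_progressing": float(fit.slopes.get("progressing", np.nan)),
        "slopes": {k: float(v) for k, v in fit.slopes.items()},
        "configured": {"fw_slope_progressing": cfg.fw_slope_progressing},
    }


def run_growth_detection(config: Optional[CohortConfig] = None):
    """Full progression-mapping pipeline at brain-equivalent scale;
    median annualized detected WMH growth across subjects."""
    cfg = config or brain_scale_config()
    detected, true_vals = [], []
    for sub in range(cfg.n_subjects):
        s = simulate_subject(cfg, sub)
        t = s.truth
        _, _, _, part = _subject_stage(s)
        duration = t.timepoints[-1] - t.timepoints[0]
        g = annualized_growth(part, study_duration_years=duration,
                              ticv_voxels=t.ticv_voxels)
        detected.append(g["growth_ml_per_year"])
        true_vals.append(float(t.progression_mask.sum()) * cfg.voxel_volume_ml / duration)
    return {
        "median_detected_ml_per_year": float(np.median(detected)),
        "median_true_ml_per_year": float(np.median(true_vals)),
        "detected": detected,
        "true": true_vals,
        "configured": {"target_growth_ml": cfg.target_growth_ml},
    }


def run_prediction(config: Optional[CohortConfig] = None, n_boot: int = 200, seed: int = 0):
    """Pooled-voxel prediction: AUC per DTI predictor and clinical-only."""
    from .voxelstats import fit_logistic_clustered, roc_auc
    cfg = config or CohortConfig()
    scheme = default_scheme()
    tables = []
    for sub in range(cfg.n_subjects):
        s = simulate_subject(cfg, sub)
        t = s.truth
        _, _, _, part = _subject_stage(s)
        res = FreeWaterModel(s.dwi(0.0, scheme), scheme, mask=t.wm_mask).fit(
            mode="anchored", csf_mask=t.tissue_labels == 1, voxel_size=t.voxel_size)
        tables.append(subject_design(part, res, dict(t.covariates)))
    table = assemble_design(tables)
    rng = np.random.default_rng(seed)
    out = {"n_voxels": int(len(table))}
    from .voxelstats import liu_cutoff
    for pred in ("fw", "md_tissue", "fa_tissue", "clinical"):
        cols = [] if pred == "clinical" else [pred]
        fit = fit_logistic_clustered(table, cols)
        # ROC on the fitted model's probabilities (the classifier under
        # test is the logistic regression, not the raw metric)
        score = fit.predict(table)
        roc = roc_auc(score, table["outcome"].to_numpy(), table["subject"].to_numpy(),
                      n_boot=n_boot, rng=rng)
        out[pred] = {"auc": roc.auc, "auc_ci": list(roc.auc_ci),
                     "pseudo_r2": fit.pseudo_r2}
        if pred != "clinical":
            # the operating point is reported in raw metric units
            cut, sens, spec = liu_cutoff(table[pred].to_numpy(),
                                         table["outcome"].to_numpy())
            out[pred].update({"cutoff": cut, "cutoff_sens": sens,
                              "cutoff_spec": spec})
    return out
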