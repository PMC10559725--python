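"""Pooled-voxel prediction of WMH progression and ROI-level models.

Penumbra voxels from all subjects are pooled into one design table
(outcome: progressing vs stable) and analyzed with logistic regression
whose standard errors are clustered by subject, ROC/AUC with a
subject-level bootstrap CI, and the Liu optimal cutoff (maximizing
sensitivity x specificity).  ROI-level longitudinal change is estimated
with a random-intercept linear mixed model and a tissue-by-time
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ROI_LONG_NAMES = {1: "wmh", 2: "progressing", 3: "stable", 4: "nawm"}


# ---------------------------------------------------------------------------
# design assembly

def assemble_design(subject_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject penumbra-voxel tables into one design.

    Each table needs columns: outcome, fw, fa_tissue, md_tissue, subject,
    age, sex, race, site, baseline_wmh_ml.
    """
    if len(subject_tables) == 0:
        raise ValueError("no subject tables supplied")
    df = pd.concat(list(subject_tables), ignore_index=True)
    required = {"outcome", "fw", "fa_tissue", "md_tissue", "subject"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if not df["outcome"].isin([0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    return df


def subject_design(partition, fw_results_or_maps, covariates: dict) -> pd.DataFrame:
    """One row per penumbra voxel for a single subject.

    fw_results_or_maps: FreeWaterResults or dict with f/fa_tissue/
    md_tissue volumes (true fields can be passed for oracle analyses).
    """
    pen = partition.penumbra
    if hasattr(fw_results_or_maps, "f"):
        maps = {"fw": fw_results_or_maps.f,
                "fa_tissue": fw_results_or_maps.fa_tissue,
                "md_tissue": fw_results_or_maps.md_tissue}
    else:
        maps = fw_results_or_maps
    rows = {
        "outcome": partition.penumbra_progressing[pen].astype(int),
        "fw": np.asarray(maps["fw"])[pen],
        "fa_tissue": np.asarray(maps["fa_tissue"])[pen],
        "md_tissue": np.asarray(maps["md_tissue"])[pen],
    }
    df = pd.DataFrame(rows)
    for key in ("subject", "age", "sex", "race", "site", "baseline_wmh_ml"):
        df[key] = covariates.get(key)
    return df.dropna(subset=["fw", "fa_tissue", "md_tissue"])


# ---------------------------------------------------------------------------
# clustered logistic regression

@dataclass
class LogisticFit:
    """Cluster-robust logistic fit (statsmodels Results-backed)."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    llf: float
    llnull: float
    pseudo_r2: float      # McFadden: 1 - llf/llnull
    converged: bool
    separation_flag: bool
    n_obs: int
    n_clusters: int
    results: object = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.results.predict(X))

    def summary(self):
        return self.results.summary()


def _design_from_predictors(table: pd.DataFrame, predictors, covariates: bool,
                            include_site: bool):
    terms = list(predictors)
    if covariates:
        terms += ["age", "sex", "C(race)", "baseline_wmh_ml"]
        if include_site and "site" in table.columns:
            terms += ["C(site)"]
    formula = "outcome ~ " + " + ".join(terms) if terms else "outcome ~ 1"
    return formula


def fit_logistic_clustered(table: pd.DataFrame, predictors: Sequence[str],
                           covariates: bool = True, include_site: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression with subject-clustered
    sandwich standard errors and McFadden pseudo-R^2."""
    import statsmodels.formula.api as smf

    groups = table["subject"].to_numpy()
    if np.unique(groups).size < 2:
        raise ValueError("need at least two subject clusters")
    y = table["outcome"].to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    formula = _design_from_predictors(table, predictors, covariates, include_site)
    model = smf.logit(formula, data=table)
    with np.errstate(all="ignore"):
        res = model.fit(disp=False, maxiter=200,
                        cov_type="cluster", cov_kwds={"groups": groups})
    p = res.predict()
    separation = bool(np.any((p > 1 - 1e-10) & (y == 0)) or np.any((p < 1e-10) & (y == 1)))
    if separation:
        import warnings
        warnings.warn("possible complete separation; coefficients unreliable")
    return LogisticFit(
        params=res.params, bse=res.bse,
        cov=pd.DataFrame(res.cov_params(), index=res.params.index, columns=res.params.index),
        llf=float(res.llf), llnull=float(res.llnull),
        pseudo_r2=float(1.0 - res.llf / res.llnull),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=separation,
        n_obs=int(res.nobs), n_clusters=int(np.unique(groups).size),
        results=res,
    )


# ---------------------------------------------------------------------------
# ROC / AUC / Liu cutoff

@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple
    optimal_cutoff: float
    cutoff_sens: float
    cutoff_spec: float
    n_boot: int

    def summary(self) -> str:
        lo, hi = self.auc_ci
        return (f"AUC {self.auc:.3f} ({lo:.3f} - {hi:.3f}); "
                f"Liu cutoff {self.optimal_cutoff:.3f} "
                f"(sens {self.cutoff_sens:.2f}, spec {self.cutoff_spec:.2f})")


def _auc_mannwhitney(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """AUC via the Mann-Whitney identity (ties count 1/2), using ranks."""
    from scipy.stats import rankdata
    pos = outcomes == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _roc_curve(scores: np.ndarray, outcomes: np.ndarray):
    order = np.argsort(-scores, kind="mergesort")
    y = outcomes[order]
    s = scores[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # thresholds at each distinct score
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    sens = tps[distinct] / tps[-1]
    spec = 1.0 - fps[distinct] / fps[-1]
    thr = s[distinct]
    return thr, sens, spec


def roc_auc(scores, outcomes, subject_ids=None, n_boot: int = 1000,
            rng=None) -> RocResult:
    """ROC curve, Mann-Whitney AUC, subject-level bootstrap percentile
    CI, and the Liu cutoff."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, int)
    auc = _auc_mannwhitney(scores, outcomes)
    thr, sens, spec = _roc_curve(scores, outcomes)
    cutoff, c_sens, c_spec = liu_cutoff(scores, outcomes)

    ci = (np.nan, np.nan)
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(rng)
        if subject_ids is None:
            subject_ids = np.zeros(len(scores), int)
        subject_ids = np.asarray(subject_ids)
        uniq = np.unique(subject_ids)
        groups = {s: np.flatnonzero(subject_ids == s) for s in uniq}
        stats_ = []
        for _ in range(n_boot):
            pick = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([groups[s] for s in pick])
            if outcomes[idx].min() == outcomes[idx].max():
                continue
            stats_.append(_auc_mannwhitney(scores[idx], outcomes[idx]))
        if stats_:
            ci = tuple(np.percentile(stats_, [2.5, 97.5]))
    return RocResult(thresholds=thr, sensitivity=sens, specificity=spec,
                     auc=auc, auc_ci=ci, optimal_cutoff=cutoff,
                     cutoff_sens=c_sens, cutoff_spec=c_spec, n_boot=int(n_boot or 0))


def liu_cutoff(scores, outcomes):
    """Threshold maximizing sensitivity x specificity over candidate
    thresholds (midpoints of sorted unique scores); ties break toward
    the lower threshold.  Classification rule: positive if score >= t."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, int)
    pos = outcomes == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required")
    u = np.unique(scores)
    if u.size == 1:
        cands = np.array([u[0]])
    else:
        cands = (u[:-1] + u[1:]) / 2.0
    # vectorized sens/spec at each candidate
    pos_sorted = np.sort(scores[pos])
    neg_sorted = np.sort(scores[~pos])
    sens = 1.0 - np.searchsorted(pos_sorted, cands, side="left") / n1
    spec = np.searchsorted(neg_sorted, cands, side="left") / n0
    prod = sens * spec
    best = int(np.argmax(prod))  # argmax returns the first (lowest threshold) tie
    return float(cands[best]), float(sens[best]), float(spec[best])


# ---------------------------------------------------------------------------
# ROI-level longitudinal mixed model

@dataclass
class RoiLongitudinalFit:
    """Random-intercept model of an ROI measure over time.

    slopes[roi] is the estimated annual change within each ROI;
    contrasts[roi] the difference vs NAWM with Bonferroni-adjusted p.
    """

    slopes: dict
    slope_se: dict
    contrasts: dict
    contrast_se: dict
    contrast_p_bonferroni: dict
    results: object = field(repr=False, default=None)

    def summary(self):
        return self.results.summary()


def roi_longitudinal(long_table: pd.DataFrame, value_col: str = "value",
                     reference_roi: str = "nawm", covariates: Optional[list] = None,
                     method: str = "lbfgs") -> RoiLongitudinalFit:
    """Fit value ~ roi * time + covariates with random intercepts per
    subject; report per-ROI annual change and contrasts vs the reference.

    long_table columns: subject, roi, time, value, plus covariates.
    """
    import statsmodels.formula.api as smf

    df = long_table.copy()
    if df["subject"].nunique() < 2:
        raise ValueError("mixed model needs at least two subjects")
    rois = [r for r in df["roi"].unique()]
    if reference_roi not in rois:
        raise ValueError(f"reference ROI {reference_roi!r} absent")
    df["roi"] = pd.Categorical(df["roi"],
                               categories=[reference_roi] + [r for r in rois if r != reference_roi])
    terms = [f"C(roi) * time"]
    for c in covariates or []:
        terms.append(c)
    formula = f"{value_col} ~ " + " + ".join(terms)
    model = smf.mixedlm(formula, data=df, groups=df["subject"])
    res = None
    for meth in (method, "powell", "nm"):
        try:
            res = model.fit(reml=True, method=meth)
            break
        except np.linalg.LinAlgError:
            continue
    if res is None:
        raise np.linalg.LinAlgError("mixed model failed to converge with all optimizers")

    names = res.params.index
    base = float(res.params["time"])
    base_se = float(res.bse["time"])
    slopes, slope_se, contrasts, contrast_se, pvals = {}, {}, {}, {}, {}
    slopes[reference_roi] = base
    slope_se[reference_roi] = base_se
    others = [r for r in df["roi"].cat.categories if r != reference_roi]
    for r in others:
        key = next((n for n in names if n.startswith("C(roi)") and f"[T.{r}]:time" in n), None)
        if key is None:
            continue
        est = float(res.params[key])
        se = float(res.bse[key])
        cov_bt = float(res.cov_params().loc["time", key])
        slopes[r] = base + est
        slope_se[r] = float(np.sqrt(base_se ** 2 + se ** 2 + 2 * cov_bt))
        contrasts[r] = est
        contrast_se[r] = se
        from scipy import stats as sps
        p = 2.0 * sps.norm.sf(abs(est / se)) if se > 0 else np.nan
        pvals[r] = min(1.0, p * len(others))
    return RoiLongitudinalFit(slopes=slopes, slope_se=slope_se, contrasts=contrasts,
                              contrast_se=contrast_se, contrast_p_bonferroni=pvals,
                              results=res)


def roi_means_long_table(subjects_maps: Sequence[dict]) -> pd.DataFrame:
    """Build the long table of per-subject, per-ROI, per-timepoint means.

    Each element: {"subject", "times", "roi_masks": {name: mask},
    "volumes": [vol_t0, ...], optional covariates}.
    """
    rows = []
    for s in subjects_maps:
        for t, vol in zip(s["times"], s["volumes"]):
            for roi, m in s["roi_masks"].items():
                if m.sum() == 0:
                    continue
                rows.append({
                    "subject": s["subject"], "roi": roi, "time": float(t),
                    "value": float(np.nanmean(np.asarray(vol)[m])),
                    **{k: s[k] for k in ("age", "sex", "race", "site", "baseline_wmh_ml")
                       if k in s},
                })
    return pd.DataFrame(rows)
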