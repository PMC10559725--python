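import numpy as np
import pandas as pd
import pytest

from fwpenumbra.voxelstats import (assemble_design, fit_logistic_clustered,
                                   liu_cutoff, roc_auc, roi_longitudinal)


def make_table(rng, n_subjects=10, n_per=200, beta=2.0, icc=0.0):
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, icc)
        x = rng.normal(0, 1, n_per)
        p = 1 / (1 + np.exp(-(-0.5 + beta * x + u)))
        y = rng.random(n_per) < p
        rows.append(pd.DataFrame({
            "outcome": y.astype(int), "fw": x,
            "fa_tissue": rng.normal(size=n_per), "md_tissue": rng.normal(size=n_per),
            "subject": s, "age": 70 + s, "sex": s % 2, "race": "white",
            "site": s % 2, "baseline_wmh_ml": 10.0 + s,
        }))
    return assemble_design(rows)


# ---------------------------------------------------------------------------
# clustered logistic regression

def test_null_predictor_coefficient_near_zero():
    rng = np.random.default_rng(0)
    table = make_table(rng, beta=0.0)
    fit = fit_logistic_clustered(table, ["fw"], covariates=False)
    assert abs(fit.params["fw"]) < 3 * fit.bse["fw"]
    assert 0.0 <= fit.pseudo_r2 < 0.05


def test_singleton_clusters_equal_hc0():
    rng = np.random.default_rng(1)
    table = make_table(rng, n_subjects=1, n_per=300)
    table["subject"] = np.arange(len(table))  # each row its own cluster
    fit = fit_logistic_clustered(table, ["fw"], covariates=False)

    import statsmodels.api as sm
    X = sm.add_constant(table["fw"].to_numpy())
    res = sm.Logit(table["outcome"].to_numpy(), X).fit(disp=False, cov_type="HC0")
    # identical sandwich up to the finite-sample cluster correction
    # G/(G-1) * (N-1)/(N-K) with G = N singleton clusters
    n, k = len(table), 2
    corr = np.sqrt(n / (n - 1) * (n - 1) / (n - k))
    np.testing.assert_allclose(np.sort(fit.bse.to_numpy()),
                               np.sort(res.bse) * corr, rtol=1e-10)


def test_matches_newton_raphson_sandwich_oracle():
    """30-row toy fit vs an independently coded Newton-Raphson MLE with
    a by-hand cluster sandwich covariance."""
    rng = np.random.default_rng(2)
    n = 30
    x = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 1.2 * x)))).astype(int)
    groups = np.repeat([0, 1, 2], 10)
    table = pd.DataFrame({"outcome": y, "fw": x, "subject": groups})

    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    for _ in range(200):
        p = 1 / (1 + np.exp(-X @ beta))
        W = p * (1 - p)
        H = X.T @ (W[:, None] * X)
        gvec = X.T @ (y - p)
        step = np.linalg.solve(H, gvec)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-14:
            break
    p = 1 / (1 + np.exp(-X @ beta))
    bread = np.linalg.inv(X.T @ ((p * (1 - p))[:, None] * X))
    meat = np.zeros((2, 2))
    for g in np.unique(groups):
        sg = (X[groups == g] * (y - p)[groups == g, None]).sum(axis=0)
        meat += np.outer(sg, sg)
    n_g = len(np.unique(groups))
    corr = n_g / (n_g - 1) * (n - 1) / (n - 2)
    cov = corr * bread @ meat @ bread

    fit = fit_logistic_clustered(table, ["fw"], covariates=False)
    np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
    np.testing.assert_allclose(np.diag(fit.cov.to_numpy()), np.diag(cov), rtol=1e-6)


def test_clustered_se_exceeds_naive_under_correlation():
    import statsmodels.api as sm
    rng = np.random.default_rng(3)
    wins = 0
    for _ in range(20):
        table = make_table(rng, n_subjects=8, n_per=100, beta=0.5, icc=1.0)
        fit = fit_logistic_clustered(table, ["fw"], covariates=False)
        X = sm.add_constant(table["fw"].to_numpy())
        naive = sm.Logit(table["outcome"].to_numpy(), X).fit(disp=False)
        if fit.bse.iloc[0] >= naive.bse[0]:
            wins += 1
    assert wins >= 16  # intercept SE inflated by intra-cluster correlation


def test_errors_on_degenerate_inputs():
    rng = np.random.default_rng(4)
    table = make_table(rng, n_subjects=1)
    with pytest.raises(ValueError, match="clusters"):
        fit_logistic_clustered(table, ["fw"], covariates=False)
    table2 = make_table(rng, n_subjects=4)
    table2["outcome"] = 1
    with pytest.raises(ValueError, match="single class"):
        fit_logistic_clustered(table2, ["fw"], covariates=False)


# ---------------------------------------------------------------------------
# ROC / AUC / Liu

def test_auc_trivial_cases():
    y = np.r_[np.zeros(10), np.ones(10)].astype(int)
    perfect = np.r_[np.zeros(10), np.ones(10)]
    assert roc_auc(perfect, y, n_boot=0).auc == 1.0
    assert roc_auc(np.zeros(20), y, n_boot=0).auc == 0.5
    with pytest.raises(ValueError):
        roc_auc(perfect, np.ones(20, int), n_boot=0)


def test_auc_pair_enumeration_oracle():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=20)
    scores[5] = scores[15]  # force a tie
    y = (rng.random(20) < 0.4).astype(int)
    if y.sum() in (0, 20):
        y[:3] = [0, 1, 0]
    auc = roc_auc(scores, y, n_boot=0).auc
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


from hypothesis import given, settings, strategies as st


@given(st.lists(st.floats(-50, 50), min_size=6, max_size=40),
       st.integers(0, 2 ** 31 - 1), st.floats(0.1, 5.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_auc_invariant_under_monotone_transform(vals, label_seed, scale):
    # round to a grid so exp() stays strictly monotone in floating point
    scores = np.round(np.asarray(vals), 3)
    y = np.random.default_rng(label_seed).integers(0, 2, size=len(scores))
    if y.min() == y.max():
        y[0] = 1 - y[0]
    a1 = roc_auc(scores, y, n_boot=0).auc
    a2 = roc_auc(np.exp(scale * scores / 50.0) + 5, y, n_boot=0).auc
    assert a1 == pytest.approx(a2, abs=1e-12)
    assert 0.0 <= a1 <= 1.0


def test_bootstrap_ci_contains_point_estimate():
    rng = np.random.default_rng(7)
    table = make_table(rng, n_subjects=8, n_per=100, beta=1.0)
    roc = roc_auc(table["fw"].to_numpy(), table["outcome"].to_numpy(),
                  table["subject"].to_numpy(), n_boot=200, rng=1)
    lo, hi = roc.auc_ci
    assert lo <= roc.auc <= hi
    assert hi - lo < 0.2


def test_liu_cutoff_exhaustive_oracle():
    rng = np.random.default_rng(8)
    scores = np.round(rng.normal(size=10), 2)
    y = np.array([0, 0, 1, 0, 1, 1, 0, 1, 0, 1])
    cut, sens, spec = liu_cutoff(scores, y)
    best = (-1, None)
    u = np.unique(scores)
    for c in (u[:-1] + u[1:]) / 2:
        s = ((scores >= c) & (y == 1)).sum() / (y == 1).sum()
        sp = ((scores < c) & (y == 0)).sum() / (y == 0).sum()
        if s * sp > best[0] + 1e-12:
            best = (s * sp, c)
    assert cut == pytest.approx(best[1])
    assert sens * spec == pytest.approx(best[0])


def test_liu_perfect_separation_lowest_midpoint():
    scores = np.r_[np.zeros(5), np.ones(5)]
    y = np.r_[np.zeros(5), np.ones(5)].astype(int)
    cut, sens, spec = liu_cutoff(scores, y)
    assert sens == 1.0 and spec == 1.0
    assert cut == pytest.approx(0.5)  # only separating midpoint
    with pytest.raises(ValueError):
        liu_cutoff(scores, np.ones(10, int))


# ---------------------------------------------------------------------------
# ROI longitudinal mixed model

def make_long(rng, n_subjects=6, subject_sd=0.05, slopes=(0.0, 0.058), noise=0.002):
    rows = []
    times = [0.0, 0.25, 0.5, 0.75, 1.0]
    for s in range(n_subjects):
        u = rng.normal(0, subject_sd)
        for roi, sl in zip(("nawm", "progressing"), slopes):
            for t in times:
                rows.append({"subject": s, "roi": roi, "time": t,
                             "value": 1.0 + u + sl * t + rng.normal(0, noise)})
    return pd.DataFrame(rows)


def test_zero_between_subject_variance_matches_pooled_ols():
    rng = np.random.default_rng(9)
    df = make_long(rng, subject_sd=0.0, noise=0.003)
    fit = roi_longitudinal(df)
    import statsmodels.formula.api as smf
    ols = smf.ols("value ~ C(roi, Treatment('nawm')) * time", data=df).fit()
    key = [k for k in ols.params.index if "progressing" in k and ":time" in k][0]
    assert fit.contrasts["progressing"] == pytest.approx(ols.params[key], abs=1e-6)


def test_interaction_recovers_injected_slope():
    rng = np.random.default_rng(10)
    df = make_long(rng, subject_sd=0.05, slopes=(0.0, 0.058))
    fit = roi_longitudinal(df)
    est = fit.contrasts["progressing"]
    se = fit.contrast_se["progressing"]
    assert abs(est - 0.058) < 3 * se + 1e-6
    assert abs(fit.slopes["nawm"]) < 0.005


def test_identical_series_zero_interaction():
    times = [0.0, 0.5, 1.0]
    rows = [{"subject": s, "roi": roi, "time": t, "value": 1.0 + 0.02 * t + 0.01 * s}
            for s in range(4) for roi in ("nawm", "stable") for t in times]
    fit = roi_longitudinal(pd.DataFrame(rows))
    assert fit.contrasts["stable"] == pytest.approx(0.0, abs=1e-8)


def test_single_subject_rejected():
    rng = np.random.default_rng(11)
    df = make_long(rng, n_subjects=1)
    with pytest.raises(ValueError, match="two subjects"):
        roi_longitudinal(df)


def test_assemble_design_validation():
    with pytest.raises(ValueError, match="no subject"):
        assemble_design([])
    df = pd.DataFrame({"outcome": [0, 2], "fw": [0.1, 0.2],
                       "fa_tissue": [0.4, 0.5], "md_tissue": [1, 2],
                       "subject": [0, 0]})
    with pytest.raises(ValueError, match="binary"):
        assemble_design([df])
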