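import numpy as np
import pytest

from fwpenumbra.freewater import (FREE_WATER_DIFFUSIVITY, FreeWaterModel,
                                  compute_trace, fit_dti_wls,
                                  fit_freewater_singleshell, tensor_scalars)
from fwpenumbra.phantom import bitensor_signal, _axisym_tensors
from fwpenumbra.scheme import AcquisitionScheme

from conftest import axisym_tensor6


def single_tensor_signal(s0, t6, scheme):
    return bitensor_signal(np.atleast_1d(s0), np.zeros(1), np.atleast_2d(t6), scheme)


# ---------------------------------------------------------------------------
# WLS tensor fit

def test_wls_exact_on_noiseless_single_tensor(scheme):
    t6 = axisym_tensor6(0.7e-3, 0.5, (0.3, 0.5, 0.9))
    sig = single_tensor_signal(800.0, t6, scheme).reshape(1, 1, 1, -1)
    t6_hat, s0_hat = fit_dti_wls(sig, scheme)
    np.testing.assert_allclose(t6_hat[0, 0, 0], t6, atol=1e-9)
    np.testing.assert_allclose(s0_hat[0, 0, 0], 800.0, rtol=1e-9)


def test_wls_isotropic_gives_zero_fa(scheme):
    t6 = np.array([0.7e-3, 0.7e-3, 0.7e-3, 0, 0, 0])
    sig = single_tensor_signal(500.0, t6, scheme).reshape(1, 1, 1, -1)
    t6_hat, _ = fit_dti_wls(sig, scheme)
    fa, md, _ = tensor_scalars(t6_hat[0, 0, 0])
    assert fa < 1e-9
    np.testing.assert_allclose(md, 0.7e-3, rtol=1e-9)


def test_wls_md_arithmetic_oracle(scheme):
    t6 = np.array([1.5e-3, 0.4e-3, 0.4e-3, 0, 0, 0])
    sig = single_tensor_signal(1000.0, t6, scheme).reshape(1, 1, 1, -1)
    t6_hat, _ = fit_dti_wls(sig, scheme)
    _, md, _ = tensor_scalars(t6_hat[0, 0, 0])
    np.testing.assert_allclose(md, (1.5 + 0.4 + 0.4) / 3 * 1e-3, rtol=1e-9)


def test_wls_rejects_coplanar_directions():
    g = np.zeros((10, 3))
    ang = np.linspace(0, np.pi, 8, endpoint=False)
    g[2:, 0] = np.cos(ang)
    g[2:, 1] = np.sin(ang)
    scheme = AcquisitionScheme(bvals=np.r_[0, 0, np.full(8, 1000.0)], bvecs=g)
    with pytest.raises(ValueError, match="singular design"):
        fit_dti_wls(np.ones((1, 1, 1, 10)) * 100, scheme)


# ---------------------------------------------------------------------------
# trace image

def test_trace_constant_and_geometric_mean(scheme):
    dwi = np.ones((2, 2, 1, len(scheme))) * 7.0
    np.testing.assert_allclose(compute_trace(dwi, scheme), 7.0)

    bvals = np.array([0.0, 1000.0, 1000.0])
    g = np.vstack([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                   [0, 0, 1], [0.707107, 0.707107, 0], [0.707107, 0, 0.707107],
                   [0, 0.707107, 0.707107]])
    sch = AcquisitionScheme(bvals=np.r_[0, np.full(6, 1000.0)], bvecs=g)
    vols = np.ones((1, 1, 1, 7))
    vols[..., 1] = 1.0
    vols[..., 2] = 4.0
    vols[..., 3:] = 2.0
    tr = compute_trace(vols, sch)
    expected = np.exp(np.log([1.0, 4.0, 2.0, 2.0, 2.0, 2.0]).mean())
    np.testing.assert_allclose(tr, expected, rtol=1e-12)


def test_trace_matches_independent_log_mean_exp(scheme):
    rng = np.random.default_rng(0)
    dwi = rng.uniform(10, 1000, size=(3, 4, 2, len(scheme)))
    tr = compute_trace(dwi, scheme)
    dw = dwi[..., scheme.dwi_mask]
    oracle = np.exp(np.mean(np.log(dw), axis=-1))
    np.testing.assert_allclose(tr, oracle, rtol=1e-12)


# ---------------------------------------------------------------------------
# tensor scalars

@pytest.mark.parametrize("lam,expected_fa", [
    ((1.0, 1.0, 1.0), 0.0),
    ((1.0, 0.0, 0.0), 1.0),
])
def test_tensor_scalar_limits(lam, expected_fa):
    t6 = np.array([lam[0], lam[1], lam[2], 0, 0, 0])
    fa, md, _ = tensor_scalars(t6)
    np.testing.assert_allclose(fa, expected_fa, atol=1e-12)
    np.testing.assert_allclose(md, np.mean(lam), atol=1e-12)


def test_tensor_scalars_numeric_oracle():
    lam = np.array([1.5e-3, 0.4e-3, 0.4e-3])
    # independent eigen-decomposition route on a rotated tensor
    rng = np.random.default_rng(3)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    D = Q @ np.diag(lam) @ Q.T
    t6 = np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
    fa, md, _ = tensor_scalars(t6)
    lbar = lam.mean()
    fa_oracle = np.sqrt(1.5 * ((lam - lbar) ** 2).sum() / (lam ** 2).sum())
    np.testing.assert_allclose(fa, fa_oracle, rtol=1e-9)
    np.testing.assert_allclose(md, lbar, rtol=1e-9)


def test_all_zero_tensor_has_fa_zero():
    fa, md, _ = tensor_scalars(np.zeros(6))
    assert fa == 0.0 and md == 0.0


# ---------------------------------------------------------------------------
# free-water fit

def grid_voxels(scheme, fs, fas, md=0.7e-3, seed=0):
    rng = np.random.default_rng(seed)
    fw, t6 = [], []
    for f in fs:
        for fa in fas:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            t6.append(_axisym_tensors(np.array(md), np.array(fa), v))
            fw.append(f)
    fw = np.array(fw)
    t6 = np.array(t6)
    sig = bitensor_signal(np.full(len(fw), 1000.0), fw, t6, scheme)
    return fw, t6, sig


def test_noiseless_identifiability_grid(scheme):
    """Over f x FA, the noiseless single-shell fit recovers f within 0.01
    without oracle initialization."""
    fw, _, sig = grid_voxels(scheme, np.arange(0.0, 0.95, 0.1),
                             np.arange(0.2, 0.85, 0.1))
    res = fit_freewater_singleshell(sig.reshape(-1, 1, 1, len(scheme)), scheme)
    assert np.nanmax(np.abs(res.f.ravel() - fw)) < 0.01


def test_pure_free_water_voxel(scheme):
    fw, _, sig = grid_voxels(scheme, [1.0], [0.5])
    res = fit_freewater_singleshell(sig.reshape(1, 1, 1, -1), scheme)
    assert res.f.ravel()[0] >= 0.99


def test_zero_free_water_reduces_to_wls(scheme):
    fw, t6, sig = grid_voxels(scheme, [0.0], [0.6])
    res = fit_freewater_singleshell(sig.reshape(1, 1, 1, -1), scheme)
    assert res.f.ravel()[0] <= 0.01
    t6_wls, _ = fit_dti_wls(sig.reshape(1, 1, 1, -1), scheme)
    fa_wls, _, _ = tensor_scalars(t6_wls[0, 0, 0])
    assert abs(res.fa_tissue.ravel()[0] - fa_wls) < 0.01


def test_oracle_init_stays_at_truth(scheme):
    f_true = 0.3
    fw, t6, sig = grid_voxels(scheme, [f_true], [0.5])
    init = {"f": np.full((1, 1, 1), f_true),
            "tensor": t6.reshape(1, 1, 1, 6),
            "s0": np.full((1, 1, 1), 1000.0)}
    res = fit_freewater_singleshell(sig.reshape(1, 1, 1, -1), scheme, init=init)
    assert abs(res.f.ravel()[0] - f_true) < 1e-4


def test_monotone_plausibility(scheme):
    """Adding free water raises conventional MD and lowers conventional
    FA, while the fitted tissue scalars track the tissue tensor."""
    t6 = axisym_tensor6(0.7e-3, 0.6, (1, 1, 0))
    md_conv, fa_conv = [], []
    for f in (0.0, 0.2, 0.4):
        sig = bitensor_signal(np.array([1000.0]), np.array([f]),
                              t6[None], scheme).reshape(1, 1, 1, -1)
        t6_wls, _ = fit_dti_wls(sig, scheme)
        fa, md, _ = tensor_scalars(t6_wls[0, 0, 0])
        fa_conv.append(fa)
        md_conv.append(md)
        res = fit_freewater_singleshell(sig, scheme)
        fa_t, md_t, _ = tensor_scalars(t6)
        assert abs(res.fa_tissue.ravel()[0] - fa_t) < 0.02
        assert abs(res.md_tissue.ravel()[0] - md_t) < 0.05e-3
    assert md_conv[0] < md_conv[1] < md_conv[2]
    assert fa_conv[0] > fa_conv[1] > fa_conv[2]


def test_all_zero_voxel_marked_unfit(scheme):
    sig = np.zeros((2, 1, 1, len(scheme)))
    sig[1, 0, 0] = bitensor_signal(np.array([1000.0]), np.array([0.2]),
                                   axisym_tensor6(0.7e-3, 0.5)[None], scheme)
    res = fit_freewater_singleshell(sig, scheme)
    assert not res.mask[0, 0, 0]
    assert np.isnan(res.f[0, 0, 0])
    assert res.mask[1, 0, 0]


def test_simplex_oracle_agreement(scheme):
    """Independent scipy Nelder-Mead fit of a scalar-coded bi-tensor
    objective agrees with the vectorized fit within f tolerance 0.05."""
    from scipy.optimize import minimize

    f_true, fa = 0.35, 0.55
    t6 = axisym_tensor6(0.7e-3, fa, (0.2, 0.9, 0.1))
    sig = bitensor_signal(np.array([1000.0]), np.array([f_true]), t6[None],
                          scheme).ravel()

    b, g = scheme.bvals, scheme.bvecs

    def objective(p):
        s0, f = np.exp(p[0]), 1 / (1 + np.exp(-p[1]))
        L = np.zeros((3, 3))
        L[np.tril_indices(3)] = p[2:]
        D = L @ L.T
        q = np.einsum("ni,ij,nj->n", g, D, g)
        m = s0 * (f * np.exp(-b * FREE_WATER_DIFFUSIVITY) + (1 - f) * np.exp(-b * q))
        return ((m - sig) ** 2).sum()

    x0 = np.r_[np.log(900.0), 0.0, np.linalg.cholesky(
        0.8e-3 * np.eye(3))[np.tril_indices(3)]]
    best = minimize(objective, x0, method="Nelder-Mead",
                    options={"maxiter": 20000, "fatol": 1e-18, "xatol": 1e-12})
    f_simplex = 1 / (1 + np.exp(-best.x[1]))

    res = fit_freewater_singleshell(sig.reshape(1, 1, 1, -1), scheme)
    assert abs(res.f.ravel()[0] - f_simplex) < 0.05


def test_anchored_mode_recovers_roi_means(small_subject, scheme):
    """On a noisy phantom, the b0-anchored fit recovers the class mean FW
    within 0.02 and FA_Tissue within 0.03."""
    t = small_subject.truth
    res = FreeWaterModel(small_subject.dwi(0.0, scheme), scheme,
                         mask=t.wm_mask).fit(mode="anchored",
                                             csf_mask=t.tissue_labels == 1,
                                             voxel_size=t.voxel_size)
    for code, fw_mu, fa_mu in zip((1, 4), (0.520, 0.205), (0.385, 0.479)):
        m = t.roi_labels == code
        if m.sum() < 50:
            continue
        assert abs(np.nanmean(res.f[m]) - t.fw_field[m].mean()) < 0.02
        fa_true, _, _ = tensor_scalars(t.tensor_field[m])
        assert abs(np.nanmean(res.fa_tissue[m]) - fa_true.mean()) < 0.03


def test_anchored_mode_requires_reference(small_subject, scheme):
    with pytest.raises(ValueError, match="csf_mask or s0_csf"):
        FreeWaterModel(small_subject.dwi(0.0, scheme), scheme,
                       mask=small_subject.truth.wm_mask).fit(mode="anchored")
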