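"""Single-shell free-water (bi-tensor) diffusion model fitting.

The bi-tensor model decomposes the diffusion signal into an isotropic
free-water compartment with fixed diffusivity d_fw = 3.0e-3 mm^2/s and
a tissue tensor compartment:

    S(b, g) = S0 [ f exp(-b d_fw) + (1 - f) exp(-b g' D g) ].

Per voxel the fit minimizes the sum of squared signal residuals subject
to f in [0, 1] (logistic transform) and D positive semidefinite
(Cholesky factorization), by Levenberg-Marquardt vectorized across
voxels.  Two initialization/estimation modes exist: a voxel-wise
profile over f (exact on noiseless data), and a "b0-anchored" mode for
noisy data in which f comes from the long-T2 brightening of the b=0
signal calibrated against ventricular CSF and the tensor is fit
conditionally.  Single-shell data alone constrain this model weakly —
the likelihood is nearly flat along a trade-off between f and the
tensor scale — which is why the anchor matters and why convergence is
reported per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .scheme import AcquisitionScheme

FREE_WATER_DIFFUSIVITY = 3.0e-3  # mm^2/s
MD_TISSUE_REF = 0.6e-3           # mm^2/s, reference tissue diffusivity
B0_FW_BRIGHTENING = 1.8          # b0 brightening per unit f (CSF/WM T2 contrast)
SIGNAL_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# tensor utilities

def _t6_to_mat(t6: np.ndarray) -> np.ndarray:
    m = np.empty(t6.shape[:-1] + (3, 3))
    m[..., 0, 0] = t6[..., 0]
    m[..., 1, 1] = t6[..., 1]
    m[..., 2, 2] = t6[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = t6[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = t6[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = t6[..., 5]
    return m


def _mat_to_t6(m: np.ndarray) -> np.ndarray:
    return np.stack([m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
                     m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]], axis=-1)


def tensor_scalars(t6: np.ndarray, clamp: bool = True):
    """(FA, MD) from symmetric tensors given as [xx,yy,zz,xy,xz,yz].

    Eigenvalues are clamped at zero before the scalar formulas; the
    degenerate all-zero tensor gets FA = 0.  Returns (fa, md, n_clamped).
    """
    lam = np.linalg.eigvalsh(_t6_to_mat(np.asarray(t6, float)))
    n_clamped = int(np.count_nonzero(lam < 0))
    if clamp:
        lam = np.clip(lam, 0.0, None)
    md = lam.mean(axis=-1)
    lbar = md[..., None]
    num = ((lam - lbar) ** 2).sum(axis=-1)
    den = (lam ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return fa, md, n_clamped


def compute_trace(dwi: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Trace image: voxel-wise geometric mean of the b>0 volumes."""
    dw = scheme.dwi_mask
    if not dw.any():
        raise ValueError("need at least one diffusion-weighted volume")
    vols = np.clip(np.asarray(dwi, float)[..., dw], SIGNAL_FLOOR, None)
    return np.exp(np.log(vols).mean(axis=-1))


# ---------------------------------------------------------------------------
# log-linear WLS tensor fit (initialization stage)

def _design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    b = scheme.bvals[:, None]
    g = scheme.bvecs
    return np.hstack([
        np.ones((len(scheme), 1)),
        -b * g[:, [0]] ** 2,
        -b * g[:, [1]] ** 2,
        -b * g[:, [2]] ** 2,
        -2 * b * g[:, [0]] * g[:, [1]],
        -2 * b * g[:, [0]] * g[:, [2]],
        -2 * b * g[:, [1]] * g[:, [2]],
    ])


def fit_dti_wls(dwi: np.ndarray, scheme: AcquisitionScheme, mask: Optional[np.ndarray] = None):
    """Weighted least-squares log-linear tensor fit.

    Weights are the squared observed signals (the standard first-order
    variance correction for log-transformed Rician/Gaussian data).
    Returns (tensor6 map, s0 map).
    """
    X = _design_matrix(scheme)
    if np.linalg.cond(X.T @ X) > 1e12:
        raise ValueError("singular design: gradient directions are coplanar/degenerate")
    dwi = np.asarray(dwi, float)
    shape = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    S = np.clip(dwi[mask], SIGNAL_FLOOR, None)  # (V, n)
    if S.shape[-1] < 7:
        raise ValueError("need at least 7 measurements per voxel")
    y = np.log(S)
    w = S ** 2
    A = np.einsum("ni,vn,nj->vij", X, w, X)
    rhs = np.einsum("ni,vn,vn->vi", X, w, y)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    t6 = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    t6[mask] = beta[:, 1:]
    s0[mask] = np.exp(beta[:, 0])
    return t6, s0


def _bilateral_pool(stack: np.ndarray, guide: np.ndarray, inmask: np.ndarray,
                    sigma_vox, intensity_scale: float,
                    orient: Optional[np.ndarray] = None,
                    orient_scale: float = 0.1) -> np.ndarray:
    """Edge-preserving neighborhood average of a channel stack.

    Weights are a spatial Gaussian (sigma_vox per axis, voxels) times a
    Gaussian in the guide-image difference (scale intensity_scale) and,
    when `orient` (unit-vector field, last axis 3) is given, a Gaussian
    in the principal-direction misalignment 1 - |e1.e1'| (scale
    orient_scale) so anisotropy is not destroyed by averaging across
    differently oriented tissue.  Voxels outside inmask contribute
    nothing.
    """
    sigma_vox = np.asarray(sigma_vox, float)
    radius = np.maximum(np.round(1.8 * sigma_vox).astype(int), 1)
    pooled = np.zeros_like(stack)
    wsum = np.zeros(guide.shape, dtype=stack.dtype)

    def shifted(a, off):
        sl_src, sl_dst = [], []
        for o, n in zip(off, a.shape[-3:]):
            if o >= 0:
                sl_src.append(slice(o, n)); sl_dst.append(slice(0, n - o))
            else:
                sl_src.append(slice(0, n + o)); sl_dst.append(slice(-o, n))
        out = np.zeros_like(a)
        out[..., sl_dst[0], sl_dst[1], sl_dst[2]] = a[..., sl_src[0], sl_src[1], sl_src[2]]
        return out

    orient_t = None
    if orient is not None:
        orient_t = np.moveaxis(orient, -1, 0)  # (3, X, Y, Z)
    for dx in range(-radius[0], radius[0] + 1):
        for dy in range(-radius[1], radius[1] + 1):
            for dz in range(-radius[2], radius[2] + 1):
                off = (dx, dy, dz)
                g = np.exp(-0.5 * ((dx / sigma_vox[0]) ** 2 + (dy / sigma_vox[1]) ** 2
                                   + (dz / sigma_vox[2]) ** 2))
                if g < 0.05:
                    continue
                w = g * shifted(inmask[None], off)[0] * np.exp(
                    -0.5 * ((guide - shifted(guide[None], off)[0]) / intensity_scale) ** 2)
                if orient_t is not None:
                    dot = np.abs((orient_t * shifted(orient_t, off)).sum(axis=0))
                    w = w * np.exp(-0.5 * ((1.0 - dot) / orient_scale) ** 2)
                pooled += w * shifted(stack, off)
                wsum += w
    return pooled / np.maximum(wsum, 1e-12)


# ---------------------------------------------------------------------------
# bi-tensor Levenberg-Marquardt fit

def _chol_params_from_tensor(t6: np.ndarray, lam_floor: float = 1e-6) -> np.ndarray:
    """Lower-Cholesky parameters of PSD-projected tensors, (V, 6)."""
    m = _t6_to_mat(t6)
    w, v = np.linalg.eigh(m)
    w = np.clip(w, lam_floor, None)
    m = np.einsum("...ij,...j,...kj->...ik", v, w, v)
    L = np.linalg.cholesky(m)
    return np.stack([L[..., 0, 0], L[..., 1, 0], L[..., 1, 1],
                     L[..., 2, 0], L[..., 2, 1], L[..., 2, 2]], axis=-1)


def _tensor_from_chol(c: np.ndarray) -> np.ndarray:
    l11, l21, l22, l31, l32, l33 = (c[..., k] for k in range(6))
    return np.stack([
        l11 ** 2,
        l21 ** 2 + l22 ** 2,
        l31 ** 2 + l32 ** 2 + l33 ** 2,
        l11 * l21,
        l11 * l31,
        l21 * l31 + l22 * l32,
    ], axis=-1)


def _model_and_jacobian(theta, scheme, need_jac=True, fit_f=True):
    """Bi-tensor model values and Jacobian for a batch of voxels.

    theta: (V, 8) = [ln S0, logit f, l11, l21, l22, l31, l32, l33].
    Returns (m, J) with m (V, n) and J (V, n, 8).
    """
    b = scheme.bvals
    g = scheme.bvecs
    V = theta.shape[0]
    n = len(scheme)
    s0 = np.exp(theta[:, 0])[:, None]
    f = 1.0 / (1.0 + np.exp(-theta[:, 1]))[:, None]
    l11, l21, l22, l31, l32, l33 = (theta[:, k][:, None] for k in range(2, 8))
    gx, gy, gz = g[:, 0][None], g[:, 1][None], g[:, 2][None]
    u1 = l11 * gx + l21 * gy + l31 * gz
    u2 = l22 * gy + l32 * gz
    u3 = l33 * gz
    q = u1 ** 2 + u2 ** 2 + u3 ** 2
    c = np.exp(-b * FREE_WATER_DIFFUSIVITY)[None]
    e = np.exp(-b[None] * q)
    m = s0 * (f * c + (1.0 - f) * e)
    if not need_jac:
        return m, None
    J = np.empty((V, n, 8))
    J[..., 0] = m
    if fit_f:
        J[..., 1] = s0 * (c - e) * f * (1.0 - f)
    else:
        J[..., 1] = 0.0
    common = -s0 * (1.0 - f) * e * b[None] * 2.0
    J[..., 2] = common * u1 * gx
    J[..., 3] = common * u1 * gy
    J[..., 4] = common * u2 * gy
    J[..., 5] = common * u1 * gz
    J[..., 6] = common * u2 * gz
    J[..., 7] = common * u3 * gz
    return m, J


def _lm_fit(S, theta0, scheme, max_iter=200, rtol=1e-8, fit_f=True):
    """Vectorized Levenberg-Marquardt over voxels.

    Returns (theta, cost, converged, n_iter).
    """
    theta = theta0.copy()
    V = theta.shape[0]
    lam = np.full(V, 1e-2)
    m, _ = _model_and_jacobian(theta, scheme, need_jac=False)
    cost = ((m - S) ** 2).sum(axis=1)
    converged = np.zeros(V, dtype=bool)
    active = np.ones(V, dtype=bool)
    free = np.ones(8, dtype=bool)
    if not fit_f:
        free[1] = False
    nf = int(free.sum())
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        th = theta[idx]
        m, J = _model_and_jacobian(th, scheme, fit_f=fit_f)
        r = m - S[idx]
        Jf = J[..., free]
        H = np.einsum("vni,vnj->vij", Jf, Jf)
        grad = np.einsum("vni,vn->vi", Jf, r)
        diag = np.maximum(np.einsum("vii->vi", H), 1e-12)
        A = H.copy()
        A[:, np.arange(nf), np.arange(nf)] += lam[idx][:, None] * diag
        try:
            delta = -np.linalg.solve(A, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A[:, np.arange(nf), np.arange(nf)] += 1e-8
            delta = -np.linalg.solve(A, grad[..., None])[..., 0]
        th_new = th.copy()
        th_new[:, free] += delta
        th_new[:, 1] = np.clip(th_new[:, 1], -16.0, 16.0)
        m_new, _ = _model_and_jacobian(th_new, scheme, need_jac=False)
        cost_new = ((m_new - S[idx]) ** 2).sum(axis=1)
        better = cost_new < cost[idx]
        rel = np.abs(cost[idx] - cost_new) / np.maximum(cost[idx], 1e-30)
        theta[idx[better]] = th_new[better]
        lam[idx[better]] = np.maximum(lam[idx[better]] / 3.0, 1e-10)
        lam[idx[~better]] = np.minimum(lam[idx[~better]] * 4.0, 1e8)
        done = rel < rtol  # converged whether the tiny step was accepted or not
        stuck = ~better & (lam[idx] >= 1e8)
        cost[idx[better]] = cost_new[better]
        converged[idx[done]] = True
        active[idx[done | stuck]] = False
    return theta, cost, converged, None


@dataclass
class FreeWaterResults:
    """Per-voxel free-water fit results over a mask.

    Maps are dense volumes (NaN outside the mask / unfit voxels).
    """

    f: np.ndarray
    tensor: np.ndarray      # (..., 6) tissue tensor
    s0: np.ndarray
    rmse: np.ndarray
    converged: np.ndarray
    fa_tissue: np.ndarray
    md_tissue: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0

    def roi_mean(self, roi_mask: np.ndarray, metric: str = "f") -> float:
        vals = getattr(self, metric)[roi_mask & self.mask]
        return float(np.nanmean(vals))

    def summary(self) -> str:
        lines = [
            "Free-water bi-tensor fit",
            f"  voxels fit        : {int(self.mask.sum())}",
            f"  converged         : {int(self.converged.sum())} "
            f"({100.0 * self.converged.sum() / max(self.mask.sum(), 1):.1f}%)",
            f"  eigenvalues clamped: {self.n_clamped}",
            f"  median FW         : {np.nanmedian(self.f[self.mask]):.3f}",
            f"  median FA_Tissue  : {np.nanmedian(self.fa_tissue[self.mask]):.3f}",
            f"  median MD_Tissue  : {np.nanmedian(self.md_tissue[self.mask]):.3e} mm^2/s",
            f"  median RMSE       : {np.nanmedian(self.rmse[self.mask]):.2f}",
        ]
        return "\n".join(lines)


class FreeWaterModel:
    """Bi-tensor free-water model bound to one DWI series.

    Parameters
    ----------
    dwi : ndarray (..., n_volumes)
    scheme : AcquisitionScheme (single shell with b=0s)
    mask : bool ndarray, voxels to fit
    """

    def __init__(self, dwi: np.ndarray, scheme: AcquisitionScheme,
                 mask: Optional[np.ndarray] = None):
        if not scheme.b0_mask.any():
            raise ValueError("single-shell free-water fit requires b=0 volumes")
        self.dwi = np.asarray(dwi, float)
        self.scheme = scheme
        self.mask = (np.ones(self.dwi.shape[:-1], bool) if mask is None
                     else np.asarray(mask, bool))

    def fit(self, max_iter: int = 200, rtol: float = 1e-8,
            init: Optional[dict] = None, mode: str = "voxel",
            csf_mask: Optional[np.ndarray] = None, s0_csf: Optional[float] = None,
            kappa: float = None, pool_fwhm_mm: float = 0.0,
            pool_scale_f: float = 0.04, voxel_size=(1.0, 1.0, 1.0),
            chunk: int = 40000) -> FreeWaterResults:
        """Fit every masked voxel.

        mode="voxel" (default): independent per-voxel fits with the
        profile-over-f initialization.  Exact on noiseless data, but on
        one shell the likelihood is nearly flat along an f-tensor
        trade-off, so under noise the voxel-wise f wanders; use the
        anchored mode for quantitative maps from noisy data.

        mode="anchored": f is anchored to the b=0 free-water brightening
        (the long-T2 CSF-like compartment raises the b0 signal by a
        factor 1 + kappa*f), calibrated from ventricular CSF via
        csf_mask or an explicit s0_csf; the tissue tensor is then fit
        conditionally on f, which is well-posed.

        init may carry oracle values {"f": map, "tensor": map, "s0": map}
        for round-trip testing.
        """
        shape = self.dwi.shape[:-1]
        mask = self.mask.copy()
        S_all = self.dwi[mask]
        usable = S_all.max(axis=1) > SIGNAL_FLOOR
        flat_idx = np.flatnonzero(mask.ravel())[usable]
        S = np.clip(S_all[usable], SIGNAL_FLOOR, None)
        V = S.shape[0]
        if kappa is None:
            kappa = B0_FW_BRIGHTENING

        fixed_f = False
        anchor_sd = None
        if init is None and mode == "anchored":
            if self.dwi.ndim != 4:
                raise ValueError("anchored mode needs a 4-D DWI volume")
            b0_map = self.dwi[..., self.scheme.b0_mask].mean(axis=-1)
            n_b0 = int(self.scheme.b0_mask.sum())
            if s0_csf is None:
                if csf_mask is None or not np.asarray(csf_mask, bool).any():
                    raise ValueError("anchored mode needs csf_mask or s0_csf")
                csf = np.asarray(csf_mask, bool)
                s0_csf = float(b0_map[csf].mean())
                # tissue-brightness heterogeneity, estimated where f is
                # known constant (pure CSF): spatial b0 variance minus
                # the measurement-noise contribution
                if n_b0 > 1:
                    noise_var = float(np.median(self.dwi[..., self.scheme.b0_mask][csf]
                                                .std(axis=-1) ** 2)) / n_b0
                else:
                    noise_var = 0.0
                rel_var = max(b0_map[csf].var() - noise_var, 0.0) / s0_csf ** 2
                anchor_rel_sd = float(np.sqrt(rel_var))
            else:
                anchor_rel_sd = 0.05
            s0_t_ref = s0_csf / (1.0 + kappa)  # CSF is pure free water
            b0v = S[:, self.scheme.b0_mask].mean(axis=1)
            f0 = np.clip((b0v / s0_t_ref - 1.0) / kappa, 1e-3, 1.0 - 1e-3)
            anchor_sd = np.clip(anchor_rel_sd * (1.0 + kappa * f0) / kappa, 0.01, 0.15)
            A = self._attenuations(S, b0v)
            _, t_init = self._profiled_tensor_cost(A, f0)
            s0v = b0v
            fixed_f = True
        elif init is None:
            s0v = S[:, self.scheme.b0_mask].mean(axis=1)
            f0, t_init = self._profile_f(S, s0v)
        else:
            f0 = np.clip(np.asarray(init["f"], float)[mask][usable], 1e-3, 1 - 1e-3)
            t_init = np.asarray(init["tensor"], float)[mask][usable]
            s0v = np.asarray(init["s0"], float)[mask][usable]
        theta0 = np.empty((V, 8))
        theta0[:, 0] = np.log(np.clip(s0v, SIGNAL_FLOOR, None))
        theta0[:, 1] = np.log(f0 / (1.0 - f0))
        theta0[:, 2:] = _chol_params_from_tensor(t_init)

        theta = np.empty_like(theta0)
        cost = np.empty(V)
        conv = np.empty(V, dtype=bool)
        for lo in range(0, V, chunk):
            sl = slice(lo, min(lo + chunk, V))
            th, co, cv, _ = _lm_fit(S[sl], theta0[sl], self.scheme, max_iter, rtol,
                                    fit_f=not fixed_f)
            theta[sl], cost[sl], conv[sl] = th, co, cv

        result = self._pack(theta, cost, conv, flat_idx, shape, len(self.scheme))
        if fixed_f and pool_fwhm_mm and pool_fwhm_mm > 0:
            # small edge-aware pooling of fitted tensors before the
            # scalar maps: cuts the per-voxel tensor noise that inflates
            # FA (eigenvalue repulsion) while the guide (f map) and the
            # short range preserve lesion boundaries and orientation
            guide = np.nan_to_num(result.f).astype(np.float32)
            inmask = result.mask.astype(np.float32)
            sigma_vox = pool_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_size, float)
            t6 = np.nan_to_num(result.tensor)
            w, v = np.linalg.eigh(_t6_to_mat(t6))
            e1 = v[..., -1].astype(np.float32)
            stack = np.moveaxis(t6, -1, 0).astype(np.float32)
            t6p = np.moveaxis(_bilateral_pool(stack, guide, inmask, sigma_vox,
                                              pool_scale_f, orient=e1), 0, -1)
            fa, md, _ = tensor_scalars(t6p)
            result.fa_tissue = np.where(result.mask, fa, np.nan)
            result.md_tissue = np.where(result.mask, md, np.nan)
            result.tensor = np.where(result.mask[..., None], t6p, np.nan)
        if fixed_f and anchor_sd is not None:
            # second-order (delta-method) correction of the FA/MD maps
            # for anchor uncertainty: FA of the conditional tensor is
            # convex in the anchored f, so zero-mean anchor noise
            # inflates it (Jensen); subtract the curvature term using
            # symmetric refits at f0 +/- anchor_sd
            _, D0 = self._profiled_tensor_cost(A, f0)
            _, Dp = self._profiled_tensor_cost(A, np.clip(f0 + anchor_sd, 1e-3, 1 - 1e-3))
            _, Dm = self._profiled_tensor_cost(A, np.clip(f0 - anchor_sd, 1e-3, 1 - 1e-3))
            fa0, md0, _ = tensor_scalars(D0)
            fap, mdp, _ = tensor_scalars(Dp)
            fam, mdm, _ = tensor_scalars(Dm)
            fa_adj = -0.5 * (fap + fam - 2.0 * fa0)
            md_adj = -0.5 * (mdp + mdm - 2.0 * md0)
            flat = result.fa_tissue.reshape(-1)
            flat[flat_idx] = np.clip(flat[flat_idx] + fa_adj, 0.0, 1.0)
            flat = result.md_tissue.reshape(-1)
            flat[flat_idx] = np.clip(flat[flat_idx] + md_adj, 0.0, None)
        return result

    def _corrected_tensor_init(self, S, s0, f0):
        """Tensor init from free-water-corrected attenuations."""
        dw = self.scheme.dwi_mask
        b = self.scheme.bvals[dw]
        c = np.exp(-b * FREE_WATER_DIFFUSIVITY)[None]
        A = S[:, dw] / np.clip(s0, SIGNAL_FLOOR, None)[:, None]
        At = np.clip((A - f0[:, None] * c) / (1.0 - f0[:, None]), 1e-4, 1.0)
        X = _design_matrix(self.scheme)[dw][:, 1:]  # tensor columns only
        y = np.log(At)
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        return beta.T

    def _attenuations(self, S, s0):
        dw = self.scheme.dwi_mask
        return S[:, dw] / np.clip(s0, SIGNAL_FLOOR, None)[:, None]

    def _profiled_tensor_cost(self, A, fv, n_gn: int = 3):
        """For fixed f per voxel, the profiled tensor (attenuation-space
        least squares via Gauss-Newton from the log-linear solution) and
        the profiled residual sum of squares.

        Refining in attenuation space keeps the noise-absorption part of
        the profiled cost independent of f, so the profile minimum is an
        unbiased location for f; a pure log-space solve would tilt the
        profile toward f = 0 through f-dependent noise amplification.
        """
        dw = self.scheme.dwi_mask
        b = self.scheme.bvals[dw]
        c = np.exp(-b * FREE_WATER_DIFFUSIVITY)[None]
        X = _design_matrix(self.scheme)[dw][:, 1:]
        pinv = np.linalg.pinv(X)
        fv = fv[:, None]
        At = np.clip((A - fv * c) / np.clip(1.0 - fv, 1e-6, None), 1e-5, 1.5)
        D = np.log(At) @ pinv.T

        def _cost(Dk):
            e = np.exp(np.clip(Dk @ X.T, -20.0, 3.0))
            m = fv * c + (1.0 - fv) * e
            return ((m - A) ** 2).sum(axis=1), m, e

        cost, m, e = _cost(D)
        for _ in range(n_gn):
            J = (1.0 - fv)[..., None] * e[..., None] * X[None]
            H = np.einsum("vni,vnj->vij", J, J)
            H[:, np.arange(6), np.arange(6)] += 1e-10
            g = np.einsum("vni,vn->vi", J, A - m)
            D_new = D + np.linalg.solve(H, g[..., None])[..., 0]
            cost_new, m_new, e_new = _cost(D_new)
            better = cost_new < cost
            D = np.where(better[:, None], D_new, D)
            cost = np.where(better, cost_new, cost)
            m = np.where(better[:, None], m_new, m)
            e = np.where(better[:, None], e_new, e)
        return cost, D

    def _profile_f(self, S, s0):
        """Voxel-wise profile of the residual over f: for each fixed f
        the tensor solve is well-posed, so a 1-D search in f sidesteps
        the flat f-tensor trade-off of the single-shell model.
        Returns (f0, tensor_init) per voxel.

        Isotropic voxels are exactly degenerate (a tissue tensor equal
        to d_fw * I mimics any f), so a vanishing tissue-plausibility
        penalty breaks such ties toward tensors near a biological
        diffusivity — decisive only where the data themselves cannot
        distinguish f.
        """
        A = self._attenuations(S, s0)
        V = S.shape[0]

        def cost(fv, n_gn=3):
            c, D = self._profiled_tensor_cost(A, fv, n_gn=n_gn)
            md = D[:, :3].mean(axis=1)
            tie = 1e-10 * ((md - MD_TISSUE_REF) / FREE_WATER_DIFFUSIVITY) ** 2 \
                * (1.0 - fv) ** 2
            return c + tie, D

        grid = np.linspace(0.005, 0.995, 41)
        costs = np.empty((len(grid), V))
        for k, f in enumerate(grid):
            costs[k], _ = cost(np.full(V, f))
        best = costs.argmin(axis=0)
        lo = grid[np.maximum(best - 1, 0)]
        hi = grid[np.minimum(best + 1, len(grid) - 1)]
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        for _ in range(22):
            x1 = hi - gr * (hi - lo)
            x2 = lo + gr * (hi - lo)
            c1, _ = cost(x1, n_gn=2)
            c2, _ = cost(x2, n_gn=2)
            left = c1 < c2
            hi = np.where(left, x2, hi)
            lo = np.where(left, lo, x1)
        f0 = np.clip((lo + hi) / 2.0, 1e-3, 1 - 1e-3)
        _, D = self._profiled_tensor_cost(A, f0)
        return f0, D

    def _pack(self, theta, cost, conv, flat_idx, shape, n_meas):
        def dense(vals, fill=np.nan):
            out = np.full(int(np.prod(shape)), fill)
            out[flat_idx] = vals
            return out.reshape(shape)

        f = 1.0 / (1.0 + np.exp(-theta[:, 1]))
        t6 = _tensor_from_chol(theta[:, 2:])
        fa, md, n_clamped = tensor_scalars(t6)
        fitted_mask = np.zeros(int(np.prod(shape)), bool)
        fitted_mask[flat_idx] = True
        tensor = np.full((int(np.prod(shape)), 6), np.nan)
        tensor[flat_idx] = t6
        return FreeWaterResults(
            f=dense(f),
            tensor=tensor.reshape(shape + (6,)),
            s0=dense(np.exp(theta[:, 0])),
            rmse=dense(np.sqrt(cost / n_meas)),
            converged=dense(conv, fill=0).astype(bool),
            fa_tissue=dense(fa),
            md_tissue=dense(md),
            mask=fitted_mask.reshape(shape),
            n_clamped=n_clamped,
        )


def fit_freewater_singleshell(dwi, scheme, mask=None, **opts) -> FreeWaterResults:
    """Functional wrapper over FreeWaterModel(...).fit(...)."""
    return FreeWaterModel(dwi, scheme, mask).fit(**opts)
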