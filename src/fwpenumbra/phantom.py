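"""Synthetic longitudinal FLAIR + DWI phantom cohorts with growing WMH.

The phantom is deliberately geometric rather than brain-shaped: a
spherical intracranial compartment holding a central CSF "ventricle"
ellipsoid, a white-matter shell, and a cortical gray-matter rim.
Periventricular WMH occupies a configurable fraction of intracranial
volume; lesion growth over follow-up is confined to the 3 mm penumbra
and depends on baseline free water through an exactly logistic law.

Construction of the growth law
------------------------------
Conversion labels are drawn by thresholding a smooth Gaussian random
field at the calibrated rate pi; baseline FW in the conversion-eligible
shell is then class mean + smooth jitter with pointwise SD sigma.  With
fw | label ~ N(mu_label, sigma^2) and P(label)=pi, Bayes' rule gives

    P(convert | fw) = sigmoid(a + b fw),
    b = (mu1 - mu0) / sigma^2,
    a = logit(pi) - (mu1^2 - mu0^2) / (2 sigma^2),

so the generator satisfies simultaneously: logistic dependence on
baseline FW, class-conditional FW means equal to the configured ROI
means, expected converted volume equal to the growth target, and
spatially contiguous growth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .config import CohortConfig
from .freewater import FREE_WATER_DIFFUSIVITY
from .scheme import AcquisitionScheme

# ROI codes in GroundTruth.roi_labels
ROI_WMH, ROI_PROGRESSING, ROI_STABLE, ROI_NAWM = 1, 2, 3, 4

# tissue codes
BG, CSF, GM, WM = 0, 1, 2, 3

_S0_REF = 1000.0


def _rng(config: CohortConfig, subject: int, *stream) -> np.random.Generator:
    """Deterministic stream keyed by (seed, subject, stage) so results do
    not depend on call order."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF,
                                                         int(subject), *map(int, stream)]))


def smooth_unit_field(shape, fwhm_mm, voxel_size, rng) -> np.ndarray:
    """Gaussian random field with ~unit pointwise variance and the given
    spatial FWHM (mm)."""
    sigma_vox = np.asarray(fwhm_mm, float) / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_size, float)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), np.broadcast_to(sigma_vox, (3,)))
    sd = f.std()
    if sd <= 0:
        return f
    return f / sd


@dataclass
class GroundTruth:
    """Per-subject generative truth for one phantom."""

    tissue_labels: np.ndarray          # {0 bg, 1 CSF, 2 GM, 3 WM}
    infarct_mask: np.ndarray
    exclusion_mask: np.ndarray         # infarct + peri-infarct rim
    wmh_masks: np.ndarray              # (T, X, Y, Z) bool, monotone in t
    progression_mask: np.ndarray       # converted voxels
    conversion_tidx: np.ndarray        # int, first timepoint segmented as lesion (-1: never)
    roi_labels: np.ndarray             # {0, ROI_WMH..ROI_NAWM}
    fw_field: np.ndarray               # baseline true free-water fraction
    fw_slope_field: np.ndarray         # 1/year
    tensor_field: np.ndarray           # (..., 6) tissue tensor [xx,yy,zz,xy,xz,yz], mm^2/s
    flair_base: np.ndarray             # noiseless normalized FLAIR at t=0
    flair_slope_field: np.ndarray      # 1/year
    s0_tissue: np.ndarray              # tissue-compartment b=0 brightness
    voxel_size: tuple
    timepoints: tuple
    b0_fw_brightening: float = 1.8
    growth_logit: tuple = (0.0, 0.0)
    target_growth_voxels: float = 0.0
    covariates: dict = field(default_factory=dict)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_labels > 0

    @property
    def wm_mask(self) -> np.ndarray:
        return self.tissue_labels == WM

    @property
    def gm_mask(self) -> np.ndarray:
        return self.tissue_labels == GM

    @property
    def baseline_wmh(self) -> np.ndarray:
        return self.wmh_masks[0]

    def fw_at(self, t: float) -> np.ndarray:
        return np.clip(self.fw_field + self.fw_slope_field * t, 0.0, 1.0)

    def flair_true(self, t: float) -> np.ndarray:
        """Noiseless GM-normalized FLAIR intensity at time t (years)."""
        return self.flair_base + self.flair_slope_field * t

    @property
    def ticv_voxels(self) -> int:
        return int(self.brain_mask.sum())


def _axisym_tensors(md, fa, direction) -> np.ndarray:
    """Axially symmetric tensors with the given MD/FA about `direction`.

    lam1 = MD (1 + 2 FA / sqrt(3 - 2 FA^2)), lam23 = MD (1 - FA / sqrt(3 - 2 FA^2)).
    """
    fa = np.clip(fa, 0.0, 0.99)
    md = np.clip(md, 1e-6, None)
    root = np.sqrt(3.0 - 2.0 * fa ** 2)
    lam1 = md * (1.0 + 2.0 * fa / root)
    lam23 = md * (1.0 - fa / root)
    e = direction
    out = np.empty(md.shape + (6,))
    delta = lam1 - lam23
    out[..., 0] = lam23 + delta * e[..., 0] ** 2
    out[..., 1] = lam23 + delta * e[..., 1] ** 2
    out[..., 2] = lam23 + delta * e[..., 2] ** 2
    out[..., 3] = delta * e[..., 0] * e[..., 1]
    out[..., 4] = delta * e[..., 0] * e[..., 2]
    out[..., 5] = delta * e[..., 1] * e[..., 2]
    return out


def make_anatomy(config: CohortConfig, subject: int = 0,
                 wmh_fraction: Optional[float] = None) -> GroundTruth:
    """Build one subject's anatomy, baseline lesions and true fields."""
    shape = config.grid_shape
    if min(shape) < 32:
        raise ValueError("grid too small to contain all tissue classes (need >= 32 voxels per axis)")
    vx = np.asarray(config.voxel_size, float)
    rng = _rng(config, subject, 1)

    coords = np.meshgrid(*[(np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, vx)],
                         indexing="ij")
    r = np.sqrt(sum(c ** 2 for c in coords))
    half_extent = min(n * v for n, v in zip(shape, vx)) / 2.0
    r_icv = 0.92 * half_extent

    # ventricle: elongated ellipsoid (anterior-posterior axis = y)
    semi = np.array([0.30, 0.45, 0.26]) * r_icv
    vent = (coords[0] / semi[0]) ** 2 + (coords[1] / semi[1]) ** 2 + (coords[2] / semi[2]) ** 2 <= 1.0

    brain = r <= r_icv
    gm = brain & (r > r_icv - config.gm_rim_mm) & ~vent
    labels = np.zeros(shape, dtype=np.int8)
    labels[brain] = WM
    labels[gm] = GM
    labels[vent & brain] = CSF
    wm = labels == WM

    # distance (mm) from WM voxels to the ventricle surface
    d_vent = ndimage.distance_transform_edt(~vent, sampling=vx)

    # chronic infarct: small sphere in lateral WM, plus 3 mm peri-infarct rim
    centre = np.array([0.55 * r_icv, 0.15 * r_icv, 0.0])
    d_inf = np.sqrt((coords[0] - centre[0]) ** 2 + (coords[1] - centre[1]) ** 2
                    + (coords[2] - centre[2]) ** 2)
    infarct = (d_inf <= 6.0) & wm
    exclusion = (ndimage.distance_transform_edt(~infarct, sampling=vx) <= 3.0) & brain

    # baseline periventricular WMH: patchy band hugging the ventricle
    if wmh_fraction is None:
        wmh_fraction = config.wmh_fraction_ticv
    n_wmh = int(round(wmh_fraction * brain.sum()))
    wmh0 = np.zeros(shape, dtype=bool)
    eligible = wm & ~exclusion & (d_vent > 0) & (d_vent <= config.wmh_band_mm)
    if n_wmh > 0 and eligible.sum() > 0:
        patch = smooth_unit_field(shape, config.lesion_patch_fwhm_mm, vx, _rng(config, subject, 2))
        score = patch + 1.2 * (d_vent / config.wmh_band_mm)
        n_wmh = min(n_wmh, int(eligible.sum()))
        cut = np.partition(score[eligible], n_wmh - 1)[n_wmh - 1]
        wmh0[eligible & (score <= cut)] = True

    T = len(config.timepoints)
    wmh_masks = np.repeat(wmh0[None], T, axis=0)

    roi_labels = np.zeros(shape, dtype=np.int8)
    roi_labels[wm & ~exclusion] = ROI_NAWM
    roi_labels[wmh0] = ROI_WMH

    mu_wmh, mu_prog, mu_stab, mu_nawm = config.roi_fw_means

    jit = smooth_unit_field(shape, 2.0 * max(vx), vx, _rng(config, subject, 3))
    fw = np.zeros(shape)
    fw[labels == CSF] = 1.0  # ventricular CSF is pure free water
    fw[labels == GM] = 0.15
    fw[wm] = mu_nawm
    fw[wmh0] = mu_wmh
    jit_amp = np.where(wm, config.fw_jitter_sd, np.where(labels == GM, 0.02, 0.0))
    fw = np.where(brain, np.clip(fw + jit_amp * jit, 0.0, 1.0), 0.0)

    fa_wmh, fa_prog, fa_stab, fa_nawm = config.roi_fa_means
    md_wmh, md_prog, md_stab, md_nawm = config.roi_md_means
    fa_map = np.zeros(shape)
    md_map = np.full(shape, 1.0e-3)
    fa_map[labels == GM] = 0.0
    md_map[labels == GM] = 0.8e-3
    fa_map[wm] = fa_nawm
    md_map[wm] = md_nawm
    fa_map[wmh0] = fa_wmh
    md_map[wmh0] = md_wmh
    jit_fa = smooth_unit_field(shape, 2.0 * max(vx), vx, _rng(config, subject, 4))
    jit_md = smooth_unit_field(shape, 2.0 * max(vx), vx, _rng(config, subject, 5))
    fa_map = np.where(wm, np.clip(fa_map + config.fa_jitter_sd * jit_fa, 0.02, 0.95), fa_map)
    md_map = np.where(wm, np.clip(md_map + config.md_jitter_sd * jit_md, 1e-4, 2.5e-3), md_map)

    # smooth principal-direction field
    vecs = np.stack([smooth_unit_field(shape, 12.0, vx, _rng(config, subject, 6 + k))
                     for k in range(3)], axis=-1)
    vecs[..., 2] += 0.5  # bias so the norm never vanishes
    vecs /= np.linalg.norm(vecs, axis=-1, keepdims=True)
    tensors = _axisym_tensors(md_map, fa_map, vecs)

    fl_wmh, fl_prog, fl_stab, fl_nawm = config.roi_flair_means
    flair = np.zeros(shape)
    flair[labels == CSF] = 0.25
    flair[labels == GM] = 1.0
    flair[wm] = fl_nawm
    flair[wmh0] = fl_wmh
    jit_fl = smooth_unit_field(shape, 2.0 * max(vx), vx, _rng(config, subject, 9))
    flair = np.where(brain, flair + np.where(wm, config.flair_jitter_sd, 0.01) * jit_fl, 0.0)
    # subject-level biology offsets (white matter only, so GM-based
    # normalization does not absorb them)
    rng_subj = _rng(config, subject, 11)
    flair = np.where(wm, flair + config.subject_intercept_sd * rng_subj.standard_normal(), flair)
    fw = np.where(wm, np.clip(fw + 0.5 * config.subject_intercept_sd
                              * rng_subj.standard_normal(), 0.0, 1.0), fw)

    jit_s0 = smooth_unit_field(shape, 2.0 * max(vx), vx, _rng(config, subject, 12))
    s0 = np.where(brain, _S0_REF * (1.0 + 0.05 * jit_s0), 0.0)

    rng_cov = _rng(config, subject, 10)
    covariates = {
        "subject": int(subject),
        "age": float(np.round(rng_cov.normal(71.0, 9.0), 1)),
        "sex": int(rng_cov.random() < 0.31),  # 1 = female
        "race": str(rng_cov.choice(["white", "black", "other"], p=[0.77, 0.15, 0.08])),
        "site": int(rng_cov.random() < 0.5),
    }

    return GroundTruth(
        tissue_labels=labels,
        infarct_mask=infarct,
        exclusion_mask=exclusion,
        wmh_masks=wmh_masks,
        progression_mask=np.zeros(shape, dtype=bool),
        conversion_tidx=np.full(shape, -1, dtype=np.int16),
        roi_labels=roi_labels,
        fw_field=fw,
        fw_slope_field=np.zeros(shape),
        tensor_field=tensors,
        flair_base=flair,
        flair_slope_field=np.zeros(shape),
        s0_tissue=s0,
        b0_fw_brightening=config.b0_fw_brightening,
        voxel_size=tuple(vx),
        timepoints=tuple(config.timepoints),
        covariates=covariates,
    )


def grow_lesions(truth: GroundTruth, config: CohortConfig, subject: int = 0) -> GroundTruth:
    """Fill follow-up lesion masks by converting penumbra voxels.

    Conversion is confined to the 3 mm shell around the baseline lesion
    (lesions advance at their edge); within that shell the conversion
    probability is exactly logistic in baseline FW (see module notes).
    """
    from .rois import build_penumbra  # local import to avoid a cycle

    shape = truth.tissue_labels.shape
    vx = np.asarray(truth.voxel_size, float)
    wm = truth.wm_mask
    baseline = truth.baseline_wmh
    rng = _rng(config, subject, 20)

    shell = build_penumbra([baseline], baseline, wm, truth.exclusion_mask,
                           voxel_size=vx, radius_mm=3.0)

    mu_wmh, mu_prog, mu_stab, mu_nawm = config.roi_fw_means
    sigma = config.fw_jitter_sd
    duration = truth.timepoints[-1] - truth.timepoints[0]

    n_shell = int(shell.sum())
    converted = np.zeros(shape, dtype=bool)
    target_ml = float(truth.covariates.get("growth_target_ml", config.target_growth_ml))
    n_target = target_ml * duration / config.voxel_volume_ml
    if n_shell > 0 and n_target > 0:
        pi = min(n_target / n_shell, 0.999)
        if config.growth_logit is not None:
            a, b = config.growth_logit
            p = 1.0 / (1.0 + np.exp(-(a + b * truth.fw_field)))
            if np.all(p[shell] >= 1.0 - 1e-12):
                import warnings
                warnings.warn("growth_logit forces conversion probability ~1 everywhere in the shell")
            converted[shell] = rng.random(n_shell) < p[shell]
        else:
            # smooth-field thresholding at rate pi -> contiguous patches;
            # the empirical pi-quantile fixes the converted count at the
            # target exactly (variance reduction; subject heterogeneity
            # enters through the per-subject growth target instead)
            u = smooth_unit_field(shape, config.lesion_patch_fwhm_mm, vx, rng)
            n_conv = int(round(pi * n_shell))
            converted = np.zeros(shape, dtype=bool)
            if n_conv > 0:
                cut = np.partition(u[shell], n_conv - 1)[n_conv - 1]
                converted = shell & (u <= cut)
            b = (mu_prog - mu_stab) / sigma ** 2
            a = np.log(pi / (1.0 - pi)) - (mu_prog ** 2 - mu_stab ** 2) / (2.0 * sigma ** 2)
            truth.growth_logit = (float(a), float(b))
    truth.target_growth_voxels = float(n_target)

    # schedule conversion uniformly among follow-up timepoints
    T = len(truth.timepoints)
    tidx = np.full(shape, -1, dtype=np.int16)
    idx = np.argwhere(converted)
    if len(idx):
        sched = _rng(config, subject, 21).integers(1, T, size=len(idx))
        tidx[tuple(idx.T)] = sched
    masks = [baseline.copy()]
    for t in range(1, T):
        masks.append(masks[-1] | (converted & (tidx <= t) & (tidx > 0)))
    truth.wmh_masks = np.stack(masks)
    truth.progression_mask = converted
    truth.conversion_tidx = tidx

    # final analysis penumbra around the union of lesions; reassign FW /
    # FLAIR class means there so analysis-ROI means match the config
    union = truth.wmh_masks[-1] | baseline
    penumbra = build_penumbra([union], baseline, wm, truth.exclusion_mask,
                              voxel_size=vx, radius_mm=3.0)
    penumbra = penumbra | converted  # converted voxels stay penumbra members
    jit = smooth_unit_field(shape, 2.0 * max(vx), vx, _rng(config, subject, 3))
    stable = penumbra & ~converted
    truth.fw_field[stable] = np.clip(mu_stab + sigma * jit[stable], 0.0, 1.0)
    truth.fw_field[converted] = np.clip(mu_prog + sigma * jit[converted], 0.0, 1.0)
    truth.fw_slope_field = np.where(converted, config.fw_slope_progressing, 0.0)

    fl_wmh, fl_prog, fl_stab, fl_nawm = config.roi_flair_means
    jit_fl = smooth_unit_field(shape, 2.0 * max(vx), vx, _rng(config, subject, 9))
    truth.flair_base[stable] = fl_stab + config.flair_jitter_sd * jit_fl[stable]
    truth.flair_base[converted] = fl_prog + config.flair_jitter_sd * jit_fl[converted]
    truth.flair_slope_field = np.where(converted, config.flair_slope_progressing, 0.0)

    fa_wmh, fa_prog, fa_stab, fa_nawm = config.roi_fa_means
    md_wmh, md_prog, md_stab, md_nawm = config.roi_md_means
    jit_fa = smooth_unit_field(shape, 2.0 * max(vx), vx, _rng(config, subject, 4))
    jit_md = smooth_unit_field(shape, 2.0 * max(vx), vx, _rng(config, subject, 5))
    fa_map = np.zeros(shape)
    md_map = np.zeros(shape)
    fa_map[stable] = np.clip(fa_stab + config.fa_jitter_sd * jit_fa[stable], 0.02, 0.95)
    md_map[stable] = np.clip(md_stab + config.md_jitter_sd * jit_md[stable], 1e-4, 2.5e-3)
    fa_map[converted] = np.clip(fa_prog + config.fa_jitter_sd * jit_fa[converted], 0.02, 0.95)
    md_map[converted] = np.clip(md_prog + config.md_jitter_sd * jit_md[converted], 1e-4, 2.5e-3)
    upd = penumbra
    if upd.any():
        # rebuild tensors in the penumbra with the class-specific MD/FA,
        # keeping the existing principal direction
        old = truth.tensor_field[upd]
        e1 = _principal_direction(old)
        truth.tensor_field[upd] = _axisym_tensors(md_map[upd], fa_map[upd], e1)

    truth.roi_labels[stable] = ROI_STABLE
    truth.roi_labels[converted] = ROI_PROGRESSING
    return truth


def _principal_direction(t6: np.ndarray) -> np.ndarray:
    m = np.empty(t6.shape[:-1] + (3, 3))
    m[..., 0, 0] = t6[..., 0]
    m[..., 1, 1] = t6[..., 1]
    m[..., 2, 2] = t6[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = t6[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = t6[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = t6[..., 5]
    w, v = np.linalg.eigh(m)
    return v[..., -1]


def render_flair(truth: GroundTruth, t: float, config: CohortConfig,
                 subject: int = 0, noiseless: bool = False) -> np.ndarray:
    """Raw FLAIR volume at time t: gain_t * true intensity + noise."""
    times = np.asarray(truth.timepoints)
    t_idx = int(np.argmin(np.abs(times - t)))
    if abs(times[t_idx] - t) > 1e-9:
        raise ValueError(f"t={t} is not one of the configured timepoints")
    if config.flair_noise_sd < 0:
        raise ValueError("flair_noise_sd must be >= 0")
    gain = config.gain_per_timepoint[t_idx]
    vol = gain * truth.flair_true(t)
    if not noiseless and config.flair_noise_sd > 0:
        rng = _rng(config, subject, 30, t_idx)
        vol = vol + config.flair_noise_sd * rng.standard_normal(vol.shape)
    return vol


def bitensor_signal(s0, fw, tensors, scheme: AcquisitionScheme) -> np.ndarray:
    """Noiseless two-compartment signal S(b, g) for every voxel.

    S = S0 [ f exp(-b d_fw) + (1 - f) exp(-b g'Dg) ].
    """
    b = scheme.bvals
    g = scheme.bvecs
    q = (tensors[..., None, 0] * g[:, 0] ** 2
         + tensors[..., None, 1] * g[:, 1] ** 2
         + tensors[..., None, 2] * g[:, 2] ** 2
         + 2.0 * tensors[..., None, 3] * g[:, 0] * g[:, 1]
         + 2.0 * tensors[..., None, 4] * g[:, 0] * g[:, 2]
         + 2.0 * tensors[..., None, 5] * g[:, 1] * g[:, 2])
    atten = (fw[..., None] * np.exp(-b * FREE_WATER_DIFFUSIVITY)
             + (1.0 - fw[..., None]) * np.exp(-b * q))
    return s0[..., None] * atten


def render_dwi(truth: GroundTruth, scheme: AcquisitionScheme, config: CohortConfig,
               subject: int = 0, t: float = 0.0, noiseless: bool = False,
               noise_model: str = "rician") -> np.ndarray:
    """DWI series (..., n_volumes) at time t with Rician noise at dwi_snr."""
    if not scheme.b0_mask.any():
        raise ValueError("scheme needs at least one b=0 volume")
    fw = truth.fw_at(t)
    # long-T2 free water brightens the b=0 signal
    s0_total = truth.s0_tissue * (1.0 + truth.b0_fw_brightening * fw)
    sig = bitensor_signal(s0_total, fw, truth.tensor_field, scheme)
    snr = config.dwi_snr
    if noiseless or snr is None or not np.isfinite(snr):
        return sig
    times = np.asarray(truth.timepoints)
    t_idx = int(np.argmin(np.abs(times - t)))
    rng = _rng(config, subject, 40, t_idx)
    sd = _S0_REF / snr
    if noise_model == "rician":
        n1 = rng.standard_normal(sig.shape)
        n2 = rng.standard_normal(sig.shape)
        return np.sqrt((sig + sd * n1) ** 2 + (sd * n2) ** 2)
    elif noise_model == "gaussian":
        return sig + sd * rng.standard_normal(sig.shape)
    raise ValueError(f"unknown noise model {noise_model!r}")


def segmentation_masks(truth: GroundTruth, config: CohortConfig, subject: int = 0) -> np.ndarray:
    """Lesion masks handed to downstream stages: truth optionally
    corrupted by boundary flips (emulating automated-segmentation error)."""
    rate = config.segmentation_flip_rate
    if rate <= 0:
        return truth.wmh_masks.copy()
    rng = _rng(config, subject, 50)
    out = []
    for m in truth.wmh_masks:
        border = ndimage.binary_dilation(m) ^ ndimage.binary_erosion(m)
        flip = border & (rng.random(m.shape) < rate) & truth.wm_mask
        out.append(np.where(flip, ~m, m))
    out = np.stack(out)
    # keep monotone after corruption
    for t in range(1, len(out)):
        out[t] |= out[t - 1]
    return out


@dataclass
class Subject:
    """Lazy per-subject view over the generated truth."""

    truth: GroundTruth
    config: CohortConfig
    index: int

    def flair(self, t: float, noiseless: bool = False) -> np.ndarray:
        return render_flair(self.truth, t, self.config, self.index, noiseless)

    def dwi(self, t: float = 0.0, scheme: Optional[AcquisitionScheme] = None,
            noiseless: bool = False, noise_model: str = "rician") -> np.ndarray:
        from .scheme import default_scheme
        scheme = scheme or default_scheme()
        return render_dwi(self.truth, scheme, self.config, self.index, t,
                          noiseless, noise_model)

    def seg_wmh_masks(self) -> np.ndarray:
        return segmentation_masks(self.truth, self.config, self.index)


def simulate_subject(config: CohortConfig, subject: int = 0) -> Subject:
    frac = config.wmh_fraction_ticv
    if config.wmh_fraction_sigma > 0:
        zf = float(_rng(config, subject, 61).standard_normal())
        frac = frac * float(np.exp(config.wmh_fraction_sigma * zf))
    truth = make_anatomy(config, subject, wmh_fraction=frac)
    if config.growth_subject_sigma > 0:
        z = float(_rng(config, subject, 60).standard_normal())
        truth.covariates["growth_target_ml"] = config.target_growth_ml * np.exp(
            config.growth_subject_sigma * z)
    else:
        truth.covariates["growth_target_ml"] = config.target_growth_ml
    truth = grow_lesions(truth, config, subject)
    vox_ml = config.voxel_volume_ml
    truth.covariates["baseline_wmh_ml"] = float(truth.baseline_wmh.sum() * vox_ml)
    return Subject(truth=truth, config=config, index=subject)


def simulate_cohort(config: CohortConfig):
    """Generate all subjects (list of Subject)."""
    return [simulate_subject(config, s) for s in range(config.n_subjects)]
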