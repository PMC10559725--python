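"""Configuration objects for the synthetic cohort and pipeline stages.

Defaults encode the study conditions of a chronic-stroke small-vessel
disease cohort: ROI-wise free-water and normalized-FLAIR means for
baseline WMH / progressing penumbra / stable penumbra / NAWM, an annual
FLAIR intensity rise of 0.058 in progressing voxels, an annual FW rise
of 0.034, and a target annualized lesion growth of 2.9 ml.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# ROI class order used throughout: (baseline WMH, penumbra-progressing,
# penumbra-stable, NAWM)
ROI_NAMES = ("wmh", "progressing", "stable", "nawm")


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic longitudinal cohort.

    Attributes
    ----------
    n_subjects : int
        Number of subjects to simulate.
    grid_shape : tuple of int
        Voxels per axis.
    voxel_size : tuple of float
        Voxel edge length per axis, mm.
    timepoints : tuple of float
        Acquisition times in years since baseline; strictly increasing,
        at least three values.
    seed : int
        Base seed; per-subject streams are spawned deterministically.
    flair_noise_sd : float
        Additive Gaussian noise SD on FLAIR, in GM-normalized intensity
        units (GM mean defined as 1.0).
    dwi_snr : float
        b=0 signal-to-noise ratio (S0 / noise sd) for Rician DWI noise.
        ``None`` or ``inf`` disables noise.
    roi_fw_means : tuple of float
        True baseline free-water fraction per ROI class, ordered
        (WMH, progressing, stable, NAWM).
    roi_fa_means, roi_md_means : tuple of float
        True baseline tissue-tensor FA and MD (mm^2/s) per ROI class.
    roi_flair_means : tuple of float
        True baseline GM-normalized FLAIR intensity per ROI class.
    flair_slope_progressing : float
        Annual rise of normalized FLAIR intensity in converting voxels.
    fw_slope_progressing : float
        Annual rise of the free-water fraction in converting voxels.
    growth_logit : (float, float) or None
        Logistic (intercept, slope on baseline FW) for per-voxel
        conversion.  ``None`` (default) derives both from the class
        means, ``fw_jitter_sd`` and the calibrated conversion rate.
    target_growth_ml : float
        Expected annualized converted lesion volume per subject, ml.
    growth_subject_sigma : float
        Log-normal sigma of the per-subject growth target around
        ``target_growth_ml`` (median preserved).
    gain_per_timepoint : tuple of float
        Multiplicative scanner gain applied to raw FLAIR at each
        timepoint (makes GM normalization non-trivial).
    """

    n_subjects: int = 8
    grid_shape: tuple = (48, 48, 48)
    voxel_size: tuple = (2.5, 2.5, 2.5)
    timepoints: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    seed: int = 0

    flair_noise_sd: float = 0.03
    dwi_snr: Optional[float] = 40.0
    # b=0 brightening per unit free-water fraction (long-T2 CSF-like
    # compartment; ~CSF/WM b0 brightness ratio 2.8 at TE ~ 90 ms)
    b0_fw_brightening: float = 1.8

    roi_fw_means: tuple = (0.520, 0.379, 0.285, 0.205)
    roi_fa_means: tuple = (0.385, 0.499, 0.556, 0.479)
    roi_md_means: tuple = (6.91e-4, 6.62e-4, 6.30e-4, 6.06e-4)
    roi_flair_means: tuple = (1.189, 1.112, 0.977, 0.928)

    flair_slope_progressing: float = 0.058
    fw_slope_progressing: float = 0.034

    growth_logit: Optional[tuple] = None
    target_growth_ml: float = 2.9
    growth_subject_sigma: float = 0.25

    gain_per_timepoint: tuple = (1.00, 1.07, 0.95, 1.03, 0.98)

    # Within-class voxel-wise spread (smooth fields); the cohort tables
    # report confidence intervals of ROI means, not voxel SDs, so these
    # are free generator parameters.
    fw_jitter_sd: float = 0.07
    md_jitter_sd: float = 0.4e-4
    fa_jitter_sd: float = 0.05
    flair_jitter_sd: float = 0.02
    subject_intercept_sd: float = 0.01

    # Geometry (fractions of the grid half-extent, mm thicknesses)
    wmh_fraction_ticv: float = 0.010
    wmh_fraction_sigma: float = 0.5   # log-normal spread of lesion burden
    wmh_band_mm: float = 9.0
    gm_rim_mm: float = 5.0
    lesion_patch_fwhm_mm: float = 6.0

    # Boundary flip noise on segmentation masks handed downstream
    # (emulates automated-segmentation error; 0 = truth masks).
    segmentation_flip_rate: float = 0.0

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in np.atleast_1d(self.grid_shape).repeat(
            3 if np.ndim(self.grid_shape) == 0 else 1))
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must have three axes")
        self.voxel_size = tuple(float(v) for v in np.broadcast_to(self.voxel_size, (3,)))
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 3 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing with >=3 values")
        self.timepoints = tuple(t)
        fw = np.asarray(self.roi_fw_means, dtype=float)
        if fw.size != 4 or np.any(fw < 0) or np.any(fw > 1):
            raise ValueError("roi_fw_means must be four values in [0, 1]")
        # ordered NAWM < stable < progressing < WMH
        if not (fw[3] < fw[2] < fw[1] < fw[0]):
            raise ValueError("roi_fw_means must be ordered WMH > progressing > stable > NAWM")
        if len(self.gain_per_timepoint) < len(self.timepoints):
            raise ValueError("need one gain per timepoint")
        if self.flair_noise_sd < 0:
            raise ValueError("flair_noise_sd must be >= 0")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        for k in ("grid_shape", "voxel_size", "timepoints", "roi_fw_means", "roi_fa_means",
                  "roi_md_means", "roi_flair_means", "gain_per_timepoint"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        if d.get("growth_logit") is not None:
            d["growth_logit"] = tuple(d["growth_logit"])
        return cls(**d)


def brain_scale_config(**overrides) -> CohortConfig:
    """Cohort at brain-equivalent physical scale (TICV ~ 1.6 L).

    An 80-voxel grid at 2 mm isotropic resolution puts the intracranial
    compartment near 1.6 L so absolute lesion volumes (ml) are directly
    comparable to an adult cohort.
    """
    base = dict(grid_shape=(80, 80, 80), voxel_size=(2.0, 2.0, 2.0))
    base.update(overrides)
    return CohortConfig(**base)


@dataclass
class PenumbraConfig:
    """Penumbra construction parameters: dilation radius in mm and the
    connected-component neighbor rule (1=faces, 2=+edges, 3=+corners)."""

    radius_mm: float = 3.0
    connectivity: int = 3

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.connectivity not in (1, 2, 3):
            raise ValueError("connectivity must be 1, 2 or 3")


@dataclass
class ClusterConfig:
    """Cluster-correction parameters (voxel threshold |Z| and cluster p)."""

    z_thresh: float = 2.3
    p_thresh: float = 0.01
    connectivity: int = 3
    two_sided: bool = True


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    penumbra: PenumbraConfig = field(default_factory=PenumbraConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    predictors: tuple = ("fw", "md_tissue", "fa_tissue", "clinical")
    n_boot: int = 200
    fit_dwi: bool = True
    seed: int = 0
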