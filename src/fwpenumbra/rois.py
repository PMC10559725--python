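"""WMH penumbra construction and region-of-interest bookkeeping.

The penumbra is the white-matter shell within a physical radius
(default 3 mm) of any lesion voxel at any timepoint, minus the baseline
lesion.  Dilation follows a center-to-center Euclidean rule in mm, so
anisotropic voxels are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PenumbraConfig


def _check_grids(*masks):
    shapes = {m.shape for m in masks if m is not None}
    if len(shapes) > 1:
        raise ValueError(f"mask grids do not match: {sorted(shapes)}")


@dataclass
class RoiPartition:
    """Disjoint masks partitioning white matter.

    NAWM = WM minus lesions, penumbra and exclusions.
    """

    baseline_wmh: np.ndarray
    penumbra_progressing: np.ndarray
    penumbra_stable: np.ndarray
    nawm: np.ndarray
    excluded: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        masks = [self.baseline_wmh, self.penumbra_progressing, self.penumbra_stable,
                 self.nawm, self.excluded]
        _check_grids(*masks)
        total = sum(m.astype(np.int8) for m in masks)
        if total.max() > 1:
            raise ValueError("ROI masks must be pairwise disjoint")

    @property
    def penumbra(self) -> np.ndarray:
        return self.penumbra_progressing | self.penumbra_stable

    def volumes_ml(self) -> dict:
        vox_ml = float(np.prod(self.voxel_size)) / 1000.0
        return {
            "baseline_wmh": float(self.baseline_wmh.sum() * vox_ml),
            "penumbra_progressing": float(self.penumbra_progressing.sum() * vox_ml),
            "penumbra_stable": float(self.penumbra_stable.sum() * vox_ml),
            "nawm": float(self.nawm.sum() * vox_ml),
            "excluded": float(self.excluded.sum() * vox_ml),
        }


def dilate_mm(mask: np.ndarray, radius_mm: float, voxel_size) -> np.ndarray:
    """Voxels whose center lies within radius_mm (Euclidean, mm) of any
    mask-voxel center.  Exact via the Euclidean distance transform."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    dist = ndimage.distance_transform_edt(~mask, sampling=np.asarray(voxel_size, float))
    return dist <= radius_mm + 1e-9


def build_penumbra(wmh_masks_by_time, baseline_wmh, wm_mask, exclusion_mask,
                   voxel_size, radius_mm: float = 3.0,
                   config: PenumbraConfig | None = None) -> np.ndarray:
    """Penumbra = dilate_mm(union of lesions over time) minus baseline,
    restricted to WM and minus exclusions."""
    if config is not None:
        radius_mm = config.radius_mm
    masks = list(wmh_masks_by_time)
    _check_grids(baseline_wmh, wm_mask, exclusion_mask, *masks)
    union = np.zeros_like(baseline_wmh, dtype=bool)
    for m in masks:
        union |= m.astype(bool)
    dil = dilate_mm(union, radius_mm, voxel_size)
    pen = dil & ~baseline_wmh.astype(bool) & wm_mask.astype(bool)
    if exclusion_mask is not None:
        pen &= ~exclusion_mask.astype(bool)
    return pen


def classify_penumbra(penumbra, wmh_masks_by_time, significant_increase_mask,
                      wm_mask=None, exclusion_mask=None, baseline_wmh=None,
                      voxel_size=(1.0, 1.0, 1.0)) -> RoiPartition:
    """AND rule: progressing = penumbra voxels newly segmented as lesion
    at any later timepoint AND inside a significant-increase cluster."""
    masks = [np.asarray(m, bool) for m in wmh_masks_by_time]
    baseline = masks[0] if baseline_wmh is None else np.asarray(baseline_wmh, bool)
    _check_grids(penumbra, significant_increase_mask, *masks)
    new_lesion = np.zeros_like(baseline)
    for m in masks[1:]:
        new_lesion |= m
    new_lesion &= ~baseline
    penumbra = np.asarray(penumbra, bool) & ~baseline
    progressing = penumbra & new_lesion & significant_increase_mask.astype(bool)
    stable = penumbra & ~progressing
    wm = np.ones_like(baseline) if wm_mask is None else np.asarray(wm_mask, bool)
    excl = (np.zeros_like(baseline) if exclusion_mask is None
            else np.asarray(exclusion_mask, bool))
    excluded = excl & wm & ~baseline & ~penumbra
    nawm = wm & ~baseline & ~penumbra & ~excluded
    return RoiPartition(
        baseline_wmh=baseline,
        penumbra_progressing=progressing,
        penumbra_stable=stable,
        nawm=nawm,
        excluded=excluded,
        voxel_size=tuple(voxel_size),
    )


def annualized_growth(partition: RoiPartition, voxel_size=None,
                      study_duration_years: float = 1.0,
                      ticv_voxels: int | None = None) -> dict:
    """Progressing volume in ml/year, and as % of total intracranial
    volume per year when ticv_voxels is given."""
    if study_duration_years <= 0:
        raise ValueError("study duration must be positive")
    vx = partition.voxel_size if voxel_size is None else voxel_size
    vox_ml = float(np.prod(vx)) / 1000.0
    n = int(partition.penumbra_progressing.sum())
    ml_per_year = n * vox_ml / study_duration_years
    out = {"growth_ml_per_year": ml_per_year}
    if ticv_voxels is not None:
        if ticv_voxels <= 0:
            raise ValueError("TICV must be positive")
        out["growth_pct_ticv_per_year"] = 100.0 * n / ticv_voxels / study_duration_years
    return out


def partition_rois(truth, significant_increase_mask, seg_masks=None,
                   radius_mm: float = 3.0) -> RoiPartition:
    """Analysis-side ROI partition for one phantom subject."""
    masks = truth.wmh_masks if seg_masks is None else seg_masks
    pen = build_penumbra(masks, masks[0], truth.wm_mask, truth.exclusion_mask,
                         truth.voxel_size, radius_mm)
    return classify_penumbra(pen, masks, significant_increase_mask,
                             wm_mask=truth.wm_mask, exclusion_mask=truth.exclusion_mask,
                             voxel_size=truth.voxel_size)
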