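"""NIfTI-1, FSL bval/bvec and sidecar I/O helpers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np


def affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0),
               affine: np.ndarray | None = None) -> None:
    data = np.asarray(data)
    if not np.isfinite(data[np.asarray(data, bool)] if data.dtype == bool else data).all():
        raise ValueError("refusing to write non-finite values to NIfTI")
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if affine is None:
        affine = affine_from_voxel_size(voxel_size)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(np.abs(np.diag(affine)[:len(data.shape[:3])]))[:3]
                         + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path):
    """Returns (data, affine, voxel_size)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return data, img.affine, tuple(float(z) for z in zooms)


def write_subject(outdir, subject, scheme=None) -> None:
    """Write one phantom subject: FLAIR per timepoint, 4D DWI, labels,
    bval/bvec and a JSON ground-truth sidecar."""
    from .scheme import default_scheme
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, cfg = subject.truth, subject.config
    vx = truth.voxel_size
    for k, t in enumerate(truth.timepoints):
        save_nifti(outdir / f"flair_t{k}.nii.gz", subject.flair(t), vx)
        save_nifti(outdir / f"wmh_t{k}.nii.gz", truth.wmh_masks[k], vx)
    save_nifti(outdir / "tissue_labels.nii.gz", truth.tissue_labels, vx)
    save_nifti(outdir / "infarct.nii.gz", truth.infarct_mask, vx)
    save_nifti(outdir / "exclusion.nii.gz", truth.exclusion_mask, vx)
    scheme = scheme or default_scheme()
    save_nifti(outdir / "dwi.nii.gz", subject.dwi(0.0, scheme).astype(np.float32), vx)
    scheme.to_files(outdir / "dwi.bval", outdir / "dwi.bvec")
    sidecar = {
        "timepoints": list(truth.timepoints),
        "voxel_size": list(vx),
        "growth_logit": list(truth.growth_logit),
        "target_growth_voxels": truth.target_growth_voxels,
        "covariates": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                       for k, v in truth.covariates.items()},
        "true_growth_ml_per_year": float(
            truth.progression_mask.sum() * np.prod(vx) / 1000.0
            / (truth.timepoints[-1] - truth.timepoints[0])),
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2))
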