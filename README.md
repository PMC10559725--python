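# fwpenumbra

Free-water DTI and longitudinal FLAIR analysis of the white-matter
hyperintensity (WMH) penumbra.

In chronic cerebral small-vessel disease, the normal-appearing white
matter within ~3 mm of existing FLAIR lesions — the *WMH penumbra* —
is the tissue most likely to convert to new lesion over the following
year, and elevated interstitial fluid (the *free-water fraction* f of
a bi-tensor diffusion model) precedes that conversion.  `fwpenumbra`
implements the complete analysis chain needed to study this process,
plus a seeded synthetic cohort generator so every stage is testable
without patient data:

1. **Synthetic cohorts** — pre-aligned longitudinal FLAIR + single-shell
   DWI phantoms with periventricular WMH whose growth is confined to
   the 3 mm penumbra and exactly logistic in baseline free water.
2. **Free-water fitting** — the single-shell bi-tensor model
   `S(b,g) = S0 [ f e^{-b d_fw} + (1-f) e^{-b g'Dg} ]`
   (d_fw = 3.0e-3 mm^2/s), yielding FW, FA_Tissue, MD_Tissue and trace
   maps (`FreeWaterModel(dwi, scheme, mask).fit()`).
3. **Penumbra construction** — exact physical-mm dilation of the lesion
   union, baseline subtraction, infarct exclusion, NAWM bookkeeping.
4. **Progression mapping** — GM-normalized, denoised FLAIR; per-voxel
   OLS slope over time; Z-standardization against the stable-NAWM
   null; Gaussian-random-field cluster correction (|Z| >= 2.3,
   p < 0.01) with a permutation-mode cross-check.
5. **Voxel-wise prediction** — pooled penumbra voxels, logistic
   regression with subject-clustered standard errors, ROC/AUC with
   subject-bootstrap CIs, and the Liu (max sensitivity x specificity)
   operating point.

See `docs/methods.md` for the models, assumptions and numerical
choices.

## Worked example

```python
from fwpenumbra import CohortConfig, FreeWaterModel, default_scheme, simulate_subject
from fwpenumbra.pipeline import analyze_subject

subject = simulate_subject(CohortConfig(seed=3), 0)
out = analyze_subject(subject)

print(out["growth"])
print(out["freewater"].summary())
```

prints (seed 3, subject 0):

```
{'growth_ml_per_year': 2.484375, 'growth_pct_ticv_per_year': 0.3525186236253991}
Free-water bi-tensor fit
  voxels fit        : 32464
  converged         : 32462 (100.0%)
  eigenvalues clamped: 0
  median FW         : 0.213
  median FA_Tissue  : 0.489
  median MD_Tissue  : 6.029e-04 mm^2/s
  median RMSE       : 18.04
```

i.e. this phantom subject accrued ~2.5 ml of new confirmed lesion per
year inside the penumbra, and the white-matter free-water and tissue
maps sit at their normal-appearing white-matter levels (FW ~ 0.21,
FA_Tissue ~ 0.49, MD_Tissue ~ 6.0e-4 mm^2/s), as configured (most
white matter is NAWM, so the medians track the NAWM class).  A full
cohort run — growth volumes, ROI mixed models, AUC per predictor —
goes through `fwpenumbra.pipeline.run_pipeline` or the CLI:

```bash
fwpenumbra run --seed 0 --n-subjects 8 --out results/demo
fwpenumbra simulate --out cohort/ --seed 0        # write NIfTI + bval/bvec
fwpenumbra fit-fw --dwi sub/dwi.nii.gz --bval sub/dwi.bval \
    --bvec sub/dwi.bvec --mask wm.nii.gz --out maps/
```

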