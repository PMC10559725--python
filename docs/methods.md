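# Methods

`fwpenumbra` implements, end to end, a longitudinal analysis of white
matter at risk of conversion to FLAIR white-matter hyperintensity
(WMH): a synthetic multimodal cohort generator, a single-shell
free-water (bi-tensor) diffusion fit, construction of the 3 mm WMH
penumbra, voxel-wise localization of FLAIR progression with
Gaussian-random-field (GRF) cluster correction, and pooled-voxel
prediction of progression from baseline diffusion metrics.

## The synthetic cohort

Real longitudinal stroke cohorts with serial FLAIR + DWI are not
publicly deposited, so every stage is exercised on phantoms whose
generative parameters are the published cohort values: per-class
baseline means for free water (WMH 0.520, progressing penumbra 0.379,
stable penumbra 0.285, NAWM 0.205), FW-corrected FA (0.385 / 0.499 /
0.556 / 0.479) and MD (6.91 / 6.62 / 6.30 / 6.06 x 1e-4 mm^2/s),
GM-normalized FLAIR intensity (1.189 / 1.112 / 0.977 / 0.928), an
annual FLAIR rise of 0.058 and FW rise of 0.034 in progressing voxels,
a baseline lesion burden of 1% of intracranial volume, and a target
annualized lesion growth of 2.9 ml.

The phantom geometry is deliberately simple — a spherical intracranial
compartment, a central ventricle ellipsoid, a cortical rim, and patchy
periventricular lesions — because every downstream statistic is
geometry-agnostic and exact bookkeeping (which voxel belongs to which
class, which voxel converted and when) is what the tests need.  At the
default "desk" scale (48^3 voxels, 2.5 mm isotropic) the intracranial
compartment is ~0.7 L; the brain-equivalent configuration (80^3, 2 mm)
puts it at ~1.6 L so absolute ml figures are directly comparable to an
adult cohort.

### Lesion growth

Growth is confined to the 3 mm shell around the baseline lesion.
Conversion labels are drawn by thresholding a smooth Gaussian random
field at the rate pi = target voxels / shell size (threshold at the
empirical pi-quantile, which fixes the converted count; between-subject
variability enters through a log-normal per-subject growth target,
sigma_log = 0.25).  Baseline FW in the shell is the class mean plus a
smooth jitter field with pointwise SD 0.07.  Because
fw | converted ~ N(0.379, sigma^2) and fw | stable ~ N(0.285, sigma^2),
Bayes' rule makes the conversion probability exactly logistic in
baseline FW with slope (mu1 - mu0)/sigma^2 — the generator
simultaneously satisfies the configured class-conditional means, the
growth target, the logistic dependence of risk on baseline free water,
and spatial contiguity of new lesions.  Each converting voxel is
segmented as lesion from a uniformly drawn follow-up visit onward, so
lesion masks are monotone in time; its FLAIR intensity ramps linearly
from baseline at 0.058/year and its FW at 0.034/year.

The voxel-wise within-class SDs (FW 0.07, FA 0.05, MD 0.4e-4, FLAIR
0.02, all as smooth fields) are free generator parameters: the source
tables report confidence intervals of ROI means, which at n ~ 1e5
voxels say nothing about voxel-level spread.  They were chosen once as
plausible tissue heterogeneity and give a true-FW separability (AUC
~0.83) above the published 0.732, which is expected since the published
figure also contains measurement noise.

### Signal rendering

DWI follows the bi-tensor forward model
S(b,g) = S0 [ f exp(-b d_fw) + (1-f) exp(-b g'Dg) ] with
d_fw = 3.0e-3 mm^2/s (body-temperature CSF; conventional in the
free-water literature) on a 12-direction b = 1000 s/mm^2 shell with
four b=0 volumes, with Rician noise at SNR 40 (Gaussian and noiseless
switches exist for oracle tests).  Tissue tensors are axially
symmetric with the class FA/MD about a smoothly varying principal
direction.  Crucially, the b = 0 signal carries the long-T2
free-water contrast of real acquisitions:
S0_total = S0_tissue (1 + kappa f) with kappa = 1.8, consistent with a
CSF/WM b0 brightness ratio of ~2.8 at TE ~ 90 ms.  S0_tissue has 5%
smooth spatial heterogeneity.

FLAIR volumes are class means (+ linear ramps in converting voxels)
times a per-timepoint scanner gain, plus white Gaussian noise
(SD 0.03 in GM-normalized units) and subject-level white-matter
offsets (SD 0.01) that produce genuine random intercepts in the
longitudinal models.

What the phantom does **not** emulate: cortical folding, sub-voxel
partial volume, registration error, motion/eddy artifacts,
scanner-specific distortions, lesion regression.  Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated generative assumptions, not robustness to real-world
preprocessing failures.

## Single-shell free-water fitting

Per voxel the model has eight parameters (ln S0, logit f, and a
Cholesky factor of the tissue tensor, which enforces f in [0,1] and
D >= 0).  The fit minimizes squared signal residuals by
Levenberg-Marquardt vectorized across voxels (relative cost change
< 1e-8 or 200 iterations; non-converged voxels flagged and retained).

Two modes are exposed:

**Voxel-wise mode** (library default) initializes by profiling the
residual over f: for fixed f the free-water-corrected attenuations give
the tensor by a log-linear solve refined with Gauss-Newton steps in
attenuation space, so a 1-D golden-section search in f avoids the
f-tensor trade-off valley.  On noiseless data this recovers f to
better than 0.01 across the f x FA grid.  It must be said plainly:
with a single shell the likelihood is flat along the f-tensor
trade-off to ~1e-5 relative cost, so under realistic noise the
voxel-wise maximum-likelihood f is dominated by noise and barely
tracks the truth.  This degeneracy is intrinsic to single-shell
acquisitions and is why practical single-shell free-water methods rely
on priors or external anchors.

**Anchored mode** (used by the pipeline) exploits the physical
contrast those methods lean on: free water's long T2 brightens the
b=0 signal.  The tissue-brightness reference is calibrated from
ventricular CSF (pure free water), f follows from the observed b0
brightening, and the tissue tensor is then fit conditionally on f,
which is well-posed.  The anchor's uncertainty (tissue-brightness
heterogeneity, estimated from the spatial b0 variance inside CSF after
subtracting measurement noise) propagates into the FA/MD maps through
a second-order delta correction: the conditional FA is convex in the
anchored f, so zero-mean anchor noise inflates it (eigenvalue
repulsion); symmetric refits at f +/- anchor-SD estimate and remove
the curvature term.  An optional edge-aware tensor pooling
(orientation-similarity gated) exists but is off by default.  The
brightening coefficient kappa and d_fw are treated as sequence
constants of the same epistemic status.

## WMH penumbra

Lesion masks from all timepoints are combined, dilated by 3 mm, and the
baseline lesion subtracted; the result is intersected with white
matter and the infarct + peri-infarct exclusion mask removed.
Dilation uses the center-to-center Euclidean rule in physical mm
(exact distance transform), so anisotropic voxels are handled exactly
— the unit tests pin this to brute-force lattice enumeration.
Remaining white matter is NAWM.  Penumbra voxels are classified as
progressing only if they are BOTH segmented as new lesion at a later
visit AND inside a significant FLAIR-increase cluster (the AND rule);
everything else in the penumbra is stable.

## Localizing progression

Per subject: each FLAIR volume is divided by its gray-matter mean
(absorbing scanner gain exactly — the Z maps are invariant to
per-timepoint rescaling), denoised with non-local means, and a
per-voxel OLS slope of intensity on time (years) is fit.  Slopes are
standardized against the subject's own stable-NAWM null
(Z = (beta - mu_N)/sigma_N), then cluster-corrected at |Z| >= 2.3,
cluster p < 0.01, two-sided, 26-connectivity, over the whole
white-matter mask.

NLM settings: patch radius 2, search radius 3, h = 0.8 x the
wavelet-estimated noise SD.  Stronger smoothing (h = 1.5 sigma, small
patches) visibly erodes 1-2-voxel-thick lesion rims: in
generator-truth sensitivity studies the converted-voxel slope shrank
from 0.058 to 0.037/yr and voxel detection sensitivity dropped about
ten points, while the chosen settings keep sensitivity near 0.9.
ROI-level summaries (baseline means, longitudinal models) use the
normalized but *un-denoised* volumes: ROI averaging already suppresses
noise, and the filter's rim erosion would bias thin-structure means.

GRF cluster correction pins this formula set (D = 3): per-axis FWHM
from the gradient-variance estimator of the standardized field
(floored at one voxel, where GRF is invalid); RESELs
R = V / prod(FWHM); expected cluster count
E[m] = R (4 ln 2)^{3/2} (2 pi)^{-2} (u^2 - 1) e^{-u^2/2}; expected
suprathreshold volume E[N] = V Phi~(u); extent tail
P(n >= k) = exp(-beta k^{2/3}) with beta = (Gamma(5/2)/E[n])^{2/3};
cluster-level p = 1 - exp(-E[m] P(n >= k)).  On 200 simulated smooth
null fields (FWHM 3 voxels) the two-sided family-wise error at nominal
0.01 measured 0/200 — the extent test is conservative at high
cluster-forming thresholds on small fields, which is the safe
direction for claiming progression.  A permutation mode (shuffling the
time order before slope fitting) provides a distribution-free check of
the same max-cluster statistic.

## Voxel-wise prediction

Penumbra voxels pooled across subjects form one design table
(outcome: progressing vs stable; baseline FW, FA_Tissue, MD_Tissue;
age, sex, race, MRI site, baseline WMH volume).  Logistic regressions
(one per DTI metric, plus clinical-only) use subject-clustered
sandwich standard errors; McFadden's 1 - ll/ll_null is the reported
pseudo-R^2 (variants differ, so this is stated explicitly).  ROC
curves score voxels by the fitted model's probability (the classifier
under test is the regression, which also orients metrics whose risk
direction is negative, like FA); AUC uses the Mann-Whitney identity
with ties counted 1/2; bootstrap CIs resample *subjects* with
replacement (resampling voxels would ignore exactly the clustering the
sandwich corrects for); the operating point maximizes
sensitivity x specificity (Liu) over midpoints of sorted unique raw
metric values, ties broken toward the lower threshold.

ROI-level longitudinal change uses a random-intercept linear mixed
model, value ~ ROI x time + site + age + sex + race + baseline WMH
volume (NAWM reference; covariates greedily pruned to keep the
subject-level design full rank in small cohorts; Bonferroni-adjusted
contrasts vs NAWM).

## Known limitations and numerical notes

- Detected growth underestimates true growth by ~10% (voxel detection
  sensitivity ~0.9): cluster-corrected detection of thin, 1-2-voxel
  rims is conservative.  The recovery tests budget for this.
- The mixed-model progressing-ROI FLAIR slope overshoots the injected
  0.058/yr by ~15%: the AND rule selects voxels whose (noisy) slopes
  cleared the threshold.  A selection effect of the published design,
  reproduced rather than corrected here.
- All-zero DWI voxels are excluded from maps and flagged; tensor
  eigenvalues are clamped at zero for scalar maps with the clamp count
  reported; degenerate all-zero tensors get FA = 0 by convention.
- Recovery experiments run at 48^3 (DWI) and 80^3 (growth detection)
  with 8 subjects; these sizes reproduce the published means within
  the stated tolerances while keeping a full run in minutes on one
  core.
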