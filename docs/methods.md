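# Methods

This document records the scientific model, the numerical choices and
the known limitations of the `qmrivox` pipeline.

## 1. Signal model and acquisition

The forward model for a saturation-prepared multi-echo acquisition is

```
S(td, te) = gain · PD · (1 − exp(−td · R1)) · exp(−te · R2)
```

with saturation delay `td` and echo time `te` in seconds internally
(milliseconds at the API surface), R1 and R2 in 1/s and PD in percent.
The default protocol uses 4 saturation delays (100, 400, 1380, 2860 ms)
crossed with 5 echoes (14, 28, 42, 56, 70 ms) at TR 2950 ms, i.e. 20
images per slice.  Delays must increase and stay below TR; echoes must
be positive and increasing.  Rician noise effects are approximated by
additive Gaussian noise on the magnitude signal (fractional sigma of the
maximum tissue signal, default 0.02); this is accurate away from the
noise floor, which is where all analysed voxels live.

## 2. Parameter fitting

`fit_parameter_maps` inverts the model per voxel:

* **Initialiser** — two-stage linearisation: log-linear fit of the echo
  decay at the longest delay gives R2 and an amplitude per delay; the
  saturation-recovery curve of those amplitudes is scanned over an R1
  grid and refined, giving (R1, amplitude).
* **Refinement** — batched Levenberg–Marquardt on all 20 samples
  (analytic Jacobian, vectorised over voxels, `fit_max_iter` = 30
  default).  Non-converged voxels are counted in `qc["n_nonconverged"]`.
* **Background** — voxels whose peak signal is below `background_floor`
  (default 2 % of the stack maximum) are excluded from the fit mask.
* **PD calibration** — fitted amplitudes are divided by the mean
  amplitude inside an eroded native ventricle mask and scaled to 100 %,
  making PD a percentage of CSF water.
* **Physical-range mask** — after calibration, voxels with PD outside
  [0, 150] % are removed from the mask (`pd_ceiling` = 150,
  `qc["n_pd_out_of_range"]`).  Partial-volume voxels at the brain edge
  can fit to arbitrarily large amplitudes with near-zero R1; they are
  fit artefacts, not tissue, and would otherwise dominate any
  intensity-derived threshold downstream.  150 % is far above any real
  tissue/CSF PD and far below the artefact amplitudes (10³–10⁶), so the
  cut is insensitive to its exact value.

Noiseless round-trips recover parameters to < 1e-6 relative error; at
2 % noise the fit agrees with an exhaustive grid-search oracle to within
one grid step (tests `test_relaxometry.py`).

## 3. Phantom and cohort

The template head is built from nested ellipsoids on a configurable
grid (default 64 × 64 × 48 at 2 mm): background/skull, cortical GM
shell, WM interior, deep GM nuclei, CSF ventricles; fractional tissue
maps sum to one everywhere.  Tissue parameter means (R1 1/s, R2 1/s,
PD %): WM (1.20, 11.1, 74), GM (1.02, 10.0, 75), CSF (0.29, 3.4, 100).

Per subject: anatomy jitter (small affine perturbation recorded as the
ground-truth registration), between-subject parameter variation, and
for patients: global atrophy (ventricle scale 2.5), a diffuse WM shift
of (−0.13, −0.9, +3.0) — patient WM ≈ (1.07, 10.2, 77) — focal lesions
(severity 0.7 toward CSF values) and frontal WM damage scaled by the
subject's EDSS score (half-step distribution, age-matched groups).

**What the phantom does not emulate:** B1/B0 field inhomogeneity,
slice profiles, motion, Rician noise floor, cortical folding, and any
spatial autocorrelation beyond the smooth ellipsoid geometry.  One
structural consequence matters for interpretation: the ventricle ROI is
pure CSF in both groups and per-subject PD is *calibrated to 100 %
against ventricular CSF*, so the group contrast of ventricular PD is
null by construction.  The pipeline reports it, but no significant
effect can or should appear there; ROI-level PD effects are expected in
tissue ROIs only.

## 4. Segmentation and volumes

Tissue classes are assigned by parameter ranges (`TissueClassRanges`)
inside the fit mask; the brain mask is the largest connected component
of brain-tissue voxels.  Reported measures: intracranial volume (mL),
brain volume, ventricular volume, BPF = brain/ICV · 100 and
VF = ventricles/ICV · 100.  On noiseless phantoms BPF agrees with
ground truth within 2 percentage points (VF within 1); the residual is
partial-volume classification at tissue boundaries.

## 5. Spatial normalisation

Each subject's fitted maps are converted to a synthetic T2-weighted
contrast (TE 100 ms, TR 4500 ms), smoothed (8 mm FWHM, sampled-Gaussian
separable kernel), and registered to the same contrast synthesised from
the template by minimising mean squared difference with an analytic
gradient under L-BFGS-B, multi-resolution (downsample factors 4, 2),
with parameter scaling and restarts.  The estimated affine is the
pull-back map (it inverts the applied anatomy jitter).  Maps are then
resampled onto the common 2 mm template grid.  Registration quality is
scored by the Dice overlap of the moved native ventricle mask against
the subject's ground-truth normalised ventricles (mean ≈ 0.95 at
default settings).  This is a deliberate simplification relative to
tools like SPM/FSL: affine only (the phantom contains no nonlinear
anatomy), MSD cost (identical synthetic contrast on both sides removes
the need for mutual information).

## 6. Voxel statistics

The GLM per voxel is `y = b0 + b1·group + b2·age_c` with contrast
[0, −1, 0] (positive T = reference > patient; the PD map is reported in
the patient-minus-reference direction, where the effect is positive).
Voxels with numerically zero residual variance relative to the signal
(`sigma² ≤ 1e-28 · mean(y²)`) get T = 0 instead of 0/0 noise.  Null
T-fields match the theoretical t tail (binomial-error tests).

Family-wise-error correction uses max-T permutation over group labels
within small volumes (the white-matter ROI family); when the number of
distinct label assignments `C(n, n_pat)` is below `n_perm` the
enumeration is exhaustive, making p-values seed-independent.  EDSS
slope maps are fitted in patients only; `map_regression` regresses the
group T-map on the EDSS slope map over the analysis mask and reports
slope and R².  On this phantom the observed R² is low (≈ 0.03): the
phantom's EDSS effect is confined to frontal WM while the group effect
is diffuse, so the two maps share little spatial structure.

## 7. Multi-parametric histograms

All in-mask voxels of all subjects contribute to pooled 2-D histograms
per parameter pair; counts are divided by group subject count and
subtracted (positive = reference excess, blue; negative = patient
excess, red).  Default windows: R1 0–3, R2 0–15, PD 50–100; 200 bins
whole-brain, 50 for ROI histograms on percentile-based ranges.  The
inclusion mask keeps voxels above 10 % of the mean reference PD
ceiling, where the ceiling is the 99.5th percentile of positive values
(robust to residual fit outliers), combined with the fit masks and the
template brain mask in the pipeline.  ROI markers show group mean
positions with reference→patient arrows.

## 8. ROI tools and mixed models

ROI erosion removes voxels within `level` mm of the boundary using the
exact Euclidean distance transform (strict `distance > level`); erosion
profiles over levels (0, 2, 4, 6, 8 mm) separate partial-volume rims
from ROI cores (e.g. ventricular PD rises and R1/R2 fall with erosion
as tissue contamination is removed).

The ROI-level group test is a mixed-effects model with a random subject
intercept on per-subject ROI means.  For the balanced case this reduces
exactly to the two-sample t-test on subject means (closed form, used by
default); the REML path uses `statsmodels` `MixedLM` with the Powell
optimiser (`maxiter` 2000), which reproduces the closed form to < 1e-6
where applicable.  A singular random-effects estimate
(`cov_re ≤ 1e-6 · scale`, a relative test) triggers a flagged fallback
to the closed form.

## 9. Problem sizes and runtime

Default pipeline (19 + 19 subjects, 64 × 64 × 48 at 2 mm, 300
permutations): ≈ 3 minutes single-core.  The test suite shares one
session-scoped 48 × 48 × 36 run (≈ 80 s total).  All stages are
restartable from files in the work directory; a single seed drives
three derived sub-seeds (simulate, noise, permutation), each < 2³¹.

## 10. Known limitations

* Affine-only normalisation; no nonlinear warping.
* Additive Gaussian noise approximation to Rician magnitude noise.
* Range-based segmentation (no probabilistic atlas priors).
* Ventricular PD group contrast is structurally null (calibration
  target; see §3) — mixed-model significance is expected in tissue
  ROIs and for R1/R2 everywhere, but not for ventricular PD.
* T-map versus EDSS-slope-map regression yields low R² on this phantom
  (spatially disjoint effects; see §6).
* Volumes carry a partial-volume bias of up to ~2 BPF points relative
  to ground truth; group *differences* are much less affected.
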