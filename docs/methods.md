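# Methods

`diffseg` segments white-matter (WM) tract ROIs and WM boundaries directly in
a subject's native diffusion space, guided by the subject's own T1 anatomy,
and quantifies how reproducible the resulting per-tract measures are across
repeated scans.  This note describes the models and procedures, the
parameters that matter, what the synthetic phantom does and does not emulate,
and the numerical choices made where the design was open.

## Pipeline model

The diffusion image is never interpolated out of its native grid.  Instead,
every other image is brought *to* it:

1. **DWI preprocessing.**  b0 frames are rigidly realigned to the first b0,
   their mean forms the reference; diffusion-weighted frames are realigned to
   that mean (6-DOF, normalized-correlation cost).  Realignment of b0 frames
   to the *first* b0 rather than to a naive average avoids biasing the
   reference toward a frame that moved.  Gradient directions are rotated by
   the transpose of each frame's pull-back rotation and renormalized.  A
   brain mask comes from a robust intensity threshold with hole filling and
   largest-component selection.
2. **Tensor fit.**  Per voxel, the log-linearized single-tensor model
   `ln S_i = ln S0 − b_i g_i^T D g_i` is solved by ordinary least squares
   followed by one reweighted pass with weights `w_i = Ŝ_i²` (the classical
   weighted least-squares estimator for log-transformed magnitudes).
   Non-positive samples are excluded per voxel; voxels with fewer than 7
   usable measurements are unfittable; negative eigenvalues are clamped to
   zero and flagged.  FA uses the standard eigenvalue form
   `FA = sqrt(3/2)·‖λ − λ̄‖ / ‖λ‖`.
3. **b0 → T1 registration.**  A correlation-ratio rigid pre-alignment is
   refined by boundary-based registration (BBR): sample sites on the WM
   surface of the T1 (with sub-voxel projection onto the posterior
   0.5-isocontour), outward normals from the signed-distance gradient, and a
   cost `mean(1 − tanh(M·Q))` on the percent contrast
   `Q = 100·(I_out − I_in)/(½(I_out+I_in))` of the b0 sampled at ±d mm along
   each normal.
4. **T1 → template registration.**  A bounded 12-DOF affine initialization
   followed by multi-resolution demons-style descent on the sum-of-squared
   differences, with Gaussian regularization of the displacement field.  The
   images driving this stage are *tissue-enhanced features*: normalized
   intensity plus 0.8 × the WM posterior, built identically for subject and
   template.  This sharpens exactly the surfaces that atlas back-projection
   depends on (the same idea as tissue-map registration in DARTEL-style
   pipelines).
5. **One-step back-projection.**  All transforms are pull-back point maps
   (reference world mm → source world mm).  The template→native chain is the
   inverse of the concatenated (warp, BBR) pair: the BBR rigid is inverted in
   closed form, the warp numerically (damped fixed-point iteration
   `v ← v + ω(−u(y+v) − v)`, ω = 0.5, stop at 0.01-voxel updates).  The same
   inverse rigid back-projects the T1 onto the b0 grid.
6. **Segmentation.**  The back-projected T1 is segmented into CSF/GM/WM by a
   3-class Gaussian-mixture EM (quantile-seeded, deterministic), with one
   bias-refinement round: a degree-2 polynomial is fitted to *class
   residuals* `log I − log μ_class` and divided out, which removes smooth
   intensity drift without absorbing genuine anatomical contrast.  Posteriors
   are lightly smoothed (σ = 0.5 voxel) and renormalized.  The WM map is the
   WM posterior thresholded at 0.8 (inclusive).  Each atlas tract is eroded
   one single-voxel pass (3×3×3 box) in template space, warped to the native
   grid as a trilinear probability, re-thresholded at 0.8, and cross-masked
   with the WM map; a second WM-map erosion gives the conservative variant.
   Boundary masks: the whole-WM boundary is the mask minus its erosion; the
   dilated CSF mask splits it into WM/CSF and WM/GM classes, which partition
   it by construction.
7. **Metrics and reliability.**  Per tract: mean/SD FA, voxel count, volume,
   FA histogram (bin width 0.02 on [0, 1]).  Across visits: per-subject COV
   `(sample SD / mean)·100`, tract-level means, the >5 %-in-either-erosion
   exclusion screen (strict inequality), ICC(3,1) (two-way mixed, single
   measure, consistency) with a parametric F-based CI and a two-level
   bootstrap CI (targets then raters, both with replacement, percentile
   95 %), pairwise Pearson correlation across visits, and Tukey's
   one-degree-of-freedom non-additivity test.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `wm_threshold` | 0.8 | WM-posterior cut for the restricting WM map (inclusive) |
| `tract_threshold` | 0.8 | re-binarization cut for warped tract probabilities |
| `csf_threshold` | 0.8 | CSF-posterior cut for boundary splitting |
| `pre_erode` | 1 | single-voxel tract erosions in template space |
| `wm_erode` | 1 | WM-map erosion condition (2 = conservative variant) |
| `cov_cutoff` | 5.0 % | tract-exclusion screen, either erosion condition |
| `n_boot` | 10 000 | bootstrap replicates for the ICC CI |
| BBR offsets | 1 and 2 mm | contrast sampling distances along the normal |
| BBR slope M | 0.05 | tanh slope on percent contrast |
| demons σ (field / update) | 2 / 1 voxels | Gaussian regularization |
| demons schedule | 3 levels × 50 iterations | multi-resolution descent |

The BBR surface passed by the pipeline is the 0.5 posterior isocontour: a
symmetric blur leaves the 0.5 level set in place, so that surface is an
unbiased boundary estimate, whereas the 0.8 ROI-restriction cut sits
systematically inside the tissue interface (measured to bias BBR by up to
0.8 mm when used as the registration surface).  Averaging the boundary cost
over a 1 mm and a 2 mm offset keeps it both sensitive (the 1 mm sample lies
inside the partial-volume ramp of a 2 mm b0) and well-posed (the 2 mm sample
sees purer tissue); a single saturated offset leaves a flat valley in which
the transform can drift by 1–2 mm.  Out-of-field sites contribute the worst
cost rather than being dropped, and a deterministic ±3 mm translation grid
precedes the Powell descent, which otherwise occasionally follows a spurious
valley from a displaced initialization.

## Synthetic phantom

The phantom is the study cohort: nested ellipsoidal CSF/GM/WM compartments
with two CSF ventricles and six embedded tracts of graded size — a large
callosal-like slab (~570 native DWI voxels), two medium corticospinal-like
cylinders (~85), two thinner cingulum-like bars (~85) and a small fragile
fornix-like bridge (~60) adjacent to the ventricles; the conservative
segmentation protocol retains roughly half of each.  WM tract tensors are
prolate (FA 0.85/0.75/0.70/0.65 along the tract axis; background WM 0.5), GM
is nearly isotropic (FA 0.15), CSF isotropic at 3·10⁻³ mm²/s.  The T1
renders at 1 mm (tissue means 50/120/200, Gaussian noise σ = 5), the DWI at
2 mm (64 quasi-uniform directions at b = 1000 s/mm² plus 4 b0 frames, Rician
noise at b0 SNR 20 in WM).  A smooth multiplicative intensity texture
(≤ 18 %, distinct per-axis wavelengths, asymmetric phases) is fixed in
anatomical space: real tissue is not piecewise constant, and without texture
nonlinear registration is blind to tangential motion along tissue
boundaries, while strong rotational quasi-symmetries of plain ellipsoids can
trap global alignment in flipped poses.  The subject relates to template
space by a seeded smooth sinusoidal warp (amplitude 2.5 mm) and to its own
DWI space by a seeded rigid offset (≤ 3°/2 mm); repeat visits re-render with
fresh noise, a ≤ 2°/2 mm repositioning and a perturbed inter-modality rigid.
Identical seeds give bit-identical phantoms.

What the phantom does *not* emulate: gyrification and realistic cortical
folding, susceptibility/EPI distortion (the field-map pathway is therefore
deliberately unimplemented), eddy-current shear, crossing fibres, lesions,
and scanner drift.  Passing phantom tests therefore demonstrates the
correctness and stability of the algorithms under known geometry and noise,
not performance on clinically distorted data.

Ground-truth reference masks for overlap scoring are produced by the *same*
morphological protocol (erode → warp → 0.8 threshold → WM cross-mask) using
the phantom's exact analytic transforms and partial-volume WM, so a Dice
score against them isolates estimation error (registration + segmentation)
rather than penalizing the protocol's own deliberate conservatism.

## Numerical choices and degenerate inputs

- Erosion/dilation use the full 3×3×3 box (26-connectivity); thresholds are
  inclusive (≥); out-of-field resampling fills 0.
- Dice of two empty masks is undefined and returned as NaN with a warning,
  never 0 or 1.  Empty tract masks are flagged successes, not failures —
  small structures may legitimately vanish under the conservative protocol.
- Warp fields extrapolate their nearest edge value outside the grid; a hard
  zero at the border would make the map non-invertible there.
- Rigid searches are unbounded Powell descents inside a ±20°/±25 mm trust
  region around the initialization (re-run bounded and polished if they
  escape); all schedules are fixed, so every registration is deterministic.
- The BBR cost retains a soft rotational mode of roughly a degree on smooth
  closed surfaces (slope/offset variants all land at 0.99–1.24° on the
  default phantom); the mean point error inside WM, which is what propagates
  into segmentation, stays near 0.3 mm.
- EM degeneracy (a tissue class collapsing below 0.5 % of voxels) triggers
  one re-initialization from alternative quantiles, then an error.
  Class↔tissue assignment is by ascending mean intensity and therefore
  T1-contrast only; other contrasts are rejected.
- COV uses the sample (n−1) SD.  A zero-error-variance ICC table reports
  ICC 1 with a degenerate, flagged CI.  Bootstrap resamples with a single
  distinct target are redrawn and counted.  Exactly additive tables report
  a non-additivity F of 0 with p = 1.
- Tissue-class posteriors, tract probabilities and all thresholds are logged
  in each run's provenance record (config hash, seed, package version,
  stage timings).

## Problem sizes

The default phantom uses a 72³ template/T1 grid at 1 mm and a 36³ DWI grid
at 2 mm with 68 frames; the reliability study simulates one subject with
three visits plus two further single-visit subjects.  These sizes keep a
full subject run under a minute while leaving every structure several
voxels across in native space.

## Known limitations

- BBR accuracy on undistorted data is no better than the correlation-ratio
  pre-alignment it refines (~0.1–0.3 mm); its value on real EPI data (where
  intensity costs are biased by distortion) is not demonstrated here.
- The nonlinear stage is small-deformation demons; large or discontinuous
  anatomical differences (resections, large lesions) are out of its model
  class.
- Boundary masks are one voxel thick at DWI resolution; per-tract boundary
  sampling is meaningful only for large tracts.
- The tract-exclusion screen, ICC design and bootstrap follow a fixed-cohort
  recipe; the functions accept arbitrary rectangular tables and leave the
  rater definition to the caller.
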