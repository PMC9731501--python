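# diffseg

Automated segmentation of white-matter (WM) tract ROIs and WM boundaries in
**native diffusion space**, with a built-in test–retest reliability
framework and fully synthetic multimodal phantoms for validation.

## Who this is for

Diffusion MRI studies usually compare groups after warping everyone's data
into a common template, which interpolates the diffusion signal and breaks
down when brains are structurally atypical (injury, atrophy, lesions).  The
alternative — drawing ROIs by hand on each subject's FA map — is accurate
but slow and rater-dependent.  `diffseg` automates the native-space route:
the subject's own T1 image guides registration and anatomy-restricted
segmentation, the diffusion data are never resampled out of their grid, and
atlas-defined tracts are back-projected from template space through a
single composed transform.

## The method in brief

Per subject: (1) DWI frames are rigidly realigned to the averaged b0 and
gradient vectors rotated accordingly; the diffusion tensor is fitted by
weighted least squares on the log-linearized model
`ln S_i = ln S0 − b_i gᵢᵀ D gᵢ` and FA = √(3/2)·‖λ−λ̄‖/‖λ‖ computed per
voxel.  (2) The b0 is registered to the T1 by boundary-based registration
(BBR): sample sites on the T1's WM surface are mapped into b0 space and the
percent contrast `Q = 100(I_out − I_in)/(½(I_out+I_in))` across the surface
is maximized through a `1 − tanh(M·Q)` cost.  (3) The T1 is nonlinearly
registered to a template (demons-style SSD on tissue-enhanced features).
(4) The warp and the BBR matrix are concatenated and inverted into a
one-step template→native map; the atlas tracts are eroded (3×3×3 box),
warped as probabilities, re-thresholded at 0.8 and cross-masked with the
subject's 0.8-thresholded WM map.  Boundary masks (whole WM, WM/CSF, WM/GM)
come from mask erosion and dilated-CSF cross-masking.  (5) Per-tract mean
FA, volume and FA histograms feed the reliability statistics: COV =
(SD/mean)·100 per subject across visits, ICC(3,1) with parametric and
two-level-bootstrap CIs, pairwise Pearson correlation across visits,
Tukey's non-additivity test, and the rule excluding any tract whose COV
exceeds 5 % in either erosion condition.

Because real scans are not required anywhere, the package ships a phantom
generator: a digital head with six ground-truth tracts of graded size,
known tensors, known inter-modality rigid and nonlinear transforms, and
Rician/Gaussian noise, rendered at the same resolutions as a typical
acquisition (1 mm T1, 2 mm DWI, 64 directions at b = 1000 s/mm² + 4 b0).

## Worked example

```bash
python examples/segment_tracts.py
```

builds a phantom subject (seed 7) and runs the complete workflow:

```
stage timings: {'preprocess': '30.8s', 'register': '33.3s', 'segment': '1.2s', 'metrics': '0.0s'}

tract                voxels   mean FA   DSC vs truth
cc_slab                 316     0.847        0.919
cst_left                 22     0.745        0.840
cst_right                32     0.737        0.968
cingulum_left            28     0.685        1.000
cingulum_right           35     0.683        0.740
fornix_like               5     0.660        1.000

WM boundary voxels: 3325 (WM/CSF 70, WM/GM 3255)
```

Reading this: the large callosal-like slab is segmented with 316 native
voxels at mean FA 0.847 (ground-truth FA 0.85) and Dice overlap 0.919
against the ground-truth protocol mask — sub-voxel registration accuracy at
2 mm.  Small, thin tracts fluctuate more (here the right cingulum-like bar
at 0.740): exactly the size–reliability relationship the COV screen is
designed to catch.  Other examples: `build_phantom.py` (the ground truth
itself), `fit_tensor_fa.py` (tensor fit and FA recovery),
`test_retest_reliability.py` (three visits through the pipeline, COV/ICC
report and exclusion list).

## Command line

The same workflow is scriptable from a shell:

```bash
diffseg phantom --out-dir work/sub-01 --seed 7 --visits 3
diffseg run-all --dwi work/sub-01/visit-1/dwi.nii.gz \
    --bvals work/sub-01/visit-1/bvals --bvecs work/sub-01/visit-1/bvecs \
    --t1 work/sub-01/visit-1/t1.nii.gz \
    --template work/sub-01/truth/template.nii.gz \
    --atlas work/sub-01/truth/atlas.nii.gz \
    --labels work/sub-01/truth/atlas_labels.tsv \
    --out-dir out --subject sub-01 --visit visit-1
diffseg reliability out/sub-01/*/metrics/roi_metrics.csv --out-dir out/reliability
```

Outputs land under `out/<subject>/<visit>/{dwi,anat,xfm,masks,metrics,qc}`:
NIfTI volumes, plain-text transforms, tidy CSV tables, a QC overlay PNG and
a provenance record (config hash, seed, version, timings).  Completed runs
are skipped unless `--force` is set.

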