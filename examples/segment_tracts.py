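"""Run the full native-space segmentation workflow on one subject.

Preprocess -> segment the T1 -> boundary-based b0->T1 registration ->
nonlinear T1->template -> back-project the atlas -> anatomy-restricted
tract masks -> ROI metrics, then score each mask against the phantom's
ground truth.
"""

import warnings

from diffseg.image import dice
from diffseg.phantom import TRACTS, make_phantom, truth_native_tract
from diffseg.pipeline import RunConfig, process_subject

truth, session = make_phantom(seed=7)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = process_subject(
        session.dwi, session.gtab, session.t1,
        truth.template, truth.atlas, RunConfig(subject="demo"),
    )

print("stage timings:",
      {k: f"{v:.1f}s" for k, v in result.timings.items()})
print()
print("tract                voxels   mean FA   DSC vs truth")
for code, (name, _, _) in TRACTS.items():
    est = result.tract_masks[(code, 1)]
    gt = truth_native_tract(truth, session, code)
    row = result.metrics[
        (result.metrics.tract == name) & (result.metrics.wm_erode == 1)
    ].iloc[0]
    d = dice(est, gt) if est.n_voxels + gt.n_voxels else float("nan")
    print(f"{name:20s} {est.n_voxels:6d} {row.mean_fa:9.3f} {d:12.3f}")

b = result.boundaries
print()
print(f"WM boundary voxels: {b.whole_wm_boundary.n_voxels} "
      f"(WM/CSF {b.wm_csf_boundary.n_voxels}, WM/GM {b.wm_gm_boundary.n_voxels})")
print()
print("DSC compares against a reference built with the same protocol but "
      "the exact transforms, so it measures estimation error only; values "
      "near 0.9 mean sub-voxel registration at 2 mm.")
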