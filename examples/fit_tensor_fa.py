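"""Fit the diffusion tensor and compute FA on a synthetic acquisition.

Demonstrates the preprocessing path: b0 averaging, brain masking,
weighted-least-squares tensor fit, and FA extraction, then compares
recovered FA against the phantom's known values per compartment.
"""

import numpy as np

from diffseg.dwi import average_b0, brain_mask_from_b0, fa_from_tensor, fit_tensor_wls
from diffseg.image import Volume, resample
from diffseg.phantom import TRACTS, make_phantom, truth_native_tract

truth, session = make_phantom(seed=7)

b0 = average_b0(session.dwi, session.gtab)
mask = brain_mask_from_b0(b0)
tensors = fit_tensor_wls(session.dwi, session.gtab, mask)
fa = fa_from_tensor(tensors)

print(f"brain mask: {mask.n_voxels} voxels; "
      f"clamped-eigenvalue voxels: {int(tensors.clamped.sum()) if tensors.clamped is not None else 0}")
print()
print("compartment          true FA   recovered mean FA (native voxels)")
for code, (name, fa_true, _) in TRACTS.items():
    gt = truth_native_tract(truth, session, code, protocol=False)
    vals = fa.data[gt.data]
    print(f"{name:20s} {fa_true:7.2f}   {vals.mean():7.3f}  ({gt.n_voxels})")
print()
print("Recovered FA sits slightly below truth at tract edges (partial "
      "volume with surrounding WM/GM at 2 mm) and carries Rician noise "
      "bias of a few hundredths at SNR 20 — both expected.")
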