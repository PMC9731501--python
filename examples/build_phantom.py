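"""Build a synthetic multimodal subject and look at its ground truth.

The phantom is a digital head: nested CSF/GM/WM compartments, ventricles,
six WM tracts of graded size with known diffusion tensors, a T1 at 1 mm and
a 68-frame DWI at 2 mm related by known rigid + nonlinear transforms.
"""

import numpy as np

from diffseg.phantom import TRACTS, make_phantom, truth_native_tract

truth, session = make_phantom(seed=7)

print(f"template grid : {truth.template.shape3} at 1 mm")
print(f"T1 image      : {session.t1.shape3}, intensity "
      f"{session.t1.data.max():.0f} max (WM~200, GM~120, CSF~50)")
print(f"DWI image     : {session.dwi.data.shape} at 2 mm, "
      f"{int(session.gtab.is_b0.sum())} b0 + "
      f"{int((~session.gtab.is_b0).sum())} diffusion frames")
print(f"rigid b0->T1  : translation "
      f"{np.round(truth.rigid_b0_to_t1.translation, 2)} mm")
print()
print("tract                template mm^3   native DWI voxels   true FA")
for code, (name, fa, _) in TRACTS.items():
    mm3 = int((truth.atlas.labels.data == code).sum())
    native = truth_native_tract(truth, session, code, protocol=False).n_voxels
    print(f"{name:20s} {mm3:12d} {native:17d} {fa:9.2f}")
print()
print("The graded sizes matter: reliability downstream is driven by tract "
      "size, with the small fornix-like bridge the fragile one.")
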