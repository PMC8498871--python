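"""Nucleus/whole-cell YAP intensity ratio on a closed-form synthetic image.

A ratio below 1 means cytoplasmic YAP; nuclear enrichment (mechanically
activated proliferation signaling) pushes it toward and above 1 — ratios
above 1 are excluded as mis-segmentation by convention.
"""

import numpy as np

from monolayer_mech.morphometry import yap_ratio
from monolayer_mech.synthgen import gen_yap_image

cell = np.zeros((64, 64), dtype=bool)
cell[8:56, 8:56] = True
nucleus = np.zeros_like(cell)
nucleus[20:44, 20:44] = True  # 25% of the cell pixels

img, truth = gen_yap_image(cell, nucleus, I_nuc=80.0, I_cyto=160.0, noise=0.0, seed=0)
ratios, n_excluded = yap_ratio(img, nucleus, cell)
print(f"measured ratio : {ratios[1]:.6f}")
print(f"closed form    : {truth['yap_ratio']:.6f}  "
      "(I_nuc / (f·I_nuc + (1−f)·I_cyto), f = nuclear pixel fraction)")
print(f"excluded (>1)  : {n_excluded}")

img_hi, _ = gen_yap_image(cell, nucleus, I_nuc=200.0, I_cyto=100.0, noise=0.0, seed=0)
kept, excluded = yap_ratio(img_hi, nucleus, cell, exclude_gt1=True)
print(f"nuclear-bright cell with exclusion rule: kept {len(kept)}, excluded {excluded}")
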