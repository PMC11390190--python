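"""Despeckle, equalize and strip annotation marks from a phantom.

SRAD smooths speckle while preserving the nodule boundary; histogram
equalization stretches the gray levels; the morphological mark filter
inpaints the bright caliper overlays.
"""

import numpy as np

from thyronet import (PhantomSpec, SradParams, add_annotation_marks,
                      generate_phantom, histogram_equalize,
                      remove_annotations, srad_filter)

sample = generate_phantom(PhantomSpec(height=256, width=256, n_nodules=1,
                                      nodule_radius_range=(25, 40), seed=3))

filtered = srad_filter(sample.image, SradParams(n_iterations=30, time_step=0.05))
cv_before = sample.image.std() / sample.image.mean()
cv_after = filtered.std() / filtered.mean()
print(f"speckle CV before SRAD: {cv_before:.3f}, after: {cv_after:.3f}")

despeckled = np.clip(np.round(filtered), 0, 255).astype(np.uint8)
equalized = histogram_equalize(despeckled)
print(f"gray range after equalization: [{equalized.min()}, {equalized.max()}]")

marked = add_annotation_marks(despeckled, seed=9)
restored = remove_annotations(marked)
mark_px = marked != despeckled
before = np.abs(marked.astype(int) - despeckled.astype(int))[mark_px].mean()
after = np.abs(restored.astype(int) - despeckled.astype(int))[mark_px].mean()
print(f"mean residual on mark pixels: {before:.1f} -> {after:.1f}")
# The residual drop shows the caliper marks were replaced with local
# tissue values rather than left in the frame.
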