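"""Check both network tables by shape arithmetic and a real forward pass."""

import numpy as np

from thyronet import (build_cnn4, build_cnn15, cnn4_spec, cnn15_spec,
                      init_weights, validate_architecture)

for spec in (cnn15_spec(), cnn4_spec()):
    report = validate_architecture(spec)
    print(f"{report.name}: {'conformant' if report.conformant else 'MISMATCH'} "
          f"- {report.conv_layers} conv, {report.pool_layers} pool, "
          f"{report.fc_layers} fc, final {report.final_shape}")

rng = np.random.default_rng(0)
seg = init_weights(build_cnn15(), seed=0)
pmap = seg.predict(rng.normal(size=(1, 2, 353, 353)).astype(np.float32))
print(f"CNN15 forward: 2x353x353 -> probability map {pmap.shape[2]}x{pmap.shape[3]}, "
      f"values in [{pmap.min():.3f}, {pmap.max():.3f}]")

clf = init_weights(build_cnn4(), seed=1)
probs = clf.predict(rng.normal(size=(3, 2, 64, 64)).astype(np.float32))
print(f"CNN4 forward: 2x64x64 -> class distributions, row sums "
      f"{probs.sum(axis=1)}")
# A 353x353 patch maps to one 44x44 nodule-probability grid (8 px/cell);
# the classifier emits a softmax over nodule / not-nodule.
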