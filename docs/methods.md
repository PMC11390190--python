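# Methods

This note records the models, the defaults and their rationale, the
numerical choices, and what the synthetic phantoms do and do not
establish about clinical data.

## Synthetic phantoms

The generator emulates three properties of B-mode thyroid frames:
fully developed speckle, hypoechoic lesions, and burned-in annotation
marks.

- **Speckle** is multiplicative unit-mean Gamma noise,
  `pixel = background_mean · G`, `G ~ Gamma(s, 1/s)` with
  `s = speckle_shape` (default 6, giving a background coefficient of
  variation `1/√s ≈ 0.41`, typical of envelope-detected tissue after
  display mapping). Gamma is the standard fully-developed-speckle
  surrogate; no acoustic simulation is attempted.
- **Nodules** are rotated ellipses whose interior echo level is scaled
  by `1 − nodule_contrast` (default 0.5), with a 2-px Gaussian-smoothed
  rim. Default radii 20–60 px on a 512² frame. Real nodules have
  textured interiors, irregular margins and posterior acoustic
  artifacts; none of these are modeled.
- **Annotation marks** are 2–6 caliper crosses and dashed segments at
  intensity ≥ 240.

Seeding: every sample in a dataset draws its seed from a SHA-256
counter stream over `(dataset_seed, index)`, so datasets are
order-independent and byte-reproducible.

Consequently, passing tests show that each stage implements its
contract and that the cascade is lossless given correct upstream
outputs; they do not show clinical detection accuracy, which depends on
lesion appearance variability the phantoms deliberately omit.

## SRAD

The diffusion update is the explicit 4-neighbour scheme
`I ← I + (Δt/4)·div(c ∇I)` with the conduction coefficient driven by
the instantaneous coefficient of variation q:

```
q² = [½(|∇I|/I)² − (1/16)(∇²I/I)²] / [1 + ¼(∇²I/I)]²
c  = 1 / (1 + (q² − q₀²)/(q₀²(1 + q₀²)))
```

with `q₀(t) = q₀·exp(−ρ·t)`. Defaults: 30 iterations, Δt = 0.05
(well inside the 0.25 explicit-scheme stability bound), q₀ = 1, ρ =
0.05. `c` is clipped to [0, 1] and the output to the input range;
borders replicate. A constant image is an exact fixed point.

The pipeline order is SRAD → histogram equalization → annotation
removal → augmentation. Annotation removal must follow despeckling:
on raw speckle, single-pixel bright grains are locally
indistinguishable from caliper marks.

## Histogram equalization

8-bit LUT `v ↦ round(255·(cdf(v) − cdf_min)/(N − cdf_min))`; the
monotone map preserves the rank order of distinct levels and a constant
image is returned unchanged (the degenerate denominator case). The map
is idempotent up to one gray level of quantization drift.

## Annotation removal

A pixel counts as a mark when it is bright (≥ 240) *and* thin (white
top-hat under a 3×3 cross ≥ 40). The detected mask is dilated by one
pixel and replaced with the 5×5 grayscale opening of the image — the
opening suppresses thin bright structures, so it provides the local
tissue level to inpaint with. (A closing would preserve the bright
marks instead of removing them.)

## Augmentation

`multiplier` total outputs: the resized original plus `multiplier − 1`
variants combining a random affine (rotation ±15°, scale 0.9–1.1 — the
operation classes are fixed, the ranges are this package's defaults),
optional horizontal/vertical flips, and a random crop to `crop_size`
(default 230). Warps fill with reflected content so the frame stays
complete. The default multiplier is 10; much larger factors mostly add
redundant near-duplicates.

## Soft morphology and enhancement

Soft erosion with `[B, A, k]` is the k-th smallest of the multiset
holding k copies of each core (A) sample and one copy of each soft
boundary (B\A) sample; dilation is the k-th largest; opening is erosion
followed by dilation with the reflected system. With k = 1 and A = B
these are exactly the classical min/max operators (verified against an
independent implementation in the tests). Borders replicate edges.

Element geometry: the printed description ("middle cross is 1, the
remaining positions 0") is read as B = A = cross; a `soft_boundary`
switch makes B the full square with A the cross for users who want a
true soft rim. The rank default is k = 2 and the per-layer enhancement
weights default to 1.0 — rank and weight are stored as separate fields
even though the source notation reuses one symbol for both.

Top-hat layers are clamped at 0: soft opening with k > 1 is not
guaranteed anti-extensive, and the additive enhancement presumes
nonnegative bright features. The cascaded decomposition (each scale's
top-hat taken on the image already opened at the smaller scales) is the
default, honoring the idempotence argument — a feature of a given size
is extracted and amplified exactly once; the direct per-scale mode is
retained for comparison. In the anti-extensive case the cascade
telescopes exactly: `image − g_n = Σ layers`.

The threshold `m = m_fraction · max(image)` is recomputed per image
(default fraction ⅔). Sub-threshold pixels are returned bit-identical;
boosted pixels clip at 255, so enhancement is pointwise non-decreasing.

## Networks

Both layer tables are embedded as data and re-derived by
`validate_architecture` via `out = ⌊(in + 2p − f)/s⌋ + 1`; the builders
realize them with numpy kernels (im2col convolution, −∞-padded max
pooling, cumulative-sum LRN windows, sub-pixel shuffle).

- **PReLU** is `x ≥ 0 ? x : a·x` with the slope *scheduled*, not
  gradient-trained: a = 0.9 initially, minus 0.01 per epoch. (The
  printed activation formula is the plain rectifier, but the
  surrounding text specifies the parametric unit with this schedule.)
- **LRN** uses the canonical cross-channel form
  `b = a / (k + (α/n)·Σ_{window} a²)^β` with a symmetric window of
  n/2 channels each side, truncated at the borders. Parameter sets:
  segmentation net sites (96, 24, 5e-4, 0.75) and (256, 16, 5e-4,
  0.75); classifier sites (64, 24, …) and (64, 16, …).
- **Double size** is factor-2 sub-pixel rearrangement: 22×22×256 →
  44×44×64 conserves all 123 904 elements; it is the only reading under
  which the printed sides and channels are consistent.
- **CNN15's head** is a per-cell logistic squashing of the final
  single-channel 44×44 map. (The softmax-over-2-labels sentence
  belongs to the fully connected classifier; a single map admits only
  per-cell squashing.)
- **CNN4's head** defaults to 2 logits + softmax; the printed table's
  single output unit is available as `n_logits=1` with a sigmoid. The
  meaning of the 2 input channels is never stated in the source; this
  package pairs the preprocessed image with its enhanced companion,
  falling back to duplication.
- Conv2a uses stride 2 (the table value; the prose contradicts itself).

## Training

SGD; weights ~ N(0, 0.01²), biases 0; weight decay 5e-4 on weights
only; batch 64 (or the dataset size); momentum ramped linearly from 0
to 0.9 across the first 10 epochs ("linear at 0.9 within 10 epochs");
PReLU slopes follow the decay schedule. CNN15: constant lr 2e-4,
per-cell binary cross-entropy against the ground-truth mask
area-downsampled to 44×44 and thresholded at 0.5 (the target
construction is this package's choice; none is stated in the source).
CNN4: softmax cross-entropy; base lr 1.0 — the printed rate, which is
well-behaved here because the 0.01-std initialization keeps gradient
magnitudes near 1e-6 — with multiplier `2^(−(epoch−6)/8)` after epoch
10 (the printed exponent is garbled; the decaying reading is adopted
and non-increasing by construction).

Splits: 4:3:3 train/validation/test, or 75/25 train/test with 10% of
the training portion carved out as validation so best-epoch selection
(minimum validation loss, earliest tie) stays applicable. All
shuffling, init and batching are driven by explicit seeds; training is
bit-reproducible on one device.

Problem sizes in the test suite are chosen for a single CPU: classifier
convergence is demonstrated on 32 training / 16 validation separable
patches within 15 epochs, and segmentation-net smoke convergence on 6
replicated phantom patches for 3 epochs; the degenerate all-background
fit uses a small two-convolution map network trained for 400 epochs.
These sizes demonstrate that the optimization recipe and gradients are
correct, not that the full networks reach clinical accuracy.

## Cascade

Binarization threshold 0.5, 3×3 square erosion/dilation elements,
8-connectivity — standard choices; none are stated in the source.
Regions sort by descending area with row-major centroid tie-breaks.
Coordinates are 0-based, row-major, with half-open patch extents; map
cells upscale by 8 to image pixels.

The 80%-area rule is read as *the patch covering ≥ 80% of its region's
area* (with a 64×64 patch this is the only generally satisfiable
direction) plus the patch center lying inside the region; "correctly
segmented" is operationalized as region∩truth ≥ 50% of the region
area. Both fractions are configurable.

Multiview inference averages over the four axis-aligned symmetries
(identity, horizontal flip, vertical flip, 180° rotation), each its own
inverse. Full-image maps are stitched by arithmetic mean over
overlapping tiles (default stride 176 ≈ 50% overlap); images smaller
than a tile are reflect-padded.

## Evaluation

ROC-AUC by average ranks (ties ½). FROC sweeps the distinct detection
scores; a ground-truth region is hit when an above-threshold
detection's centroid falls inside it, greedily by score, one detection
per region and one region per detection; unmatched detections are false
positives. Ensembling is the elementwise weighted mean of two score
lists with weights proportional to member validation accuracies.
K-fold splitting is a seeded shuffle into folds differing by at most
one element.

## Known limitations

- Phantoms omit lesion texture, acoustic shadowing/enhancement, probe
  geometry and inter-device variability; metrics on phantoms bound the
  plumbing, not clinical performance.
- The numpy kernels target correctness and CPU-scale workloads, not
  GPU throughput; full-scale training of the segmentation network is
  out of reach at desk scale.
- Black top-hat (dark-feature) enhancement, DICOM I/O, 3-D volumes and
  the transfer-learning baselines are out of scope.
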