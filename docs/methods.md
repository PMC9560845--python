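# Methods

## The model

MHA-Net is an encoder/decoder network for binary segmentation of medical
images (retinal vessels, stent wires in fluoroscopy, polyps in endoscopy).
It has three parts:

1. **Feature encoder.** A ResNet-34 trunk (7×7/stride-2 stem, 3×3/stride-2
   max pool, residual stages of [3, 4, 6, 3] basic blocks at widths
   64/128/256/512) with the classifier removed. Five taps feed the decoder:
   the stem output (stride 2, 64 ch, taken *before* pooling — the only
   choice that makes the decoder's final full-resolution stage line up),
   the four stage outputs (strides 4/8/16/32 at 64/128/256/512 ch).
2. **Pyramid split attention (PSA) bridge** on the 512-channel bottleneck:
   split into 4 groups of 128 channels; convolve each group at its own
   scale (kernels 3/5/7/9, group-convolution counts 1/4/8/16 to keep the
   large kernels cheap); compute an SEWeight vector per group; softmax the
   four weights across the group axis at each channel index; rescale and
   re-concatenate. Output shape equals input shape.
3. **MHA decoder.** Each of four stages: channel-preserving transposed
   convolution (kernel 4, stride 2, padding 1 — exact doubling without
   checkerboard bias), concatenation with the skip tap (center-cropped by
   at most one pixel per edge if sizes disagree; with /32 inputs no crop
   occurs), two 3×3 conv+BN+ReLU layers, SE channel attention, and an
   elementwise sum with the same skip. Stage outputs are 256/128/64/64
   channels — each equal to its skip width so the summation is well-typed.
   A fifth, skip-free transposed convolution reaches full resolution at 32
   channels, and two final 3×3 convolutions (32→32 with BN+ReLU, 32→1
   plain) produce the logit map. Probabilities are sigmoid(logits).

On an 800×800×3 input the intermediate sizes are 25×25×512 (bottleneck),
50×50×512 (upsampled), 50×50×768 (concat), 50×50×256 (stage-1 output),
100×100×384 (stage-2 concat), …, 800×800×32 (pre-head);
`mhanet.shape_trace` records them all.

### Width of the two decoder convolutions

The stage's concat width and output width are fixed by the skip chain, but
whether the first 3×3 convolution already reduces to the output width is a
genuinely open design choice. We run both convolutions wide
(concat→concat, then concat→out). The resulting trainable-parameter total
is 36,867,649 (36.87 M), within 6% of the published 34.79 M figure;
the reduce-early alternative totals 30.57 M (−12%). Since the published
budget sits between the two conventions, no simple consistent chain hits
it exactly; we chose the convention that lands closer. Widths are
exposed in `DecoderStageConfig` for anyone who wants the other variant.

### Other under-determined choices

* The fourth PSA kernel is printed as 8 in the source description; an even
  kernel cannot be same-padded symmetrically and the pyramid convention is
  3/5/7/9, so the default is 9. The kernel list is configurable.
* "Channel attention" in the decoder stage is an SE block with reduction
  16 (matching the SE ablation label); reduction is configurable, and an
  SE block refuses construction when the reduction would leave no hidden
  unit.
* BN follows every 3×3 convolution except the final 1-channel head conv.
* PSA is applied once, at the bottleneck only.
* Batch norm uses biased batch variance for both normalization and the
  running-statistics update (momentum 0.1, eps 1e-5) — one consistent
  convention.

## Compute engine

The network runs on a compact numpy layer engine (`mhanet.nn`): a
reverse-mode autodiff tape over ndarrays with hand-derived backward passes
for convolution (plain/grouped/transposed), batch norm, max pooling,
SE/softmax/activations, and a fused logit-space binary cross-entropy, plus
Adam. Convolution is computed tap-by-tap in a channels-last layout so each
kernel offset is a single contiguous BLAS matmul; no im2col buffer is
materialized, which keeps the 800×800 full-width forward pass inside
ordinary desktop memory. Gradients of every op are checked against central
finite differences in the test suite (relative error ≲ 1e-6 in float64).
All weight initialization is He-style from an explicit
`numpy.random.Generator`, so a model built twice from one seed is bitwise
identical; evaluation mode is fully deterministic.

ImageNet-pretrained encoder weights are a convenience only: the
`pretrained=True` flag loads a user-supplied `.npz` state dict and errors
without one. Nothing in the tests or defaults depends on it.

## Training protocol

Binary cross-entropy computed on logits (identical to probability-space
BCE to ~1e-7, but stable), Adam at learning rate 1e-4, constant schedule,
no augmentation. Reference batch sizes are 4 (retina, X-ray) and 8
(polyp), with 300/150/150 epochs respectively at full scale. The snapshot
with the best validation Dice is retained. Images whose sides are not
multiples of 32 (e.g. 584×565 fundus images) are reflection-padded on the
bottom/right and predictions cropped back, which is information-preserving
(resizing is available in preprocessing if wanted, but padding is the
default).

## Synthetic data: what it emulates, what it does not

`mhanet.synth` renders three mask families with matched low-level
statistics — dark random-walk curvilinear structures of varying thickness
(vessel), thin bright mirrored-sinusoid lattices (stent), low-contrast
deformed-ellipse blobs with blurred boundaries (polyp) — over smooth
low-frequency background texture with per-channel gain jitter and Gaussian
pixel noise. A bounded retry loop rescales structure count/size until the
foreground fraction falls in the spec's interval (defaults: vessel
0.03–0.15, stent 0.01–0.08, polyp 0.05–0.30). Per-sample seeds derive from
a global seed by a counter-based `SeedSequence`, so a dataset is
reproducible regardless of generation order; masks are stored as {0, 255}
8-bit PNG and binarized at >127 on read, so the disk round trip is exact.

These fixtures exercise every pipeline stage — geometry, padding, class
imbalance, optimization, metrics — but they are *not* photorealistic: no
vessel branching topology, no specular highlights, no acquisition
artifacts, no inter-patient variability. Passing the synthetic training
checks demonstrates that the architecture and optimization are wired
correctly and can fit curvilinear/blob structure; it says nothing about
accuracy on clinical data, which requires the real datasets and full-scale
training.

## Desk-scale problem sizes

The shipped checks run on a single CPU in minutes, at sizes chosen once:

* Architecture trace: one 800×800×3 forward pass of the full 36.9 M-param
  model (inference mode).
* Training smoke test: quarter-width model (2.31 M params), 40 synthetic
  96×96 polyp-style images, 30 epochs, batch 4, lr 1e-4 → held-out Dice
  > 0.9 over 8 fresh seeds.
* Capacity check: one sample memorized for 200 steps. The dataset protocol
  rate 1e-4 memorizes only to Dice ≈ 0.84 in 200 Adam steps; a capacity
  check wants the fastest stable rate, so this check (and only this check)
  runs at lr 1e-3, reaching Dice 1.0.
* Ablation harness: the four variants (baseline / +PSA / +SE / full) train
  one epoch on 96×96 stent-style data at quarter width; the
  parameter-count ordering baseline < baseline+SE < full and
  baseline < baseline+PSA < full is asserted at full width
  (36.41 / 36.43 / 36.86 / 36.87 M).

## Metrics

All metrics derive from the TP/FP/TN/FN pixel tallies; AUC is computed
from the un-thresholded probabilities via `sklearn.metrics.roc_auc_score`
and is validated against an independent Mann–Whitney pair-enumeration
oracle in the tests, as are all count-based formulas against a naive
per-pixel loop (agreement to 1e-12). Conventions where the definitions are
silent: binarization threshold 0.5 (overridable); empty-vs-empty
comparisons score 1.0 with a warning (both raters agree there is nothing
to find); dataset aggregation is macro (unweighted per-image mean) with a
pooled micro variant available. The Dice–Jaccard identity
DC = 2·IoU/(1+IoU) and mIoU = (IoUp+IoUb)/2 hold by construction and are
property-tested.

## Known limitations

* CPU-only and unbatched BLAS: full-width 800×800 inference takes tens of
  seconds; the engine is built for correctness, determinism and desk-scale
  experiments, not throughput.
* Binary segmentation only; no deep supervision, multi-class heads, or
  test-time augmentation.
* The published benchmark scores on DRIVE/FRSA/polyp data require the
  external datasets and GPU-scale training and are out of scope here; the
  readers accept those datasets' layouts, but nothing downloads them.
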