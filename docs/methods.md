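# Methods

This note records the models, conventions and design choices behind
`lvseg`, at the level of detail a maintainer or reviewer needs to
interpret the outputs and the test suite.

## Network

The segmentation model is a U-shaped encoder/decoder of residual units.
For an `ArchConfig(n_levels=L, base_channels=c)` the encoder level `l`
produces `c·2^l` channels (l = 0…L−1), a transition residual unit at the
bottom produces `c·2^L`, and the decoder mirrors the encoder with 2×2
transposed-convolution upsampling. The head is a 1×1 convolution to
`n_classes` followed by a per-pixel softmax, so output resolution equals
input resolution. Defaults: 128 px inputs, L = 4, c = 32. Endocardium and
epicardium are segmented by two separately trained binary networks rather
than one 3-class model, which keeps the two tasks' class balances and
post-processing independent.

**Residual unit.** With short skips enabled:

```
f1  = ReLU(BN(conv1(x)))
y   = conv2(concat[f1, x])      # concatenative short skip
out = ReLU(BN(y + proj(x)))     # additive short skip
```

`proj` is the identity when input and output channel counts match and a
1×1 convolution otherwise. The additive join sits *before* the second
BN+ReLU, so a unit whose convolution weights are all zero reduces exactly
to `ReLU(BN(x))` — a property the tests exploit. With
`use_short_skip=False` the unit degrades to two plain conv+BN+ReLU
blocks. The precise placement of the two short skips is a design choice
of this package: the wiring is isolated in one class so alternatives are
swappable.

**Medium skips.** At each contracting step `i ≥ 1` the raw model input is
passed through a per-level 1×1 convolution with stride `2^i` and
`base_channels` output channels, then concatenated with the downsampled
features. Because the skip is concatenative, toggling it changes not only
the 1×1 weights but also the input widths (and hence weights) of every
downstream residual unit; the parameter-audit test asserts the exact
analytic delta of this wiring.

**Depth-wise separable block.** For a block mapping `c₁ → c₂` channels
(c₂ even): S1 = 3×3 convolution with `c₂/2` outputs; S2 = per-channel
(depth-wise) 3×3 convolution of S1, `c₂/2` channels; output = `[S1, S2]`,
normalized and rectified after the (possibly residual-joined) block.
Kernel weights: `9·c₁·c₂/2 + 9·c₂/2` vs `9·c₁·c₂` for a plain 3×3
convolution — 2448 vs 4608 at 16→32. Convolutions followed by BN carry
no bias, so these counts are exact in the built network.

**Downsampling** is 2×2 max-pooling by default (strided 1×1 convolution
selectable); upsampling is a 2×2 transposed convolution. Weight
initialization is He-normal from a per-model seeded generator.

## Numerical engine

The network runs on a small reverse-mode autograd engine over numpy
arrays (`lvseg.nn`): dense 3×3 convolutions via im2col + BLAS matmul,
the depth-wise pass as a fused single-read numba kernel, and standard
batchnorm/pooling/softmax ops. Two engineering choices matter for
behavior:

* convolution backward passes recompute their im2col columns instead of
  retaining them in the graph — peak memory stays a few hundred MB where
  retention would reach gigabytes at realistic widths;
* every backward formula is verified against central finite differences
  in the test suite, and the dense convolution against
  `scipy.signal.correlate2d`.

Training is deterministic for a fixed seed (weight init, shuffling and
phantom noise all flow from seeded generators; the engine is pure
numpy/numba single-process).

## Training

Per-pixel cross-entropy is the default loss; soft-dice and the sum of
both are selectable. (The loss, optimizer and batch size are choices of
this package.) Optimizer: Adam (SGD selectable), batch size 8, 150
epochs by default. The learning rate decays linearly from 0.001 to
0.0001 over the first 120 epochs and is constant afterwards; the
recorded history's learning-rate column equals this schedule exactly.
Model selection keeps the epoch with the best validation dice
(foreground dice, empty-vs-empty slices scoring 1). Non-finite loss
aborts with the epoch and learning rate in the message.

At inference the argmax mask (ties resolve to background, the lower
class index) is reduced to its largest 4-connected component, since the
LV is a single structure; the post-processing is switchable.

## ROI localization and cropping

The LV is the most strongly moving structure in a cine stack, so the
locator computes the per-pixel temporal standard deviation across
frames, clusters the values with k-means (k = 3), binarizes the
highest-mean cluster, and uses the centroid of the connected component
nearest the frame center; an Otsu threshold on the variation map is the
fallback when clustering yields nothing. A constant stack raises a
degenerate-input error — there is no motion cue to exploit. The exact
published localization procedure behind this step is not recoverable;
the implementation is a documented stand-in consistent with
"clustering + threshold adjustment" practice.

Crops are fixed-size windows (128 px default) centred on the estimate
and *clamped* — never padded — into the frame, so ROI pixels are always
real data; the recorded (row, col) offset maps predictions back to
full-frame coordinates. All coordinates are 0-based.

## Augmentation

Each training pair expands tenfold: original, seven clockwise rotations
(45°–315° in 45° steps) and horizontal/vertical flips of the original —
the printed factor of ten forces flips to apply to the original only.
90°-multiples and flips are exact pixel permutations; the 45° family
uses bilinear interpolation for images and nearest-neighbour for masks
(masks stay strictly binary), filling out-of-frame corners with the
median of the image corners (0 for masks). Augmentation applies to the
training split only, after ROI cropping.

## Evaluation conventions

* **Dice** is computed on pixel sets; both masks empty is an error, not
  silently 0 or 1.
* **Contours** come from the 0.5 iso-line of the binary mask (marching
  squares), requiring a single connected component.
* **APD** is symmetric: the mean over vertices of each contour of the
  distance to the nearest *segment* of the other, averaged over both
  directions, in mm (axes scaled independently for anisotropic spacing).
  Whether the historical challenge metric was one-directional is not
  documented; the symmetric choice is this package's convention.
* **Good contour**: APD < 5 mm, strictly.
* **Per case**: PGC is over all slices; DM/APD means over good slices
  only. An empty prediction counts against PGC and is excluded from the
  means. Cohort summaries report mean and *sample* SD (ddof = 1; a
  single case reports SD 0).

## Clinical indices

Volumes are slab sums: Σ slice area × (thickness + gap), gap 0 by
default (whether real acquisitions included an inter-slice gap is
configurable rather than assumed). LVM = (V_epi^ED − V_end^ED) · 1.05 g/ml,
defined only when the epicardial volume encloses the endocardial one;
EF = 100·(V_end^ED − V_end^ES)/V_end^ED. Agreement statistics: mean bias,
±1.96·SD(sample) limits, t-based 95% CI and one-sample t-test of the
bias, OLS slope/intercept/R². In the pipeline, a case whose *predicted*
volumes violate physiology (epi < endo, or empty ED stack) is flagged
`physiological=False` with NaN auto indices instead of aborting the run;
the strict errors remain in the library functions.

## Phantom

Each case: a per-case base endocardial radius (14–22 px at 256 px
frames), wall thickness (5–9 px), center jitter (±10 px), 6–12 slices,
ED radius tapering by 0.93 per slice toward the apex, ES endocardial
radius = 0.65 × ED (per-slice area ratio 0.65², i.e. EF ≈ 58%,
physiological). Intensities: pool 400, myocardium 180, background 60,
plus N(0, 12²) noise on the image only — ground truth is computed on the
noiseless geometry. Pixel spacing defaults to 1.367 mm and thickness to
8 mm, matching a typical short-axis cine protocol.

Rasterization rule, fixed and relied on by the volume/dice oracles: a
pixel is inside a disc iff its center is strictly within the radius. An
optional sinusoidal boundary perturbation (amplitude in px, integer lobe
count) makes contours non-circular so distance metrics are exercised on
non-trivial geometry.

**What the phantom does not emulate:** MR physics (coil bias, k-space
artifacts), papillary muscles, anatomical shape variability, the right
ventricle, through-plane motion. Passing on phantoms therefore
demonstrates that the implementation is correct and that the
architecture can learn this family of shapes — not clinical-grade
accuracy on real MR data.

## Benchmark problem sizes

The built-in benchmarks (`lvseg.experiments`) run at desk scale: 96 px
phantom frames whose 64 px ROI plays the role of the 128 px ROI of
full-size acquisitions; an improved network with 3 levels and 8 base
channels; 128 ten-fold-augmented training slices, 32 held-out validation
slices, 2 test cases; 12 epochs with the linear schedule spanning the
run. Under these conditions the held-out dice reaches ≈ 0.94 and every
test contour is good (PGC 100%).

The per-epoch timing comparison between the separable network and its
standard-convolution twin runs channel-heavy — 32 px inputs with 64 base
channels on a proportionally scaled phantom — because the separable
block's saving lives in convolution arithmetic: at toy widths the step
time is dominated by width-independent bookkeeping and data movement,
and a timing there would measure overhead, not the convolution cost.
Epochs are timed with process CPU time (equal to wall-clock for this
single-process engine up to scheduler jitter); first-call JIT
compilation is excluded, the two variants alternate batch by batch
inside one loop so machine-speed drift hits both equally, and the best
of five timed epochs per variant is reported. Under these conditions
the separable network's epoch costs 0.82–0.87 of the twin's. The
parameter audit (separable strictly fewer weights than the twin at
every tested configuration) is the width-independent mechanism behind
the difference.

## Known limitations

* The autograd engine supports exactly the ops this architecture needs;
  it is not a general framework.
* Phantom realism is deliberately limited (see above); no claims
  transfer to clinical data without retraining and re-evaluation.
* The ROI locator assumes the LV is near the frame center and moving;
  static or far-off-center hearts defeat the heuristic.
* 45°-family rotations are the only interpolating augmentations; no
  elastic or intensity augmentation is provided.
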