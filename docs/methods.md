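# Methods

## Problem and approach

Digitizing homologous landmarks on insect wing venation — vein bases,
crossings, bifurcations and termini — is the rate-limiting step of
landmark-based wing morphometrics. `wingmark` implements heatmap-regression
landmark detection for beetle hindwings: each of the K landmarks (K = 36 by
default, the standard hindwing scheme spanning the humeral plate, subcostal
and radial veins, the radial cell, the medial field and the cubitus-anal
field) is represented by a 2-D Gaussian score map, a multi-resolution
convolutional network regresses these maps from a wing image crop, and the
decoded peaks are the predicted landmark coordinates. Detection error is
summarized by the normalized mean error

NME(P, P̂) = (1/K) Σᵢ ‖pᵢ − p̂ᵢ‖ / d,

with d the specimen's reference distance: landmark 1 (proximal anterior
point of the humeral plate) to landmark 18 (distal point of RA1), the
wing's long axis. d is computed from the ground-truth coordinates of each
test specimen, never from predictions, so the normalizer is a property of
the specimen.

Because annotated hindwing corpora are tiny (hundreds of specimens), the
package centers on parameter transfer: load a backbone pretrained on a
large source domain, re-initialize the heatmap head randomly, and choose
which network stages to retrain. Three named strategies cover the
spectrum — TH (head only), TS (stage 1 retained as a general feature
layer; stages 2–4 and head retrained), TA (everything retrained) — with
arbitrary per-stage masks available as `custom`.

## Network

The backbone keeps a high-resolution branch throughout and adds a parallel
half-resolution, double-channel branch per stage:

- **Stem**: two 3×3 stride-2 convolutions to 1/4 resolution. The stem is a
  design necessity not fixed by the architecture's published numbers (the
  stated stages start at 1/4 resolution); two stride-2 convs is the
  minimal standard choice.
- **Stage 1**: four bottleneck residual units, conv layout
  (1×1,1,0)–(3×3,1,1)–(1×1,1,0), channels reduced then expanded 4×.
- **Stages 2–4**: basic residual units, (3×3,1,1)–(3×3,1,1), on 2/3/4
  parallel branches; a fusion module after every four basic units; 1, 4
  and 3 fusions in stages 2, 3 and 4.
- **Fusion**: every output branch is the sum of all input branches
  resampled to its resolution — stride-2 3×3 convolutions downward, 1×1
  conv + bilinear upsampling upward, ReLU after summation.
- **Transitions**: each stage's new lowest-resolution branch is created by
  a stride-2 3×3 convolution from the previous lowest branch.
- **Head**: the three low-resolution maps are bilinearly upsampled to the
  high-resolution grid, concatenated with it, mixed by a 1×1 conv+BN+ReLU,
  and projected to K channels by a final 1×1 convolution. The final conv
  is small-initialized (weights ~ N(0, 0.001), zero bias): starting from
  near-zero heatmaps removes a large, uninformative initial error term
  from the MSE and measurably speeds up convergence.

Every convolution is followed by batch normalization; ReLU everywhere
except immediately before residual additions. For the full-size hindwing
configuration (base width 18, 256×256 RGB input) the branch channel counts
are (18, 36, 72, 144) and the head emits (B, 36, 64, 64).

Parameters partition into named groups {stem, stage1…4, head}; the stem is
grouped with stage 1 for freezing (it precedes it and is equally generic),
and the transition convolutions belong to the stage whose branches they
create.

The network, its autodiff, and Adam are implemented in numpy inside the
package (`wingmark.nn`): a tape-based reverse-mode core with exactly the
operations the model needs (im2col convolution, batch norm, ReLU, bilinear
resampling with an exact-transpose backward, concatenation, MSE).
Gradients are validated against central finite differences in the test
suite. This keeps the dependency footprint to the scientific Python stack
and makes every numerical choice inspectable; the cost is throughput,
which the reduced configuration (below) absorbs.

## Heatmap codec

The crop window is the annotation's bounding box expanded to the input
aspect ratio and padded 25% per side (configurable); heatmap cell (i, j)
corresponds to the image point (x₀ + (j+0.5)·s_x, y₀ + (i+0.5)·s_y). The
input is 4× the heatmap resolution (the retained high-resolution stride),
so 256×256 inputs give 64×64 heatmaps.

Encoding places an isotropic Gaussian (σ = 2 heatmap cells by default,
the common choice for 64×64 maps) at the *continuous* landmark position
and normalizes the channel to peak value 1 at the nearest cell. Landmarks
outside the window produce a zero channel and a warning.

Decoding takes the per-channel argmax (row-major first on ties) and
refines it to sub-cell precision. The default refinement fits a
log-parabola through the peak and its two neighbors per axis — exact for
a sampled Gaussian (peak normalization cancels in the log differences) —
so the encode→decode roundtrip is accurate to well under half an input
pixel for landmarks at least 2σ from the window edge. A quarter-cell
shift toward the larger neighbor ("quarter") and no refinement ("none")
are available; the quarter shift alone cannot beat 0.25 cell = 1 input
pixel at stride 4, which is why the parabola fit is the default.
All-zero channels are undecodable: they yield the crop center and a flag.

## Training protocol

Adam (β = 0.9/0.999), batch size 8, 80 epochs; base learning rate 1e-4
dropped to 1e-5 at epoch 40 and 1e-6 at epoch 55 (0-based epochs; a drop
"at epoch e" applies from e's first batch). No data augmentation by
default — an optional horizontal-flip flag exists but is off, keeping
runs exactly reproducible. Loss is the mean squared error between
predicted and target heatmap stacks over all B·C·H·W elements.

The split protocol mirrors sample-size experiments on a 256-specimen
corpus: 80 test specimens drawn first, then 10 training groups for each
size in (1, 3, 5, 10, 50, 100), drawn independently (with overlap allowed
between groups — 10 disjoint groups of 100 cannot exist in a 176-specimen
pool) but always disjoint from the test set. Splits are deterministic in
the seed and serialize canonically.

Frozen groups are excluded from the optimizer entirely, and their batch-
normalization running statistics are pinned (configurable), so a retained
stage is bit-identical after any amount of training — the suite asserts
this exactly, not approximately.

## Synthetic wings

The generator emulates the geometry of a hindwing landmark corpus, not its
photographic appearance. A canonical 36-point template lays the landmarks
along stylized vein paths (margin chain, radial cell, distal tips, medial
chain, cubitus-anal cluster) with the (1, 18) pair spanning the long axis.
Per sample: per-landmark Gaussian jitter (std 0.008 frame units at
baseline), a random affine deformation (rotation ±8°, scale 0.9–1.1,
shear ±0.06, translation ±3%), mapping into the image with an 8% border,
and anti-aliased polyline rendering of the vein segments. Annotations
store the exact post-deformation coordinates — rendering introduces no
annotation error — plus a tight bounding box padded 5%.

Two domains share identical geometry: `source` (high-contrast veins,
clean background) and `target` (low-contrast veins, darker textured
background, extra noise, slight blur), providing a pretrain/fine-tune
domain gap without any external data. Cubitus-anal landmarks get 2.5×
jitter and distal landmarks 2×, and the veins touching them are rendered
at reduced contrast — reproducing qualitatively the hard-landmark
structure of real hindwings, where most morphological variation
concentrates in the cubitus-anal field and distal veins membranize into
traces.

What the generator does *not* emulate: photographic texture, folding
artifacts, specimen damage, illumination gradients, inter-species shape
variation beyond affine + jitter. Passing tests therefore demonstrate the
pipeline's mechanics and the transfer effect under a controlled domain
gap, not field performance on real imagery.

Default image size is 256 px (64 px in the reduced experiments) rather
than the native 4288×2848 of real captures; the crop path is exercised by
generating at any size and letting the codec resize.

## Reduced experiment scale

The full-size study (w18 backbone, ImageNet pretraining, GPU fine-tuning)
is out of desk scale. The shipped experiment uses a reduced configuration
chosen once: base width 8, stem width 16, one bottleneck in stage 1, one
fusion per stage with one basic block per branch, 64×64 single-channel
input, 16×16 heatmaps. Scaled problem sizes: 200 source-domain wings for
pretraining (10 epochs, base lr 1e-3 stepped down ×0.3 at 60% and 85% of
the run), 3 target-domain wings for fine-tuning (80 epochs, same stepped
shape), 30 held-out target wings for evaluation, median over 3 seeds.
With these sizes one full comparison (pretrain + both arms + evaluation)
runs in about half a minute on one CPU core.

The fine-tuning arms differ only in initialization and freezing: TS loads
the pretrained backbone, re-initializes the head and freezes stem+stage 1;
the scratch arm trains the identical architecture from random
initialization with the identical schedule and data. The transfer arm
consistently achieves roughly half the test NME of the scratch arm at
n = 3, qualitatively reproducing the small-sample transfer advantage; the
absolute numbers are not comparable to full-scale results and are not
claimed to be.

The overfit-one sanity check uses the reduced model at 128×128 input
(32×32 heatmaps) with lr 3e-3 dropped to 1e-3 at epoch 60: 80 epochs on a
single wing bring every decoded landmark within 2 image pixels, verifying
the encode–train–decode loop end to end.

## Numerical choices and degenerate inputs

- Coordinates are continuous pixel positions, top-left origin, 0-based
  internally; landmark numbering is 1-based externally. Measurement
  exports with a lower-left origin are converted by y ↦ H − y (an
  involution).
- The visibility flag in annotations is preserved on round-trips and
  ignored by computation (all landmarks on a prepared wing are visible).
- Records missing a bounding box get a tight box around the keypoints
  padded 5% per side.
- Decode ties break to the first maximum in row-major order; log-parabola
  refinement falls back to the quarter shift when a neighbor is
  non-positive and clips offsets to ±0.5 cell.
- A degenerate reference pair (coincident landmarks) raises on direct
  computation and excludes the sample (with a count) during evaluation;
  undecodable channels contribute the crop-center fallback rather than
  being dropped, to avoid biasing small-sample comparisons.
- Group summary spread uses the sample standard deviation (n−1).
- Float32 throughout the network; Adam ε = 1e-8; BN ε = 1e-5, momentum
  0.1.

## Known limitations

- Throughput: the numpy network is 1–2 orders of magnitude slower than a
  GPU framework; the full-size configuration is practical for inference
  and structure checks, not for full-scale training.
- Single instance per image; no multi-wing disambiguation.
- No alternative target encodings (offset maps, integral regression) and
  no PCK/CED metrics — extension points exist at the codec and evaluator
  seams.
- The residual-network baseline used for comparison at full scale is out
  of scope; the backbone interface would admit one.
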