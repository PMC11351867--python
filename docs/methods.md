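# Methods

`cascadeseg` implements a quality-gated, human-in-the-loop cascade for
lesion segmentation on co-registered multi-channel 2D image slices, together
with the evaluation machinery needed to study its workload/accuracy
trade-off. This note records the model, the choices made where the design
was open, and what the synthetic experiments do and do not establish.

## The cascade

For an input slice `x ∈ R^{3×H×W}` (channels: T2W-like, ADC-like,
high-b-value-DWI-like):

1. **Coarse stage.** A U-Net variant `θ_C` produces a two-channel per-pixel
   probability map `p^c = θ_C(x)` (background/foreground softmax) and the
   final decoder feature map `f` (the representation just before the 1×1
   classifier). The encoder has five convolutional blocks with four 2×2
   max-pooling steps (output stride 16). Squeeze-and-excitation units
   (global average pool → two FC layers → sigmoid channel gates) follow
   every encoder/decoder block; embedded-Gaussian non-local attention units
   sit on the two deepest skip connections, where the quadratic cost in
   pixel count is affordable.
2. **Quality regression.** A rejection network `θ_R` maps the channel-wise
   concatenation `cat(f, p^c)` to a scalar score `s` estimating the Dice
   coefficient the coarse mask would achieve against ground truth. The
   regression head is three fully connected layers (ReLU between, final
   width 1); the output is linear during training and clamped to [0, 1] at
   inference only, so the MSE training objective is unchanged.
3. **Gate.** A threshold `t` routes each slice: `s < t` (strictly) → manual
   bounding-box input; `s ≥ t` → automatic boxes, one per 8-connected
   component of the binarised coarse mask. The boundary score stays
   automatic. The *rejection ratio* — the fraction of slices routed to
   manual input — is the human workload of a run.
4. **Fine stage.** Every box is expanded by 40% (20% per side, edges
   rounded outward and clipped) and fed with the image to a box-prompted
   segmenter `θ_F`; per-box masks are unioned into the final segmentation.
   Manual interaction is simulated from ground truth: the tight box of each
   ground-truth component, expanded by the same 40%.

Training is stage-wise: `θ_C` with soft Dice loss; then, with `θ_C` frozen
(verified bitwise), `θ_R` with MSE against Dice targets recomputed from the
frozen coarse predictions each epoch; then `θ_F` with binary cross-entropy
plus Dice, prompted by ground-truth boxes jittered per epoch (expansion
uniform in [0, 60%], each corner shifted by an integer uniform in
[−20, 20] px, repaired to a minimum 2×2 box).

## Numerical and design choices

- **No GPU runtime exists in the target environment**, so the networks are
  built on a small numpy reverse-mode autodiff layer private to this
  package (`cascadeseg._nn`): im2col convolutions via BLAS matmuls,
  deterministic max-pooling tie-breaks (first maximum), float32 throughout.
  Gradients of every op are verified against central differences in the
  test suite.
- **Desk-scale profiles.** The full-scale regime (256×256 inputs, base 64
  channels, EfficientNet-class rejection backbone, 150–200 epochs, Adam
  lr 1e-3 / backbone 1e-4 with polynomial decay power 0.9) is expressed in
  the configs; tests and the acceptance script run desk-scale profiles:
  64×64 slices, base 8 channels, a four-stage conv backbone for the
  rejection network with head widths (64, 32, 1), and ≤16 epochs per stage.
  The desk-scale learning rate is 3e-3 for the segmentation stages: the
  much smaller networks and cohorts tolerate and need it.
- **Instance normalisation** follows every 3×3 convolution. With no
  normalisation the desk-scale nets train an order of magnitude slower.
- **Classifier bias initialisation** at (+2, −2) (background, foreground)
  starts both segmentation nets near the background prior. Lesions occupy
  a few percent of pixels; from the uniform 0.5 start, Dice loss suppresses
  the background excruciatingly slowly, and this one-line prior fixes it.
- **Dice loss smoothing** ε = 1e-5 in numerator and denominator keeps the
  loss defined on lesion-free slices (which stay in coarse training; real
  cohorts contain them).
- **Checkpoint selection.** Coarse and prompt stages keep the epoch with
  the highest validation mean DSC *over lesion-bearing slices*; with the
  both-empty-masks-score-1 convention, an all-background net would
  otherwise win on cohorts dominated by lesion-free slices. The rejection
  stage keeps the lowest validation MSE.
- **Prompt encoding.** The built-in fine segmenter takes a fourth input
  channel rendering the box interior, rather than coordinate embeddings —
  the simplest faithful conditioning for an axis-aligned box at this scale.
  The box channel is re-injected (max-pooled) at every encoder stage, and
  training adds negative samples (a box over a lesion-free region paired
  with an empty target): both are needed for the net to actually *use* the
  prompt — with a single visible lesion per slice, image contrast alone
  predicts the target and a small net otherwise learns to ignore the box.
  Prompt respect is asserted on the binarised output (less than 20% of
  predicted-foreground pixels escape the expanded box); the soft
  probability mass is not a usable measure here because the softmax floor
  spreads tiny probabilities over thousands of background pixels.
  Its `freeze_policy` supports the frozen-encoder/trainable-decoder regime
  used when adapting a pretrained promptable model; the built-in net has no
  pretrained encoder, so its default policy trains all parameters.
  An adapter hook for an external SAM-style backend exists but requires
  external weights and runtimes; it raises a explicit error without them
  and is excluded from the core suite beyond its error contract.
- **Gate threshold domain.** Scores live in [0, 1]; `GateConfig` accepts
  thresholds above 1 as an explicit "route everything manual" limit so the
  sweep can realise both endpoints of the rejection-ratio curve.
- **Metrics.** DSC uses both-empty = 1, one-empty = 0. The 95% Hausdorff
  distance takes boundary pixels (mask pixels with a 4-neighbour outside
  the mask; image borders count as outside), computes both directed
  nearest-neighbour distance sets in physical units, and returns the 95th
  percentile (linear interpolation) of their union — symmetric by
  construction; undefined (NaN, excluded and counted) when either mask is
  empty. Lesion-level recall/precision treat lesions as 3D 26-connected
  components across a patient's slice stack: a ground-truth component is
  detected when its summed overlap fraction with the predicted
  segmentation reaches τ = 0.1 (low, reflecting inter-observer variability
  in lesion delineation); predicted components are scored symmetrically for
  precision; counts pool across patients before rates are formed, and
  volumes with no components contribute no denominators.

## The phantom generator

The synthetic cohorts stand in for multiparametric prostate MRI. Each
patient has an elliptical gland-like region with smooth low-frequency
texture; lesions are ellipse-like blobs whose radius is modulated by two
low-frequency angular harmonics (amplitude ≤ 0.25), giving the irregular,
ambiguous boundaries the cascade targets. Lesions extend over 1–4
contiguous slices with an ellipsoid-like radius profile so lesion-level 3D
metrics are meaningful. Channel contrasts are signed — the ADC-like channel
is dark (−0.40), the DWI-like channel bright (+0.50), the anatomy channel
mildly positive (+0.20) — and scale with `1 − difficulty`; Gaussian noise
(σ = 0.08) is added per channel. Per-patient difficulty is a shuffled even
grid over [0.02, 0.98], so every cohort spans the full range from trivially
segmentable to essentially invisible lesions; this is precisely the
heterogeneity the rejection network must rank. Splits are assigned per
patient (never per slice), with sizes matching the requested fractions to
within rounding. Identical seeds give bit-identical cohorts.

What the phantoms do **not** emulate: anatomical zonal structure, MR
physics (bias fields, coil profiles, Rician noise), inter-sequence
misregistration, and realistic lesion texture. A green end-to-end test
therefore establishes that the cascade, gating and evaluation machinery
behave correctly and that quality regression is learnable when coarse
quality varies — not that any particular clinical accuracy is attainable.

## What the acceptance checks establish

1. Published lesion-level F1 values are reproduced from their printed
   recall/precision by the package's harmonic-mean implementation, and the
   published gating-improvement deltas follow from the printed means. (One
   published row, TPR 75.0 / PPV 42.1 / F1 55.1, is arithmetically
   inconsistent with the F1 formula and is not asserted.)
2. The 95% HD implementation agrees exactly with a brute-force all-pairs
   oracle (including the percentile step) on hundreds of random mask pairs.
3. At `t = 0` the cascade is the fully automatic pipeline; above the
   maximum score it is the fully manual-prompt pipeline; the rejection
   ratio is a monotone step function of `t` with endpoints 0 and 1.
4. On a 40-patient mixed-difficulty desk-scale cohort: held-out
   quality-regression R² ≥ 0.5; mean final DSC at `t = 0.7` is at least
   that of the fully automatic run; and mean DSC correlates positively
   (Spearman) with `t` across a six-point grid — the qualitative
   workload/accuracy trade-off.

## Known limitations

- Slice-based only; no 3D context in any network.
- The numpy autodiff layer is single-threaded apart from BLAS and is meant
  for desk-scale problems; full-scale profiles would need hours per stage.
- Manual interaction is simulated from ground truth; the interactive
  provider is a callback interface only.
- The external SAM-style adapter is an untested integration point by
  design (no weights, no GPU runtime in the build environment).
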