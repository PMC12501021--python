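# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Enhancement

The adaptive average filter computes, per pixel,

```
I'(i,j) = μ_L(i,j) + clamp((σ_L²(i,j) − σ_N²) / σ_L²(i,j), 0, 1) · (I(i,j) − μ_L(i,j))
```

with `μ_L`, `σ_L²` the mean and population variance over a `w×w` window
(default `w = 7`, odd, configurable) and `σ_N²` the assumed noise variance.
The clamp is our addition: the raw ratio is undefined at `σ_L² = 0` and
negative when the local variance falls below the noise floor; clamping to
[0, 1] makes those pixels smooth fully to the local mean, which is the
filter's intent, and makes the output a convex combination of the pixel and
its window mean (so outputs stay inside the local min/max — a tested
invariant). `σ_N²` is rarely known, so by default it is estimated as the
**median of the local-variance map**: local variance is inflated around
lesion structure in only a minority of windows, so the median tracks the
flat-skin noise floor (verified on noisy constants to within 15% at
256×256, w=7). A fixed value can be supplied instead.

Sharpening convolves the smoothed image with a 3×3 Laplacian (8-neighbour
centre −8 by default; 4-neighbour selectable) and **adds** the signed
response to the smoothed image before clipping to [0, 255]. The additive
fusion is deliberate (rather than the classical `I − ∇²I` subtraction
form); with the centre-negative kernels it darkens edge cores and brightens
their flanks, and the clip keeps the result a valid intensity image. All
window operations use edge-duplicating reflection padding so borders do not
manufacture gradients.

## Hair removal

Hairs are thin, dark, elongated. Grayscale closing with a linear structuring
element fills any dark structure narrower than the element, so the residual
`closed − original` is large exactly on hair pixels. The detector closes the
luminance image with a length-17 line at 8 orientations (0°…157.5°),
takes the per-pixel maximum over orientations, thresholds the residual
(Otsu by default; a fixed threshold is available for reproducible tests),
and dilates the mask by a 1-px disk to cover hair fringes. SE length and
orientation count are configurable; the defaults follow standard
razor-style practice for dermoscopy at this resolution. The residual is
invariant to global additive intensity shifts (closing commutes with them),
which the tests assert.

One honest caveat: the closing residual also fires on high-curvature tips
of small, high-contrast lesions, where no 17-px chord fits inside the
lesion. That is a property of the method, not a bug; at ISIC-style
resolutions lesions are large relative to the SE and the effect is
marginal.

Inpainting replaces each masked pixel by the inverse-Euclidean-distance
weighted mean of non-hair pixels, growing the square search window until at
least `inpaint_min_neighbors` (default 4) donors are available. Unmasked
pixels are never modified (exact equality, tested). RGB policy: enhancement
per channel, detection on Rec.601 luminance, inpainting per channel under a
shared mask.

## Balancing

For target `T ≈ 8000` (the dominant nevus class size), each class gets an
integer factor `F_c = max(1, round_half_up(T / N_c))`, with `F_c = 1` for
any class already at or above the target. Round-half-up reproduces the
published factors for six of the eight inventory rows; the VASC row prints
factor 52 where the rule gives 49, so the planner accepts per-class
overrides, and the BCC row of that table is internally inconsistent
(212 × 64 ≠ 8504) — we do not attempt to reproduce it. The planner is
label-set agnostic. Augmentations (flips, rotation ≤ ±30°, zoom 0.9–1.1,
photometric factors 0.8–1.2 — ranges are our defaults, chosen to stay
clinically plausible) preserve label, dtype range and canvas size; every
augmented image records its parent id, and materialisation is a pure
function of the seed.

## The hybrid model

**Patch branch.** Images are resized to 600×450 and tiled into 30×30
patches (300 tokens); patchify itself never resizes and refuses
non-divisible inputs. Tokens are linear projections of flattened patches
plus a fixed sinusoidal positional table with **frequency base 1000** —
a deliberate departure from the conventional 10000, kept as a parameter.
Sines occupy even columns, cosines odd. The embedding width D defaults to
256, matching the SDEB output width so the token stream is dimensionally
consistent.

**SDEB.** Three parallel convolutions over the token grid
(3×3/64, 5×5/128, 7×7/256, ReLU each) capture fine, meso and large-scale
structure. An element-wise sum of maps with different channel counts is not
defined, so each branch passes through a 1×1 projection to the common width
C = 256 before summation; a final ReLU(Conv1×1, C) fuses the sum. The token
sequence is reshaped onto its (rows × cols) grid for the convolutions and
flattened back afterwards. Spatial dims below the 7×7 kernel are rejected.

**Encoder.** Six blocks (configurable) of pre-LN attention with residual,
post-LN, and a residual GELU MLP (hidden = 4·D). Residual connections are
not optional extras: at depth six they are what keeps gradients usable, and
with attention/MLP weights zeroed the stack collapses to iterated
layer normalisation — a closed form the tests check. LayerNorm carries no
learned affine by default (`(x − μ)/√(σ² + ε)`, ε = 1e−6). Heads default to
8 over D/heads slices. Token count is constant through the stack; an
optional learned token-upsampling stage (linear mix along the token axis,
doubling per block) exists but is off by default since no concrete growth
mechanism is specified for the "token count increases" idea.

**CNN branch.** A declarative stage table builds the backbone. The pruned
variant uses a 3×3/32 stride-2 stem, dense blocks of 6/12/16 layers, and
drops dense block 4; the reference variant is the standard DenseNet169
feature extractor (7×7/64 stem, blocks 6/12/32/32). Unstated details follow
DenseNet convention: growth 32, BN-ReLU-Conv with 4·growth bottlenecks,
transition compression 0.5, global average pooling at the end. This is a
reconstruction: it yields ≈ 12.5 M parameters for the reference features
and ≈ 3.25 M for the pruned variant. Published per-stage totals for the
same pruning (~7.35 M vs ~14.3 M) are approximate and not reproducible from
the stated stage list under any standard growth/bottleneck combination; we
document the discrepancy rather than tune toward it. The tested claim is
the structural one: the pruned variant carries well under half the
parameters (measured fraction 0.26).

**Fusion and head.** The flattened branch vectors differ in length
(300·256 = 76 800 vs 380), so element-wise addition is made well-defined by
per-branch linear projections to a shared fusion dimension (default 1024) —
the minimal change that types the sum. The head is LayerNorm → dropout →
dense → dropout → dense(7) → softmax; dropout defaults to 0.1 and is
disabled in eval mode, making inference deterministic.

**Training harness.** Adam + categorical cross-entropy, explicit seeds for
weight init, dropout and batch order. The harness is plumbing for
desk-scale verification, not a claim about how the full-scale system should
be optimised.

## Synthetic data

The generator renders one elliptical lesion (boundary perturbed by three
low-frequency harmonics) on a skin-toned background with Gaussian pixel
noise, plus optional dark curved hair strokes (quadratic Bézier polylines,
1–3 px thick) whose exact raster support is returned as ground truth. The
seven classes occupy disjoint HSV hue bands, and the dataset generator
holds lesion area in a narrow band (25–35% of the canvas) so class identity
is carried by colour rather than size; a mean-RGB nearest-centroid
classifier separates the classes at ≥ 95% by construction. This
separability is what the smoke-training check leans on: reaching ≥ 90%
training accuracy shows the gradient path and the fusion wiring are
correct, not that the architecture ranks well on real dermoscopy. Real
lesions differ in essentially every hard way — texture, hue overlap between
classes, imaging artefacts, calibration drift — so passing tests here
validate mechanics, never clinical performance.

## Metrics

One-vs-rest TP/FP/FN/TN bookkeeping gives precision, sensitivity,
specificity and one-vs-rest accuracy per class (percentages; zero
denominators yield NaN, never exceptions). Published per-class "accuracy"
figures in this area track per-class recall (row-diagonal over row total),
so that quantity is exposed separately as `class_accuracy`; both columns
are labelled explicitly. Overall rows are unweighted macro means rounded to
two decimals; micro accuracy (trace/n) is reported alongside because
sources rarely say which they used. ROC-AUC is the rank statistic
(ties count ½) — the occasionally printed "TPR/FPR" ratio is exposed
verbatim as `tpr_fpr_ratio` but is not an AUC and is not used as one.
McNemar's test offers the continuity-corrected χ² closed form
`(|b−c|−1)²/(b+c)` and an exact two-sided binomial variant; "auto" uses the
exact form when b + c < 25. A pooled two-proportion z-test is provided for
rate comparisons between models evaluated on different samples.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale as a
design choice: 32×32 canvases, 4×4 patches (64 tokens, D = 16), two encoder
blocks and a small dense-block stack for training (n = 70, ≤ 50 epochs);
96×96 canvases for hair-removal checks; one full-size pruned-backbone
forward at 224×224 and the full parameter accounting at real size. All
randomness flows through explicit `numpy.random.Generator` seeds, so every
reported number is reproducible bit-for-bit for a fixed seed.

## Known limitations

- Full-scale dermoscopy results (accuracy ≈ 97% territory on ISIC 2018)
  require GPU training on the real archive and are out of scope; nothing
  here estimates them.
- The autodiff core implements exactly the op set these models need; it is
  not a general-purpose framework (no broadcasting matmul beyond the used
  cases, no mixed precision, single-threaded conv via im2col).
- The inpainting is local weighted averaging; exemplar- or
  diffusion-based filling is explicitly out of scope.
- The balancing table's BCC row cannot be reproduced from its own
  arithmetic (see above); it is excluded from reproduction targets.
- Statistical comparisons (McNemar, z-test) reproduce method behaviour on
  constructed inputs; reproducing a specific published significance table
  would require the original per-sample predictions, which are not
  available.
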