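# Methods

## Problem and pipeline

HER2 status in gastric cancer is graded on immunohistochemically (IHC)
stained whole-slide images: a pathologist scores the slide 0, 1+, 2+ or 3+
from the intensity and completeness of brown (DAB) membrane staining in
tumor cells, where a pattern must appear in more than 10 % of tumor cells to
count. 0/1+ read out as clinically negative, 2+ as equivocal (reflexed to
FISH), 3+ as positive.

`her2quant` automates this in two stages:

1. **Tile-level classification (TLCN).** The slide is cut into 256×256-px
   tiles by a non-overlapping sliding window and every tile is assigned one
   of six classes — the four HER2 scores plus `normal` (non-tumor tissue)
   and `noise` (blank glass, blur, folds). No tumor segmentation or
   cell-level annotation is used; artifact and non-tumor content is handled
   purely as two extra classes.
2. **Slide-level score prediction (WHSPN).** The proportions of the four
   scored classes among tiles predicted as scored classes form a
   4-dimensional vector p = (p₀, p₁₊, p₂₊, p₃₊), Σp = 1. A small learned
   model (polynomial-kernel SVM or a four-layer MLP) maps p to the slide
   score, so the >10 % decision boundary is learned from data rather than
   hard-coded.

## The re-parameterizable backbone

The tile classifier is a VGG-style chain of 22 3×3 convolution layers in
five stages (depths [1, 2, 4, 14, 1], widths [48, 48, 96, 192, 1280], stride
2 on the first layer of each stage), global average pooling and a linear
six-class head. A 256×256 input reaches an 8×8 map before pooling. The
depths/widths are fixed by the package as the configuration whose closed-form
parameter arithmetic reproduces all published size figures of the
architecture family (7.031/7.036/7.045/7.049/7.316/7.836/7.849 M for the
respective variants).

During **training** each layer is an enhanced convolution module (ECM):
three parallel branches — 3×3 conv + BN, 1×1 conv + BN, and (when stride is
1 and channels match, i.e. in 17 of the 22 layers) identity + BN — summed,
then optional channel attention, then ReLU. Convolutions carry no bias; the
per-branch BN absorbs it.

At **deployment** every block is collapsed into a single 3×3 convolution
with bias by exact algebra:

* conv+BN fusion: K′ = K·γ/σ, B′ = (B − μ)·γ/σ + β, with σ = √(running
  variance + ε), ε = 1e-5, per output channel;
* the 1×1 kernel is zero-padded into the centre of a 3×3 kernel;
* the identity branch becomes a Dirac 3×3 kernel fused with its BN;
* branch kernels/biases are summed (linearity of convolution).

This is an identity transformation, not an approximation: the test suite
checks logit agreement between the training network (inference mode) and its
fused network for arbitrary random weights and inputs at 1e-4 (float32) and
1e-9 (float64) max-abs — the float32 allowance reflects accumulation-order
differences only. Channel attention sits outside the branch sum (applied to
the block output, before ReLU), so its parameters pass through fusion
untouched; where exactly ReLU sits relative to attention is an open design
point and this package fixes it as sum → attention → ReLU.

### Channel attention

*GCT* (gated channel transformation) computes per channel an l2 embedding
s_c = α_c·√(Σ_{h,w} x² + ε), normalises it across channels
ŝ_c = s_c·√C/√(Σ_c s_c² + ε), and gates with 1 + tanh(γ_c·ŝ_c + β_c).
With the standard initialisation α = 1, γ = β = 0 the gate is exactly 1, so
a GCT-augmented network starts as its plain counterpart. ε = 1e-5 guards
both square roots. GCT adds 3 parameters per channel (13,488 over the full
network).

*SE* (squeeze-and-excitation) pools each channel globally, passes the C
statistics through a biased bottleneck C → C/r → C (r = 16) with ReLU, and
gates with a sigmoid, so gates lie strictly in (0, 1).

### Parameter accounting

`count_params` enumerates learnable arrays: conv kernels, conv biases
(deploy mode), BN scale/shift (training mode; running statistics are
buffers, not parameters), attention parameters, head weight/bias. The chain
baseline used for ablation parity has neither bias nor BN. The test suite
checks this enumeration against an independent closed-form layer-by-layer
sum for every (mode, attention, arch) combination.

## Training recipe

SGD with momentum 0.9, initial learning rate 0.1, weight decay 1e-3, batch
256, 200 epochs, cross-entropy loss, cosine decay of the learning rate to
zero. Momentum and the cosine schedule are the package's choices (the
de-facto standard for this optimizer family); the remaining values are the
reference recipe. The checkpoint with the best validation accuracy is
returned (ties keep the earliest epoch). Splits are drawn at tile level in
an 8:1:1 ratio; source-slide ids are retained so slide-level splitting
remains available. Monte-Carlo cross-validation redraws the split, retrains
from scratch and reports mean ± population standard deviation per metric
(default 5 rounds).

All tensor computation is NumPy: convolutions are lowered to im2col/col2im
matrix products (with a direct fast path for 1×1 kernels), and every layer
implements an explicit backward pass that the test suite verifies against
central finite differences at 1e-6 relative tolerance. Training is
bit-reproducible given its seed; the only randomness is weight
initialisation and epoch shuffling.

## Evaluation metrics

Per class, one-vs-rest: accuracy (TP+TN)/(TP+TN+FP+FN), precision
TP/(TP+FP), recall TP/(TP+FN), specificity TN/(FP+TN), and F1 as the
harmonic mean of precision and recall. Headline values are unweighted
(macro) averages — the averaging scheme is the package's choice — and
overall accuracy (trace over total) is reported alongside. Zero-denominator
cases are defined as 0 with a warning rather than NaN so repeated-split
aggregation never propagates NaN. The clinical merge (0/1+ → Negative,
2+ → Equivocal, 3+ → Positive) is a deterministic relabeling; because it
only collapses 0 with 1+, three-class accuracy is provably ≥ four-class
accuracy on the same predictions.

## Synthetic data: what it emulates and what it does not

No public gastric HER2 IHC dataset exists at the granularity this pipeline
needs, so the package ships a generator used by all end-to-end tests.

Tiles are rendered directly in RGB (no stain-deconvolution model, since the
classifier consumes RGB): an eosin-pink background, cells with hematoxylin-
purple nuclei, and brown membrane rings whose intensity and completeness
are drawn from class-conditioned ranges — intensity ≈0 (score 0), 0.10–0.25
(1+), 0.35–0.55 (2+), 0.70–0.95 (3+); completeness 0.25–0.45 / 0.60–0.80 /
0.90–1.00 for 1+/2+/3+. The intensity ranges are disjoint by construction,
which makes the task well-posed at desk scale: a plain mean-brown-intensity
threshold already separates the four scored classes (checked at ≥ 0.95 on
400 tiles). `normal` tiles render sparse small cells without membrane
staining; `noise` tiles render blank glass, defocus blur, or fold streaks.
Identical seeds give bit-identical images.

Synthetic slides are tile mosaics drawn from a class mixture; ground truth
follows the clinical >10 % rule transposed from cells to tiles: the score is
the highest class among {1+, 2+, 3+} whose share of the *tumor* tiles
exceeds 0.10, else 0 (applied to realized tile counts, via largest-remainder
apportionment of the mixture). Slide-score training vectors are sampled
class-balanced on the simplex conditioned on that rule.

What passing these tests shows: the architecture, fusion algebra, training
loop, aggregation and scoring rule recovery all work end to end. What they
do not show: performance on real histology — the generator has no nuclear
pleomorphism, stromal texture, stain variability between labs, basolateral
(incomplete-by-pattern) staining, or scanner artifacts beyond the three
noise archetypes, so accuracies on synthetic data say nothing quantitative
about clinical accuracy.

## Scaled-down study sizes

The end-to-end acceptance test miniaturises the study to desk scale: 600
tiles (100 per class, 480/60/60 split), backbone widths [8, 8, 16, 32, 64]
with the full depth profile, batch 32, learning rate 0.05 (the reference
0.1 is calibrated to batch 256; the smaller batch takes a proportionally
smaller step), 8 epochs, seed 7. The slide scorer is trained on 200
rule-labeled vectors and evaluated on 100 fresh ones, for both SVM
(poly kernel, γ = 10, C = 2, degree 3, coef0 = 0 — degree and coef0 are
library defaults, unspecified in the reference recipe) and MLP
(4 → 32 → 16 → 8 → 4; "four fully connected layers, each followed by ReLU"
is read as ReLU on the hidden layers only, since a ReLU on the output would
clip logits; hidden widths are the package's choice of the smallest
standard funnel; full-batch momentum SGD with cosine decay, lr 0.1, 1000
epochs — full-batch gradients on ≲200 vectors are cheap and the smaller
step sizes typical of minibatch training leave this funnel underfit).

## Numerical choices and degenerate inputs

* BN: biased batch variance for normalisation and the running average;
  momentum 0.1; ε = 1e-5. Fusion uses inference-mode (running) statistics
  and rejects non-positive standard deviations.
* Argmax ties (tile class and slide score alike) break toward the lowest
  class index in the canonical order (0, 1+, 2+, 3+, normal, noise).
* Slides smaller than one tile yield an empty grid with a warning; slides
  whose tiles are all predicted normal/noise yield an *unscorable* record,
  not an exception; proportion vectors are validated to sum to 1 ± 1e-6
  before scoring.
* Partial edge windows are dropped (stride = tile size = 256); tiles are
  taken at the raster's native resolution.

## Known limitations

* No stain normalisation, no overlap-and-vote tiling, no tumor-region
  segmentation (by design — the pipeline avoids manual intervention).
* The 2+ (equivocal) output is a triage verdict; FISH confirmation is
  outside the software.
* Monte-Carlo cross-validation at full scale (200 epochs, batch 256) is
  computationally out of reach of the NumPy backend; it is exercised at
  reduced scale.
* The SVM scheme offers no calibrated probabilities; use the MLP scheme
  where per-score confidence is needed.
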