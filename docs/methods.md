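# Methods

## The model

`vesselseg` implements a U-shaped shifted-window transformer for binary
retinal-vessel segmentation, extended with three boundary-oriented
components: cross-level texture fusion of the encoder pyramid (CTCM),
pixel-wise texture highlighting in the decoder (PTHM), and a clip-truncated
Hausdorff term in the loss.

**Backbone.** The input image (H×W×3, values in [−1, 1]) is cut into 4×4
patches, giving an (H/4)×(W/4) grid of 48-dimensional tokens, which a linear
embedding projects to C channels. Three encoder stages operate at 1/4, 1/8
and 1/16 scale with C, 2C and 4C channels; patch merging (2×2 neighbor
concatenation + linear reduction) moves between scales. Each stage is a
sequence of block *pairs*: a window-attention block followed by a
shifted-window block (shift = ⌊window/2⌋, cyclic shift with an attention
mask across wrap-around boundaries, learned relative-position bias per
head). Blocks are pre-norm residual: `x + WMSA(LN(x))` then `x + MLP(LN(x))`
with a GELU MLP of ratio 4.

**CTCM.** The encoder pyramid (F1, F2, F3) is fused at the finest scale:
all three maps are projected to 4C channels by independent 1×1 convolutions,
F2 and F3 are upsampled 2× and 4× (bilinear by default), and two difference
maps Fδ1 = F1′ − F3^{4×}, Fδ2 = F2^{2×} − F3^{4×} capture texture lost in
downsampling. The weighted concatenation [αFδ1 ; βFδ2] passes through two
conv→ReLU→2×2-average-pool blocks (8C→4C→4C) back to 1/16 scale and is added
to F3 residually. Average pooling (not max) keeps recovered texture from
being discarded. α = β = 1 by default; the output always has F3's shape.

**PTHM / PT Swin block.** Per decoder feature map Fin: pixel-normalize
(divide each pixel's channel vector by its RMS, ε = 1e-8), take the
per-channel Sobel gradient magnitude, add it to Fin (Z), blur with a 3×3
Gaussian (σ = 0.8, kernel renormalized to sum 1) to get the gate G, gate
V = G ⊙ Fin, and blend Fout = Conv1×1([V ; Fin]) back to C channels. Sobel
and blur use reflective padding so image borders do not read as edges. The
PT Swin block applies this chain before its attention pair by default
("enrich locally, then mix globally"); an "after" placement is available for
ablation, as are flags that disable CTCM/PTHM entirely, reducing the network
to the plain Swin-UNet-style baseline.

**Decoder / head.** From the CTCM output: PT block at 1/16 scale → 2× patch
expand → concatenate skip F2, linear-reduce → PT block → 2× expand →
concatenate F1, reduce → PT block → 4× final expand → per-token linear head
producing NC = 2 logits per pixel. Forward emits raw logits; losses and
metrics apply their own activations.

## The loss

Total objective: `(ω1·CE + ω2·Dice + ω3·ClipHaus) / (ω1+ω2+ω3)` with
ω = (10, 10, 1). CE is the mean per-pixel negative log-likelihood; Dice loss
is 1 − Dice with smoothing 1e-5, averaged over classes.

The clip-truncated Hausdorff term bounds each directed distance by
`eps = sqrt(H² + W²)/NC` so the large background cannot dominate the thin
vessel class. As printed in its source formulation the directed term uses
*squared* Euclidean pixel distances while the cap is a linear diagonal
length; the package implements the squared form faithfully
(`haus_distance="squared"`) and exposes a `"linear"` variant. Empty-set
policy: both foregrounds empty → 0, exactly one empty → eps.

Two routes exist and are kept separate by design:

* **Exact route** (`clip_haus_loss`): set-based, used for evaluation and as
  the oracle in tests (verified against an exhaustive pairwise brute force).
* **Differentiable surrogate** (`soft_clip_haus`), used in training. The
  P→G direction smooth-maximizes `p_i · min(d_G(i)², eps)` over pixels,
  where d_G is the Euclidean distance transform of the reference foreground;
  the G→P direction smooth-maximizes `(1−p_i) · min(d_P̂(i)², eps)` over
  reference pixels against the transform of the thresholded prediction
  (recomputed each step, no gradient through the transform). The two
  directions combine via `a + relu(b − a)`.

Numerical choices in the surrogate, each of which mattered in practice:

* **Smooth max = Boltzmann operator** (softmax-weighted mean), not plain
  log-sum-exp: LSE carries a `+τ·log(n)` offset (n ≈ 5·10⁴ pixels) that
  breaks the exact-reduction property on hard masks; the Boltzmann operator
  is exact on constant inputs and approaches the hard max as τ → 0.
* **Temperature** defaults to τ = 0.05·eps ("auto"). On the squared-distance
  scale (0…eps ≈ 158 for a 224-px image) a fixed τ = 1 is numerically a hard
  max: only the single worst pixel receives gradient per step, which probes
  showed leaves whole populations of distant false positives untouched.
  Tests pass τ = 1e-3 explicitly where the hard-max reduction is asserted.
* **Detached weights**: the Boltzmann weights are constants in backward.
  Differentiating through them multiplies each offender's gradient by
  `w_i(1 + (a_i − smax)/τ)`, which is *negative* for offenders below the
  soft max — pushing mid-tier false positives upward. With detached weights
  the gradient is a nonnegative weighted average of descent directions.
* **Normalization in the total objective** (`haus_normalize`, default on):
  inside the ω-weighted sum the surrogate term is divided by ε, making it
  dimensionless in [0, 1] like the CE and Dice terms. The raw term has
  magnitude up to ε (≈158 for a 224-px image) concentrated on a few
  worst-offender pixels — a per-pixel gradient thousands of times larger
  than CE's — and in training probes it overwhelmed the pixel losses under
  every mitigation tried (temperature spreading, weight warmup, global
  gradient clipping). Dividing by ε preserves the cap's intent (a scale
  that adapts to image size) while making the three loss terms commensurate.
  Logs and the `clip_haus` entry of the loss parts still report the raw,
  unnormalized value.
* **Empty-prediction penalty**: the directed P→G term adds
  `eps·(1 − softmax-sharp-max(p))`. On hard masks this reproduces the
  empty-set policy exactly; on soft maps it gives an all-background
  prediction a restoring gradient (a plain constant eps made all-background
  a stationary point of the term, observed as early-training collapse).

## Training

SGD with momentum 0.9, weight decay 1e-4, batch size 2, polynomial decay
`lr = lr0·(1 − epoch/max_epoch)^0.9` with lr0 = 0.01 and max_epoch = 200 as
full-scale defaults. One integer seed drives weight initialization,
shuffling, augmentation (independent 0.5-probability horizontal/vertical
flips) and phantom generation; runs are bit-reproducible.

Initialization is truncated normal (std 0.02) with zero biases, with two
refinements that matter on short schedules: residual-branch *output*
projections (the attention projection and second MLP layer) use a smaller
std (default 0.005) so every transformer block starts near the identity,
and the training loop starts the segmentation head's bias at the empirical
class-prior logits, so the initial prediction matches base rates instead of
50/50 — without this, heavily imbalanced training spends its first epochs
collapsing to all-background and then recovering.

Two optional stabilizers for the Hausdorff term on short schedules (both
off by default, i.e. the nominal protocol): a linear warmup of ω₃ over the
first K epochs (`haus_warmup_epochs`), and a global gradient-norm clip
(`grad_clip`). The surrogate's gradient concentrates magnitude ~ε on a few
worst-offender pixels — thousands of times a per-pixel CE/Dice gradient —
which a 200-epoch schedule amortizes but a 30-epoch one does not.

A configurable fraction of the
training set (default 20%) is held out to select the best checkpoint by F1;
the last checkpoint is always written too. Per-epoch logs record lr and each
loss term separately so the ablation switches are auditable.

## Preprocessing

Resize to the model size (bilinear for images, nearest for masks/FOV so
binarity is preserved) → CLAHE on the L channel of Lab (scikit-image
parameterization: clip limit 0.02, 8 tiles per side) → gamma 1.2 → linear
map of 8-bit values to [−1, 1] via x/127.5 − 1. Enhancement runs on 8-bit
intensities before normalization; resize comes first to bound compute.
CLAHE/gamma parameter values are conventional fundus-processing choices and
are config-exposed.

## Synthetic phantoms

`vesselseg.phantom` renders fundus-like images with exact ground truth: a
circular field of view (radius 0.46 of the side) on a dark frame, a radially
shaded background (mean 0.55, brighter centrally), a binary tree of straight
anti-aliased vessel segments starting on the FOV rim (root width 6 px,
width ×0.75 per generation floored at 1 px, branch half-angle ≈0.55 rad,
segment length ×0.78 per generation, contrast fading ×0.92 per generation
from a root vessel mean of 0.25), and Gaussian noise with σ = 8/255.
Defaults give a vessel fraction of ~7–8% of the image, matching the
vessel-to-FOV area ratio of real fundus data. Randomness is keyed per tree
node, so the depth-d phantom is a strict subtree of the depth-(d+1) phantom
for the same seed, and the foreground is a single connected component by
construction.

What the phantoms do **not** emulate: optic disc and macula, vessel
tortuosity and crossings, central reflex, pathology, inter-image color
variation. Tests passing on phantoms therefore demonstrate that the
architecture, losses and pipeline are implemented correctly and can learn
vessel-like structure — not that the model reaches any particular accuracy
on real fundus photographs.

## Problem sizes used in tests and the acceptance script

Unit tests exercise the network at 64 px with an 8–12-channel embedding and
window 2 (the smallest geometry that visits all three scales). The learning
smoke test and `scripts/acceptance.py` train the full model (all components
enabled) on 8 phantoms at 224 px for 30 epochs with embed_dim 32, depths
(1,1,1), heads (2,4,8), window 7 — a deliberately small configuration chosen
so a complete training run is a few minutes on one CPU core. Its training
protocol is the scaled-down counterpart of the full-scale recipe: batch size
1 (240 optimizer steps), initial lr 0.05 on a 60-epoch decay horizon of
which the first 30 epochs are trained (annealing all the way to zero within
30 epochs measurably hurt the final fit), Hausdorff weight warmed up over
5 epochs, and augmentation off (the run is an overfit-capacity check; flips
trade training fit for invariance). The full-scale defaults (448 px, C = 96,
depths (2,2,2), heads (3,6,12), batch 2, lr 0.01 over 200 epochs, flips on)
remain the package defaults for real training.

For reference, the smoke-scale phantoms admit a best-case *per-pixel
intensity threshold* F1 of about 0.83 (anti-aliased boundary pixels are
intrinsically ambiguous from single-pixel intensity); the trained network
exceeds this by using spatial context, and ~90% of its residual errors lie
within one pixel of the true vessel boundary.

## Known limitations

* CPU-only: a full-scale 448-px, C = 96 training run is computationally out
  of reach of this implementation; the package targets correctness,
  verifiability and small-scale experimentation.
* The Hausdorff surrogate's G→P direction takes no gradient through the
  distance transform of the thresholded prediction; its gradient is exact
  only in the probabilities, matching common practice for distance-transform
  losses.
* The squared-distance/linear-cap unit mismatch in the clip truncation is
  inherited as printed; the `"linear"` option exists but is not the default.
* Dataset readers cover DRIVE/CHASEDB1-style directory layouts only.
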