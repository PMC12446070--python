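# Methods

## Model

`hespex` predicts per-cell gene expression y′ ∈ R^{n_genes} from an H&E
patch x ∈ R^{h×w×3} and a nuclei instance map, by jointly solving four
coupled tasks. The design assumption throughout is that nuclear
morphology, cell type, local cell-type composition and expression are
mutually informative: each auxiliary task regularises the visual features
toward biology that the primary expression task needs.

**Backbone.** A UNet3+-style encoder–decoder with five feature scales and
full-scale skip connections; deep supervision is omitted. Encoder stages
are 3×3 conv + ReLU with channel doubling per scale (64, 128, …, 1024
under default widths). Each decoder stage aggregates all five scales —
encoder maps max-pooled down, decoder maps upsampled (nearest) — through
per-source **1×1 channel projections** to 64 channels each, concatenated
(320 channels) and fused by a 3×3 conv. Spatial context is supplied by the
encoder convs and the fusion convs; making the skip projections pointwise
is this package's choice and keeps the full-scale aggregation topology
intact at a fraction of the arithmetic. A 1×1 classifier head emits
per-pixel probabilities over cell types plus background; its training
target rasterises each nucleus's type onto the instance map (background
class 0). The per-pixel cross-entropy L_Morph is averaged over all pixels,
with probabilities clamped at 1e-8 inside logs.

**Nucleus features.** The first encoder volume (64 ch) and the last
decoder volume (320 ch) are concatenated per pixel (384-d), masked by each
nucleus, summed and divided by the nucleus pixel area — pooling is
therefore exactly invariant to nucleus size for spatially constant
features. The patch-level vector is the spatial mean of the same volumes.
Their concatenation (768-d) passes through FC(256) → ReLU → FC(256),
giving x_nucleus. The hidden width equals the output width (256); the
source description fixes only the output size.

**Cell type and consistency.** FC(256) → ReLU → FC(M) produces type
logits; argmax ties resolve to the lowest class index. A second head of
the same shape consumes expression vectors (predicted and measured): the
cross-entropy on its logits is computed only for predicted expression
(L_CT,expr); the embedding term is mean(1 − cos) between the two hidden
representations with ε-regularised norms (ε = 1e-8); the logit term is the
squared logit difference averaged over types and cells.

**Neighborhood composition.** The mean x_nucleus of a patch passes through
FC → ReLU → FC → softmax over the M cell types, giving p_est. Both
composition losses are KL divergences in nats with the ratio clamped at
1e-8: L_NC,est = KL(p_est ‖ Q) against the true composition Q, and
L_NC,pr = KL(p_CT ‖ Q) where p_CT is the composition implied by the
predicted classes. During training p_CT is the mean of per-cell softmax
probabilities (a soft composition — hard argmax counts are not
differentiable); at inference the hard composition is used.

**Recovery.** For each target type t, one draw Φ_t ~ N(p_est,t, 1) per
patch (the boost is indexed by type, not by cell) gives
v_t = α·n_cells·(p_est,t − p_CT,t)·|Φ_t|, added to every cell's logit for
t (α defaults to 2). Cells confidently predicted as a *protected* type
(softmax probability above 0.6) are exempt; the protected set is
configurable and generalises the original single protected type. The final
class is the argmax over {current class} ∪ target types on revised logits,
so recovery can only move cells into target types and never introduces
other classes. The domain-shift "knowledge injection" mode re-runs the
same mechanism with a very large α (10⁴) and p_CT forced to 0 for the
injected types.

**Expression.** In reference mode, FC(256) → ReLU → FC(n_profiles) →
softmax yields weights W on the profile simplex and S = W·R; with b ≡ 0
the prediction lies in the convex hull of the reference profiles. The
reference R is log1p-transformed to match the expression scale. Direct
mode replaces S by a plain FC(256) → ReLU → FC(n_genes) regression. The
cross-attention residual uses 8 heads at model width 512 (64 per head)
by default: the key/value sequence has one token per gene,
token_j = g_j·S_j + h_j with learned per-gene identity embeddings g_j, h_j
(so the tokens are equivariant under a joint permutation of genes and
embeddings); the query is a single token from a linear map of the patch's
p_est; a final linear layer maps the attended token to n_genes, giving b.
Prediction: y′ = ReLU(S + b) (reference) or ReLU(b) (direct). Spot mode
sums per-cell predictions within each spot. One full copy of this stack
per configured target type provides the adjusted prediction y′_adj used
for recovered cells; its loss is the squared error averaged over genes and
over the cells whose true type is t (zero when the batch has none).

**Total loss.** L = L_Morph + L_CT,class + 100·L_CT,embed + L_CT,logits +
L_CT,expr + L_NC,est + L_NC,pr + (1/N_CT)·L_GE,adj + L_GE. The squared
expression losses average over the gene dimension as well as over cells;
the per-cell/per-patch sums are averaged within each minibatch.

## Training and inference

AdamW at a fixed learning rate 10⁻³ (β₁ = 0.9, β₂ = 0.999, weight decay
10⁻⁴), batch size 8, He fan-in initialisation with zero biases, inputs
standardised by per-channel mean/std of the training patches, expression
log-normalised as log(1 + count) (no library-size scaling; a transform
hook accepts alternatives), on-the-fly flip/right-angle-rotation
augmentation, sample order randomised once before training. One checkpoint
per epoch; the deployed epoch minimises the mean of the validation F1 rank
(cell-type head, macro) and validation PCC rank (mean per-gene Pearson
correlation of predicted vs measured expression — the per-gene-then-mean
aggregation is this package's choice), ties to the earliest epoch.

Whole-image inference tiles the image with a 30-pixel overlap
(approximately the widest nuclei); the final tile per axis is clamped to
end exactly at the border, so all tiles are full-sized and every pixel is
covered. Each nucleus is predicted once, from the tile containing its
largest pixel area (ties to the earliest tile in scan order). Ensembling
averages post-softmax class probabilities, expression and estimated
compositions elementwise across checkpoints before argmax/recovery —
averaging probabilities rather than votes or logits is scale-robust across
checkpoints.

## Synthetic data

The generator emulates the paired training data the model needs:
elliptical, non-overlapping nuclei (rejection-sampled; persistent failures
yield fewer nuclei, never an error) on a pink-white background, each cell
type painted in its own chromatin-like colour with texture jitter (a
"hard" palette makes two types nearly identical to exercise recovery);
per-patch type assignment combines a Dirichlet propensity draw with
per-type spatial attractors, blended with a uniform draw by
`neighborhood_mixing` (1 = i.i.d. uniform); expression counts are
Poisson(size_factor · R[type] · e^ε) with ε ~ N(0, noise_sd) per cell and
gene. Three independent substreams (layout, rendering, expression) spawn
from one seed, so changing the gene panel does not perturb geometry, and
identical seeds give byte-identical outputs.

What it does **not** emulate: realistic chromatin texture, staining
artefacts and batch effects, segmentation errors (instance maps are
exact), cell-type-dependent morphology beyond colour, spatial expression
gradients within a type, or panel-scale gene-gene correlation structure.
Passing tests therefore demonstrate that the architecture and optimisation
recover planted structure through the intended pathways — not that the
model attains any particular accuracy on real tissue.

The reference study (`hespex.study`) uses 200 patches of 128² px, 4 types,
24 genes (4 markers each), mixing 0.5, noise 0.15, a reduced-width
backbone (4 base / 4 skip channels, 64-wide attention) and 8 epochs with a
70/10/20 split — sizes chosen so the full pipeline trains in minutes on
one CPU while leaving clear headroom between signal and noise.

## Numerical choices

- The network stack is an in-package numpy implementation: reverse-mode
  autograd over whole-array ops, im2col convolutions (pointwise fast
  path), He initialisation, AdamW. Parameters and activations train in
  float32; loss formulas accept float64 and are validated against direct
  summation at 1e-6.
- Probability clamps: 1e-8 inside every log (cross-entropy on
  probabilities, KL ratios); cosine norms ε-regularised at 1e-8.
- Macenko stain normalisation: OD = −log10((I+1)/I₀) with I₀ = 240,
  transparency threshold 0.15 OD, stain vectors at the 1st/99th angle
  percentiles of the leading OD eigenplane, concentrations rescaled at the
  99th percentile; fewer than two foreground pixels (e.g. pure white)
  returns the input unchanged with a degenerate flag.
- Matching ties (equal pixel overlap) break to the smaller candidate id;
  an H&E nucleus needs ≥ 50% (inclusive) of its area overlapped. How a
  nucleus overlapping several objects ≥ 50% is resolved is our
  max-overlap decision.
- Cell filters: zero total counts, 'unassigned' type, area < 10 µm²
  (strict); transcript QC keeps qv ≥ 20 and drops control/blank/antisense
  prefixes.
- Cross-validation: k near-equal horizontal bands; validation strip =
  ⌊H/10⌋ rows (≥ 1) from the top of the remaining region.
- SSIM delegates to scikit-image (Gaussian window, conventional
  constants), dynamic range = max − min of the truth raster per gene;
  expression rasters sum cell values per spatial bin. Undefined
  correlations (constant vectors) are NaN sentinels, excluded from
  summaries, never imputed. The built-in gene-variability ranking (for
  stratified summaries and spot-gene selection) uses the variance of
  log1p values; external spatially-variable/highly-variable rankings can
  be supplied as plain gene lists.
- Spot metric rollup: average per image, then per individual (individuals
  weigh equally regardless of image count), then per gene.

## Limitations

- Instance maps are inputs; the package performs no nuclei segmentation
  of its own and no H&E/DAPI registration.
- Whole-slide pyramidal formats are out of scope; callers supply
  pre-extracted tiles or plain arrays.
- The numpy engine is single-device and unbatched across processes;
  it is sized for panel-scale (hundreds of genes) desk experiments, not
  for training on full slides.
- Survival analysis and other downstream cohort analyses are outside the
  package.
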