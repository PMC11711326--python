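# Methods

## Model

`cellstyle` is a conditional image-to-image GAN for high-content microscopy.
Each image `x ∈ R^{C×H×W}` carries a condition index `d ∈ {1..p}` — a
perturbation (drug, CRISPR guide, ORF) or a technical batch. The model
decomposes the image into:

- **content** `ĉ = E(x)`: a spatial code (512 channels at H/8 × W/8 by
  default) produced by a convolutional encoder; it carries the
  condition-invariant structure of the cell.
- **style** `ŝ = f([e_d ; z])`: a low-dimensional appearance code. `e_d` is
  the condition's embedding (fixed chemical/genetic descriptor, or a
  trainable vector for batches), `z ~ N(0, I_K)` is noise, and `f` is a
  single linear map per modality into a shared style space `R^S`. Because
  `z` is resampled per draw, each condition induces a *distribution* of
  styles, hence a distribution of predicted phenotypes.

The decoder `D(ĉ, ŝ)` mirrors the encoder and is conditioned on the style
through adaptive instance normalization: every decoder residual block
standardizes its feature maps per instance and channel and re-scales them
with `(σ(ŝ), μ(ŝ))` produced by a learned linear head (the scale head is
offset by +1 so an untrained head is the identity affine). Writing
`G(x, s) = D(E(x), s)`, inference is: sample `z`, form `ŝ' = f([e_{d'}; z])`,
decode `G(x, ŝ')`.

Supporting networks: a **style encoder** `E_sty` (convolutional, one linear
output head of size S, no output activation) recovers the style a generated
image carries; a **multi-task discriminator** with one sigmoid head per
condition scores "is this a real image of condition j" — heads are
independent (not a softmax over conditions), which suits perturbations with
similar phenotypes.

### Losses

With `ŝ'` the sampled target style and `x̂' = G(x, ŝ')`:

- adversarial value `E[log Dis_d(x)] + E[log(1 − Dis_{d'}(x̂'))]`, ascended
  by the discriminator. The generator by default maximizes
  `log Dis_{d'}(x̂')` (non-saturating variant; the saturating form is a
  config switch). Probabilities are clamped at 1e-7 from the boundary.
- style reconstruction `‖ŝ' − E_sty(x̂')‖₁` (mean over the batch) ties the
  generated appearance to the style that produced it.
- cycle consistency `‖x − G(x̂', E_sty(x))‖₁` (mean absolute pixel error)
  keeps the mapping invertible and the content preserved.
- diversification `−‖G(x, ŝ'⁽¹⁾) − G(x, ŝ'⁽²⁾)‖₁` for two independent noise
  draws of the same condition, preventing the generator from ignoring `z`.
  Its weight decays linearly to exactly 0 at the final iteration.
- R1 gradient penalty `(1/m) Σ ‖∇_x Dis_d(x)‖₂²` on **real** images at the
  active head (computed on the pre-sigmoid head output; the penalty is
  differentiated again with respect to the discriminator parameters, which
  is why the autodiff engine supports second-order gradients).

Default weights are `λ_adv = λ_sty = λ_cyc = λ_ds = λ_reg = 1`; the
desk-scale studies use `λ_adv = 2` (see below). Optimization is Adam with
`β = (0, 0.99)`; the discriminator can run at a lower learning rate than
the generator (two-timescale), and condition encoders / batch embeddings
have their own rate.

### Training iteration

1. Sample a source batch `(x, d)` — controls only in one-to-many mode.
2. Sample a target `d'` per image and two noise vectors.
3. Encode both styles with `f`.
4. **Discriminator step**: the real term uses a *reference batch* of real
   images drawn from the sampled target conditions, so every head that is
   asked about fakes also sees genuine examples of its condition that
   iteration; the fake term uses `G(x, ŝ'⁽¹⁾)` (generator detached); plus
   the R1 penalty on the reference batch.
5. **Generator step**: adversarial + style-reconstruction + cycle +
   diversification (second generation detached), updating the generator,
   style encoder, condition encoders and trainable batch embeddings.

One-to-many mode (perturbation prediction) converts controls into any
condition in the pool, control included, so a "no effect" prediction is a
valid target. Many-to-many mode (batch correction) converts any batch into
any other, `d' ≠ d`. Without the reference batch the perturbation heads
would never see real perturbed images in one-to-many mode and could not
ground the target appearance; making the targets follow a sampled real
reference is the resolution used here.

Augmentation: independent vertical/horizontal flips (probability 0.3 each)
and elementwise Gaussian noise (σ = 0.005 on the [−1, 1] pixel scale).

### Defaults and unstated constants

| parameter | default | note |
|---|---|---|
| style dim S | 64 | convention of the style-transfer GAN family this architecture follows; configurable |
| noise dim K | 16 | same |
| IN/AdaIN eps | 1e-5 | numerical floor under the square root |
| pixel range | [−1, 1] | linear map of the stored 8/16-bit range |
| LeakyReLU slope | 0.2 | everywhere |
| prob clamp | 1e-7 | inside log terms |
| widths | 64→128→256→512 | capped at `max_width` |

The discriminator and style encoder share an organization but never share
weights. The decoder output is a linear 1×1 convolution (no tanh); the
cycle and adversarial losses keep outputs in range in practice.

## Numerical engine

Networks run on a compact reverse-mode autodiff core (`cellstyle.ag`)
over NumPy arrays. Every primitive's vector-Jacobian product is written in
terms of primitives, so gradients are graph nodes and the R1 penalty's
second-order term is exact (verified against finite differences).
Convolutions are stride-1 kernels (1 or 3) composed from shifted slices and
one matmul; downsampling is 2×2 average pooling, upsampling nearest-
neighbour. Float64 is the default; the desk-scale studies use float32,
which GAN training does not notice and which runs measurably faster.

## Synthetic data

The generator renders multi-channel "cell" images: channel 0 holds
eccentric Gaussian nuclei, the remaining channels a textured cytoplasm
annulus (sinusoidal radial texture); cells are placed by a Poisson draw
with overlap-limited rejection. A phenotype controls nuclear radius and
eccentricity, cell density, per-channel gain and texture frequency; a
batch effect applies per-channel gain/offset and Gaussian blur, applied
after rendering. Everything is seeded through named streams, and ground
truth (cell counts, parameters) is emitted alongside.

Condition-embedding tables mirror phenotype geometry. For the `line`
structure, conditions sit on a straight line at positions proportional to
their mean intensity gain, then the largest pairwise distance is normalized
to `span` (default 3). The span is expressed in units of the unit-variance
noise the condition encoder concatenates with the embedding: real chemical
descriptors of distinct compounds are far apart relative to that noise, and
an unscaled line would leave the condition signal statistically buried
under the style noise.

What the generator does **not** emulate: stain physics, realistic textures,
cell-cycle or morphological heterogeneity within a condition, segmentation
artifacts. Tests passing on this data demonstrate the machinery (losses,
conditioning, correction, metrics) behaves correctly — not that real
screens will reach the same scores.

## Desk-scale studies

Two fixed study configurations (`cellstyle.studies`) exercise the full
pipeline at sizes that train in minutes on one CPU core: 32×32 images,
widths 8→32, S=16, K=8, batch size 4, generator lr 1e-3, discriminator lr
2.5e-4, condition lr 2e-3, `λ_adv = 2`.

- **Perturbation study** (800 iterations, one-to-many): control
  (gain 1.0) and treated (cytoplasm gain 0.4) conditions on a line whose
  midpoint (gain 0.7) is never trained. Endpoints measured: probe
  (logistic-regression on morphology features) accuracy of transformed
  controls against both targets; L1 spread across noise draws; FID and
  Coverage of transformed vs. real treated images; the cytoplasm-mean
  statistic of the decoded midpoint embedding relative to its neighbours.
- **Batch study** (700 iterations, many-to-many): one phenotype across
  three batches with distinct gains/offsets (one blurred), trainable batch
  embeddings. Endpoints: fraction of corrected images a batch probe assigns
  to the reference batch; cluster-impurity (entropy/Gini over Leiden
  clusters) and batch-mixing scores (batch-silhouette, iLISI) before and
  after correction.

The iteration counts and widths are the smallest we found that give the
studies comfortable margins; halving the iterations degrades the
control-target accuracy and the reference-assignment fraction first.

Two known limitations at this scale. First, the trained generator recolors
reliably but does not reconstruct fine texture, so the cycle-reconstruction
error (~0.5 mean absolute pixel difference) is not below the mean L1
between random validation pairs (~0.43, dominated by matched backgrounds).
Second, the no-effect direction — transforming a control *to the control
condition* — is seed-sensitive: the probe sometimes assigns generated
controls to the treated class even when the perturbation direction is
learned perfectly, because partially converged control renderings sit
between the two real classes in feature space. Both quantities are
computed and reported by the studies; full-scale models with 64–512 widths
are expected to close these gaps.

## Metrics

- **FID** between Gaussian moment summaries of image features, with the
  matrix square root via `scipy.linalg.sqrtm`; small negative eigenvalues
  are clipped, larger failures raise. An independent eigendecomposition
  evaluation backs the tests.
- **Coverage**: fraction of real points whose k-NN sphere (radius = distance
  to the k-th nearest *real* neighbour, boundary inclusive) contains a
  generated point. Default k = 5; ties resolve by index.
- **Batch-silhouette** = mean of 1 − |s_i| with batch as the cluster label;
  **iLISI** = per-point inverse Simpson index of batch frequencies among k
  nearest neighbours, rescaled from [1, n_batches] to [0, 1].
- **Cluster impurity**: per-cluster batch entropy (log2) and Gini index,
  averaged *unweighted* across clusters; clustering defaults to Leiden
  (resolution 1.0) on a k-NN graph, any labelling callable is accepted.
- **Feature extractors** are pluggable; the built-in `morphology` extractor
  computes per-channel intensity statistics, gradient/Laplacian texture and
  Otsu-based nuclear shape summaries (22 features for 3 channels), so all
  metrics run offline. Adapters for external pretrained extractors register
  at run time.
- **MoA / batch probes**: either a logistic regression on morphology
  features (fast, deterministic; used in the studies) or a convolutional
  classifier with the discriminator's architecture and a softmax head.

## Chemistry

Drug embeddings are hashed 1024-bit Morgan fingerprints (radius 2).
Similarity reporting uses the *unhashed count-based* Morgan fingerprint
(Tanimoto = Σmin/Σmax over substructure counts): bit-hashing collisions
perturb similarity values, and the count form reproduces the reference
compound-pair similarities exactly (e.g. paclitaxel–docetaxel 0.73,
methotrexate–chlorambucil 0.21). The all-zero fingerprint pair is defined
to have similarity 1.0. Scaffold splits compute Bemis–Murcko scaffolds and
assign whole scaffold groups to one side, filling the test side greedily
from the smallest groups.

Gene and DNA embedding providers are interfaces. The built-in stand-ins — a
seeded random vector per gene symbol, and a random projection of the k-mer
spectrum for sequences — are synthetic: they have the right shapes and
determinism for pipeline testing and carry no biology. Production use
should plug in published co-expression vectors and a sequence model; the
concatenated drug layout (1024 fingerprint + 200 gene dims = 1224) matches
the multi-modal configuration the model was designed for.

## Preprocessing

Illumination correction per plate and channel: flatfield = Gaussian-
smoothed (σ = 50) pixelwise 10th percentile across the plate; divide, clip
below at 1, natural log, clip above at 5, min-max rescale to [0, 255]
per image (per-plate is an option), quantize to 8 bits. A numerically
constant result maps to zero rather than amplifying float noise.

Single-cell crops are 96×96 half-open windows `[c − 48, c + 48)` around
0-based (x = column, y = row) centres; centres closer than 48 px to any
edge are dropped. QC keeps crops with all-channel pixel variance ≥ 2000
(8-bit domain) and perceptual blur ≤ 0.65. The blur score is a re-blur
comparison: the image is smoothed with a 9-tap box filter per axis and the
score is the fraction of neighbouring-pixel variation that smoothing fails
to remove, maxed over axes — 0 for sharp, 1 for maximally blurred; the
implementation is spelled out in `preprocess.perceptual_blur` so the 0.65
threshold is reproducible. Large fields of view tile into non-overlapping
256×256 patches resized to 128 (partial edge tiles discarded). Nuclear
patching applies a global Otsu threshold to the nuclear channel, keeps
connected components above a minimum area (default 40 px), and cuts one
border-filtered patch per component centroid; merged nuclei give one patch.
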