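# Methods

`dpkhsi` implements a hyperspectral-image classification pipeline in which
the convolution kernels of a CNN are not learned by back-propagation but
*pre-learned* by density-peaks clustering of image blocks, with the number
of kernels decided adaptively from the clustering geometry. Around that
core it provides ENVI cube I/O, a synthetic scene generator, a 3D
convolutional encoder with layer-feature strategies, a spectral-difference
super-resolution model, and the evaluation metrics the pipeline reports.
This note records the models, the parameters that matter, and the design
decisions taken where the method left choices open.

## Density-peaks clustering (CFSFDP)

Given the pairwise Euclidean distance matrix `D` of N samples and a cutoff
distance `d_c`, each point i carries

- local density `rho_i = #{ j != i : d_ij < d_c }` — a hard-cutoff
  indicator count (a Gaussian-kernel variant,
  `rho_i = sum_j exp(-(d_ij/d_c)^2)`, is available behind the
  `kernel="gaussian"` flag but is not the default);
- separation `delta_i = min { d_ij : rho_j > rho_i }`, with the globally
  densest point taking `delta = max_j d_ij`;
- the product `gamma_i = rho_i * delta_i`, which ranks center candidates.

Cluster centers are points that are simultaneously dense and well
separated. Non-centers are assigned, in order of decreasing density, to the
cluster of their nearest higher-density neighbour. Exact density ties are
broken by point index (the lower index counts as denser); without such a
rule `delta` is undefined on tied plateaus.

`choose_dc` picks the smallest cutoff whose mean neighbour count reaches a
target fraction of N−1 (default 0.02). In auto mode a small-sample floor
keeps the mean neighbour count at two or more: on point sets of a few dozen
samples a 2% target would make nearly every density zero and the decision
graph degenerate.

## Adaptive kernel count (MCFSFDP)

Instead of thresholding `rho` and `delta` jointly, a single distance
threshold `delta_v` is swept over candidates spanning 5–95% of the maximum
separation (50 linear steps by default). For each candidate,

- `num_v` counts points whose `delta` exceeds the threshold,
- `con_v = (num_{v+1} − num_v) / (delta_{v+1} − delta_v)` is the
  finite-difference slope,
- `quo_v = |con_v / con_{v+1}|` (0/0 → 1) is the consecutive-slope ratio.

The decided center count is the value of `num` on the plateau of the curve.
Plateau widths are measured on the **log-delta** scale: true centers sit at
inter-cluster distances whose values spread multiplicatively, so gaps
between consecutive center separations can be wide in absolute delta while
the plateau at the true count spans a large delta *ratio*. The default
`first_wide` rule takes the first maximal zero-slope run at least half as
wide (in log delta) as the widest; a `widest` rule is available. On
k-cluster Gaussian blob sets with 8-sigma centroid spacing (k = 2..6, 30
points per cluster) this recovers k in ≥ 95 of 100 seeded runs. If the num
curve has no plateau at all, the implementation falls back to the largest
relative gap in the sorted gamma sequence and warns.

The same gamma-gap statistic (`count_decision_outliers`) counts the joint
(rho, delta) outliers of a decision graph; on a 21-point two-cluster set it
returns exactly 2.

## Pre-learned-kernel CNN

The classification network is deliberately minimal:

    input patch -> conv(K frozen kernels, valid, stride 1) -> ReLU
                -> non-overlapping max-pool (p = 2) -> flatten
                -> fully connected (width 64, ReLU) -> softmax

Kernels come from cluster centers of kernel-sized sub-blocks sampled
uniformly inside the training patches; each kernel is mean-centred and
scaled to unit Frobenius norm so its response behaves as a matched filter
(`normalisation="none"` keeps raw blocks; constant blocks are rejected
because they vanish under centering). K is the MCFSFDP decision by default;
fixed-K CFSFDP, random kernels, k-means centroids and PCA components are
available as ablations. Only the fully connected head is trained (Adam,
lr 1e-3, cross-entropy, batch 64, at most 100 epochs, early stopping on
validation accuracy with patience 10); the kernels are bit-identical before
and after training, which a checksum test enforces. Pooling pads remainders
with −inf so partial windows keep their true maximum.

## Data preprocessing

Spectra are standardised per band (zero mean, unit variance) and projected
onto the top principal components of the pixel-by-band matrix; the
cumulative explained-variance ratio is returned so the "keep ≥ 99% of the
information" working point can be checked (30 components suffice on scenes
built from a handful of endmembers). PCA is fitted on all pixels by
default, matching the workflow it reproduces; `standardize=False` gives the
plain covariance eigenbasis. One patch is cut per labelled pixel with
mirror padding at the borders, and the patch set is split into
train/validation/test stratified per class (default 0.6/0.2/0.2; a class
with fewer than three samples stays whole in train, with a warning).

## Synthetic scenes

The generator emulates the geometry of agricultural benchmark scenes
without copying any real spectrum: per-class endmembers are baselines plus
2–4 Gaussian bumps over band index (smooth, positive, like reflectance
curves); the label map is a seeded Voronoi partition, so classes are
contiguous regions; each pixel is its endmember scaled by spatially smooth
multiplicative illumination jitter (5% std, 2 px correlation length) plus
i.i.d. Gaussian noise calibrated to a target SNR in dB; boundary pixels can
be linearly mixed over a configurable width. What this does **not** model:
sensor-correlated noise, atmospheric effects, intra-class spectral
variability beyond a scalar illumination factor, and spatial textures.
Passing tests therefore demonstrate the machinery is correct and that the
method behaves as designed under its own assumptions — not field
performance on real sensors.

Default study conditions for the end-to-end checks: a 64×64 scene with 4
classes, 32 bands, 30 dB SNR; 8 principal components, 5×5 patches, 3×3
sub-patches, clustering on at most 400 sampled sub-patches. The
noiseless-exactness check runs the pure-spectral configuration (1×1 patches
and kernels with K set to the class count): noiseless pixels are spectrally
separable, so per-pixel classification is exact, while 5×5 patches can
straddle class boundaries and occasionally cost a misclassified boundary
pixel even without noise.

The decided K on scene sub-patches is typically *larger* than the class
count (different seeds give K from ~2 to ~22 on the 30 dB scene): 3×3×8
sub-patch space legitimately has more density modes than spectral classes
(boundary blocks, illumination strata). This does not hurt accuracy — more
matched filters simply give the classifier a richer basis — and the
class-count recovery claim is made where it is well posed, on point-set
clustering.

## 3D convolutional encoder

The supervised 3D encoder consumes a 27×27×30 PCA-reduced patch as a
single-channel volume through three valid conv + batch-norm + ReLU +
2×2×2 max-pool blocks (32 kernels of 4×4×5, then 64 of 5×5×4, then 128 of
3×3×4), giving the shape chain 24×24×26 → 12×12×13 → 8×8×10 → 4×4×5 →
2×2×2 → 1×1×1, so the flattened code length equals the third layer's kernel
count (128). A width-500 ReLU layer and a softmax head complete the
supervised network. Batch normalisation uses running statistics at
inference, so prediction is deterministic.

The companion 2D encoder used for layer-feature experiments is a
valid-convolution stack 96@5×5 / 192@3×3 / 384@3×3 on an 11×11 input with
no inter-layer pooling. Its architecture is a *reconstruction*: the channel
counts are the published pooled feature sizes and the map sides follow from
the un-pooled sizes divided by the channels; it is asserted only against
those fourteen sizes (h1 = 96·7·7 = 4704 … pooled h1+h2+h3 = 672). A
feature strategy selects a subset of {h1, h2, h3} and either flattens maps
or takes the per-channel global spatial maximum ("pooling" is read as
global max pooling — the only reading under which the pooled size equals
the channel count). Encoders train either as convolutional autoencoders
(mirrored transposed-convolution decoder, discarded after training) or
supervised through the FC head.

A note on the pooled-beats-unpooled ordering: on centre-labelled Voronoi
patches, where the class of the centre pixel is the label, un-pooled
features *win* — spatial position inside the patch is informative and a
ridge-regularised classifier exploits it. The regime in which pooled
shallow features dominate, and which the package's ordering test
constructs, is translation variance: when the class-discriminative
structure appears at arbitrary positions in the receptive field, the global
maximum is invariant to position while the huge un-pooled concatenation
must learn every placement. That mechanism, not a universal superiority of
pooling, is what the layer-strategy comparison demonstrates.

## Spectral-difference super-resolution (SDCNN)

The model maps the first-order band difference of a spectrally degraded
spectrum to the reference band difference, one pixel at a time. Degradation
is band-block averaging by an integer factor followed by linear
interpolation back to the full band count (the generator exposes it as
`degrade_bands`). The network is a stack of same-padding 1-D convolutions
over the 1-channel difference signal — default three layers with kernel
sizes 9-5-3 (receptive field 15), hidden channels 64/32, ReLU between
layers, linear output — trained with MSE (Adam, lr 1e-3, batch 128).
Kernel-size variants (7-5-3, 7-5-1) and other depths run under the same
harness. Average PSNR and SSIM between predicted and reference differences
are logged every 20 iterations; on pooled multi-scene training data the
PSNR curve rises and then stabilises.

Restoration reintegrates the predicted differences cumulatively, anchored
at the first degraded band. Pure reintegration accumulates low-frequency
drift (the integral of small per-band errors), which can leave the restored
*spectrum* below the degraded baseline even when the predicted
*differences* are clearly better; passing `down_factor` to `apply_sdcnn`
enables a data-consistency back-projection — each band block of the
restored spectrum is shifted so its mean matches the degraded spectrum's
block mean, which block-average degradation preserves — after which
restored spectra beat the degraded baseline on held-out scenes.

## Metrics

Overall accuracy is the confusion-matrix trace fraction; average accuracy
the mean per-class recall; Cohen's kappa uses marginal-product expected
agreement and is reported both raw and ×100. The Rand index is computed
from the contingency table as (concordant-same + concordant-different)
pairs over C(n,2). Normalised mutual information uses base-2 logs and
sqrt(H(A)·H(B)) normalisation; a single-cluster side returns 0 by
convention. PSNR is `10·log10(peak²/MSE)` with an infinity sentinel at zero
MSE. SSIM is the mean of the local similarity map over a 7-pixel uniform
window with constants K1 = 0.01, K2 = 0.03, edges cropped to fully valid
windows. Library implementations (scikit-learn's kappa and geometric NMI,
scikit-image's SSIM) serve as independent cross-checks in the test suite,
never as the implementation.

## Numerical and engineering choices

- All networks run on a small in-package numpy layer stack (`_nn.py`):
  convolution layers accumulate one matmul per kernel offset, which is
  exact, differentiable by the symmetric scatter, and fast enough at these
  scales; gradients are verified against central differences to ~1e-8.
- Every generator and training routine is a pure function of its seed;
  reruns of a persisted pipeline config reproduce the classified map
  bit-for-bit.
- Problem sizes in the test and acceptance runs (64×64 scenes, 16×16 SR
  scenes, ≤ 500 training iterations, ≤ 400 clustering samples) were chosen
  so the whole suite completes in about a minute on one CPU while leaving
  every claimed margin wide.
- Interleave conversion is a pure byte permutation; round trips are
  asserted bit-exact for integer types.

## Known limitations

- Clustering materialises the full N×N distance matrix: fine up to a few
  thousand samples, not for whole-image block sets (hence the sampling cap,
  default 400).
- The 2D encoder is a size-consistent reconstruction, not a published
  architecture; only its feature dimensions are authoritative.
- The scene generator's simplifications (see above) mean accuracy figures
  here say nothing quantitative about real benchmark scenes.
- SDCNN operates per pixel on 1-D spectra; no spatial context is used in
  restoration.
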