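# Methods

## Model

The enhancer is a conditional GAN over [0,1]-scaled contact-map tiles.

**Generator.** Entry 9×9 convolution (1 → C channels) with Swish activation
(`x·σ(x)`, β = 1); a chain of residual blocks, each
`conv3 → batch norm → Swish → conv3 → batch norm → additive skip`; a
post-block 3×3 convolution + batch norm joined to the entry activation by a
long skip; an exit 9×9 convolution back to one channel; and the output
squashing `g(x) = (tanh x + 1)/2`, which keeps every output strictly inside
(0,1). All convolutions are stride-1 with same-padding, so the network is
fully convolutional: any tile side is preserved, and tiles of different
sizes can be enhanced by the same weights. The full-scale default is
C = 64 with 5 residual blocks (418,049 trainable parameters, reported by
`count_trainable_parameters`); the desk-scale configuration used by the
test suite and the acceptance script is C = 8 with 2 blocks (4,305
parameters).

**Discriminator.** VGG-flavoured stages of widening 3×3 convolutions (each
stage: stride-1 conv, Swish, stride-2 conv, Swish), global average pooling,
and a dense layer with sigmoid, yielding one realness score per tile.
Channel widths must increase strictly across stages.

**Losses.** The generator objective is
`L_G = l_MSE + α·l_feat + β·l_TV + γ·l_Ad` with α = 0.006, β = 2e-8,
γ = 0.001 (weights chosen to put the four terms on a common scale). Two
printed conventions are replaced by stabilized forms with the same
minimizer, both kept available behind `literal=True` flags:

* the raw adversarial score `mean(ŷ)` *increases* as generated tiles are
  scored more realistic, so the generator minimizes `mean(1 − ŷ)`;
* the raw discriminator sum `mean[log ŷ + log(1 − y)]` is unbounded below,
  so the discriminator minimizes standard binary cross entropy
  (real label 1, fake label 0), clamping scores to [1e-7, 1 − 1e-7].

The perceptual term compares responses of a *fixed* feature extractor. The
default extractor is a frozen three-stage strided convolution stack
(widths 8 → 16 → 16, Swish, seed-0 He initialization) — deterministic,
dependency-free, and never trained; gradients flow only to the generator
output. An identity extractor (collapsing the term onto MSE) and disabling
the term entirely are also supported.

## Initialization

At the step counts of a desk-scale run, the starting function matters as
much as the updates, so the generator uses an identity-start scheme that is
standard for restoration networks:

* the closing batch norm of every residual block and of the post-block join
  starts with scale γ = 0, making each block exactly the identity at
  initialization while leaving gradients intact (zero-gamma residual
  initialization);
* the entry convolution starts as a narrow normalized Gaussian tap
  (SD 0.5 bins) plus small He noise, and the exit convolution as a center
  tap of weight 3.363/C with bias −1.080 — the least-squares fit of
  `g(k·swish(u) + b)` to the identity on u ∈ [0,1].

The untrained generator is therefore a near-identity, mildly smoothing map
of its input rather than an arbitrary random field; training then learns
denoising and rescaling on top. Other weights are He-initialized from the
run seed; Adam moments are (0.9, 0.999).

## Training

Batches of paired (low-coverage, truth) tiles, shuffled each epoch under
the run seed. Per batch: one discriminator update on (real, detached fake)
scores, then one generator update through fresh discriminator scores —
separate Adam optimizers with identical settings, learning rate 1e-4,
batch 64. Train and test sets are split by chromosome and the split is
enforced (overlap raises). After every epoch the held-out tiles are scored:
mean per-term loss, mean tile SSIM, mean tile PSNR. Final-epoch weights are
kept (no early stopping). A fixed config + seed reproduces the entire
history bitwise on one thread. Non-finite losses abort with the epoch
number. A quasi-autoencoder control is run by passing the low-coverage
tiles as both input and target; no dedicated code path exists.

## Preprocessing

Counts are clipped at a cutoff and divided by it. Full-coverage 10-kb
targets use the fixed cutoff 255; inputs at the tabled thinning ratios
1/10, 1/16, 1/25, 1/50, 1/100 use 125, 100, 80, 50, 25; anything else uses
the 99.9th percentile of the matrix's *nonzero* entries (zeros dominate
sparse maps and would drag a raw percentile to zero), with linear
interpolation.

Tiling covers the upper triangle of the scaled map with non-overlapping
40×40 blocks, keeping a block at grid origin (r0, c0) iff c0 ≥ r0 and
(c0 − r0)·bin_size < 2 Mb (origin-distance rule; most TADs and significant
interactions lie inside that band). The matrix is zero-padded to a multiple
of the tile size and cropped after reconstruction. Reconstruction mirrors
off-diagonal tiles across the main diagonal and symmetrizes diagonal tiles,
so the output is symmetric by construction; entries outside the band are
copied from the scaled input — the model never fabricates long-range
values. Export for significant-interaction calling multiplies by 255 and
rounds half-up to integers.

## Metrics

SSIM uses the classic windowed form with local statistics under an 11×11
Gaussian window of standard deviation 3 ("variance value 3" is read as the
SD, the common implementation convention; a variance reading is available
via `sigma_is_variance`). Both inputs are min–max rescaled independently
first, so the score compares contrast and structure, not absolute
luminance; C1 = (0.01·L)², C2 = (0.03·L)² with dynamic range L = 1 after
rescaling. Windows are evaluated at fully interior positions only (no
padding). Two constant inputs score 1 by the stabilized limit. Genome-wide
SSIM is the mean over non-overlapping 1-Mb diagonal blocks, dropping the
trailing partial block. PSNR is 10·log₁₀(1/MSE) on [0,1]-scaled data, +∞
at exact equality. The per-distance profile computes, at each genomic
distance from 50 kb to 1 Mb in one-bin steps, the Pearson correlation of
the two maps' corresponding diagonals (NaN where a diagonal is constant).
Truth maps enter as raw counts, enhanced maps on their [0,1] scale —
Pearson is affine-invariant, so only clipping, not scaling, could matter.

## TAD analysis

The insulation score of bin *i* is the mean count in the 5×5 square
crossing the diagonal at *i* (rows i−5…i−1, columns i+1…i+5; diagonal
excluded), normalized as log₂(raw/mean raw) over valid bins — invariant to
global scaling of the matrix. Invalid bins: within 5 bins of an end,
low-coverage bins (zero marginal by default, or below a configurable
quantile), and bins whose raw window mean is zero (the log is undefined;
treated as a local coverage gap). Δ(i) is the mean insulation of the 5
nearest valid loci downstream minus upstream, masked where any contributor
is invalid; this orientation makes insulation minima — boundaries — the
zero-points of Δ inside *ascending* intervals, and the caller returns bins
where Δ(i) ≤ 0 < Δ(i+1) (a run of exact zeros resolves to its last bin).
TADs span adjacent boundary bins; a TAD containing an excluded bin is
dropped. Boundaries are bins — no sub-bin interpolation. Segmentations are
compared by each split point's distance to the nearest reference split
point and by each interval's best Jaccard overlap with any reference
interval.

## Synthetic data

The simulator emulates the features the method is judged on: expected
count λ_ij = c·(1+|i−j|)^(−1) (power-law decay), multiplied by 3 for pairs
inside the same TAD (blocks of 20–60 bins, 4–6 per 200-bin chromosome) and
by 8 within 1 bin of a loop anchor pair (3 loops at TAD corners), with c
normalized so the upper-triangle total equals the sequencing depth
(2×10⁶ by default — a realistically deep 2-Mb region at 10-kb bins).
Counts are Poisson around λ, drawn on the upper triangle and mirrored. Low
coverage is simulated by binomial thinning of counts, exact for
independently subsampled reads re-binned at the same bin size. The flanking
segments before the first and after the last split point also count as
domains for the boost.

What the simulator does *not* model: restriction-fragment structure,
ligation and mapping artifacts, matrix balancing (ICE/KR) biases,
inter-chromosomal contacts, stripes, and compartment-scale plaid patterns.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that enhancement works on decay+TAD+loop structure with
Poisson/binomial noise — not that the trained desk-scale weights transfer
to real data.

## Problem sizes and numerical choices

The test suite and acceptance script train on ten simulated 200-bin
chromosomes (8 train / 2 test, 150 tiles total), 1/16 thinning, batch 64,
learning rate 1e-4, 30 epochs, with the C = 8 / 2-block generator — sizes
chosen so the whole study runs in minutes on one CPU while exercising every
stage. At this scale (~60 optimizer steps) the trained model roughly
doubles held-out tile SSIM over the raw input and adds ~5 dB PSNR
chromosome-wide, and the held-out generator loss decreases monotonically;
per-distance Pearson correlation, however, improves only at a subset of
distances — the residual smoothing of the near-identity start mixes
adjacent diagonals, and removing it needs more steps than the desk-scale
budget provides. A full-scale run (64 channels, 5 blocks, 200 epochs,
thousands of tiles) is configured by the same objects.

Everything is float64. Convolutions are evaluated by im2col + BLAS matmul
for small patches and in the Fourier domain for large ones (identical
results to floating-point accuracy; the FFT path avoids gigabyte im2col
buffers for 9×9 kernels at many channels). Batch norm uses ε = 1e-5,
momentum 0.1, running statistics frozen at training end for evaluation.
Discriminator/loss scores are clamped to [1e-7, 1 − 1e-7] inside logs.
Percentiles interpolate linearly; Fit-Hi-C export rounds half-up;
symmetrization mirrors the upper triangle and is idempotent. Checkpoints
are single-file `.npz` archives holding configs, weights, batch-norm
statistics and the training manifest (seed, loss weights, cutoffs,
history); loading with a mismatched generator config raises.

## Known limitations

* Inputs with fewer than 10% nonzero entries are outside the method's
  comfort zone; enhancement warns but proceeds.
* Only intra-chromosomal, single-resolution, unbalanced matrices are
  modelled; `.hic` binary files and multi-resolution coolers are not read.
* The supplementary per-layer hyperparameter tables of the original
  architecture are not reproduced verbatim; the configuration objects
  expose every width/kernel so any published setting can be instantiated.
* The pretrained-VGG16 perceptual extractor is supported as a concept
  (pluggable extractor interface) but no pretrained weights ship with the
  package; the frozen builtin stack is the default.
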