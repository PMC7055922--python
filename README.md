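# hicsr

Adversarial super-resolution of Hi-C contact maps: predict high-coverage
contact matrices from shallowly sequenced (downsampled) Hi-C, plus the
evaluation metrics and TAD-boundary analysis used to judge the result, and a
synthetic Hi-C simulator so the entire pipeline runs end-to-end without any
external download.

## The problem

Hi-C summarizes chromosome folding as a symmetric matrix *M*<sub>n×n</sub>
of read-pair counts between fixed-size genomic bins. Fine structure —
chromatin loops, TAD boundaries, sub-TADs — only becomes visible at kilobase
bin sizes, but the read depth needed for a well-filled 10-kb matrix scales
roughly quadratically with resolution, so most published maps are shallow:
sparse, noisy, and unreliable for downstream loop/TAD calling.

`hicsr` treats map enhancement as conditional image super-resolution. A
generator *G* (a fully convolutional residual network with Swish
activations, output squashed into (0,1) by *g(x)* = (tanh *x* + 1)/2) maps
40×40-bin tiles of the low-coverage matrix to enhanced tiles; a
discriminator *D* (a VGG-style convolutional classifier ending in a sigmoid)
scores tiles as real or generated. They are trained alternately; *G*
minimizes

```
L_G = l_MSE + α·l_feat + β·l_TV + γ·l_Ad ,   α = 0.006, β = 2e-8, γ = 0.001
```

where `l_feat` is a perceptual loss (MSE between fixed feature-extractor
responses), `l_TV` the total-variation penalty, and `l_Ad` the adversarial
term. *D* minimizes binary cross entropy. Training pairs come from binomial
read thinning: each count is replaced by Binomial(count, ratio), exactly
equivalent to keeping each read with probability `ratio`.

Around the model, the package implements the full workflow:

* **I/O** — single-resolution cooler-schema `.cool` (HDF5), dense `.npz`
  archives, and `bin_i bin_j count` triplet text;
* **preprocessing** — outlier clipping (99.9th-percentile rule; fixed
  cutoffs 255 for full-coverage 10-kb targets and 125/100/80/50/25 for
  1/10…1/100 inputs), min–max scaling to [0,1], tiling of the <2-Mb
  diagonal band into 0.4-Mb tiles, reconstruction, and ×255 integer export
  for significant-interaction calling (Fit-Hi-C input format);
* **metrics** — Gaussian-window SSIM (11×11 window, σ = 3), PSNR =
  10·log₁₀(1/MSE), mean SSIM over 1-Mb diagonal blocks, and per-genomic-
  distance Pearson correlation (50 kb–1 Mb);
* **TAD analysis** — insulation score with a 5-bin window, Δ score over 5
  flanking loci, boundaries at zero-points of Δ in ascending intervals,
  TADs between adjacent boundary centers, plus the two segmentation-
  comparison statistics (nearest-boundary distance and best interval
  Jaccard index);
* **simulation** — synthetic chromosomes with power-law distance decay,
  TAD blocks, focal loops and Poisson counting noise.

## Worked example

Train at desk scale on ten simulated 200-bin chromosomes (1/16 read
thinning, batch 64, learning rate 1e-4, 30 epochs), then enhance and score
a held-out chromosome:

```bash
hicsr train --n-chroms 10 --ratio 0.0625 --seed 1 --epochs 30 --out model.npz
hicsr simulate --seed 1500 --ratio 0.0625 --out-dir sim/
hicsr enhance --model model.npz --in sim/downsampled.cool --chrom chrS \
      --ratio 0.0625 --out enhanced.cool --fithic-out fithic.txt
hicsr evaluate --a sim/truth.cool --b enhanced.cool --chrom chrS \
      --report report.json
hicsr tads --in enhanced.cool --chrom chrS --out tads.bed
```

The same experiment through the library (one seed) prints:

```
tile_ssim_downsampled:  0.197     # raw 1/16 input vs truth, 30 held-out tiles
tile_ssim_enhanced:     0.387     # enhanced output vs truth
genome_ssim_enhanced:   0.359     # mean SSIM over 1-Mb diagonal blocks
genome_ssim_downsampled: 0.209
psnr_enhanced_db:       16.7      # vs 11.8 dB for the raw input
tad_boundary_recall_noiseless_pct: 100.0
```

Read: on held-out chromosomes the trained generator roughly doubles the
structural similarity of the low-coverage map to the deeply-sequenced truth
(tile SSIM 0.20 → 0.39, +4.8 dB PSNR), and the insulation-score caller
recovers every planted TAD boundary within one bin on noiseless matrices.

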