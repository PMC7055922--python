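"""Similarity metrics between contact maps.

SSIM follows the classic windowed definition

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
                 / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

with local statistics taken under an 11x11 Gaussian window of standard
deviation 3, evaluated at every fully interior position ("valid" borders,
no padding) and averaged.  Both inputs are independently min-max rescaled to
[0, 1] first, so the score compares contrast and structure rather than
absolute luminance; C1 = (0.01 L)^2 and C2 = (0.03 L)^2 with dynamic range
L = 1.

PSNR is 10 * log10(1 / MSE) for [0, 1]-scaled matrices.  The per-distance
profile computes, for each genomic distance d, the Pearson correlation of
the two matrices' d-th diagonals (50 kb to 1 Mb by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import ContactMatrix


@dataclass(frozen=True)
class SSIMParams:
    window: int = 11
    gaussian_sigma: float = 3.0
    c1: float = 0.01 ** 2
    c2: float = 0.03 ** 2
    #: if True, read "variance value 3" as the kernel's variance rather than
    #: its standard deviation
    sigma_is_variance: bool = False

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.gaussian_sigma <= 0 or self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("sigma, C1, C2 must be positive")

    @property
    def sd(self) -> float:
        return (np.sqrt(self.gaussian_sigma) if self.sigma_is_variance
                else self.gaussian_sigma)


def gaussian_kernel(window: int, sd: float) -> np.ndarray:
    """Normalized 2-D Gaussian weights on a window x window grid."""
    half = window // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax ** 2) / (2.0 * sd * sd))
    k = np.outer(g1, g1)
    return k / k.sum()


def minmax_rescale(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def _windowed(a: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Gaussian-weighted local means at all valid positions."""
    w = kernel.shape[0]
    views = sliding_window_view(a, (w, w))
    return np.einsum("ijkl,kl->ij", views, kernel)


def ssim(a: np.ndarray, b: np.ndarray, p: SSIMParams = SSIMParams()) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch in ssim")
    if min(a.shape) < p.window:
        raise ValueError("matrix smaller than the SSIM window")
    x = minmax_rescale(a)
    y = minmax_rescale(b)
    k = gaussian_kernel(p.window, p.sd)
    mu_x = _windowed(x, k)
    mu_y = _windowed(y, k)
    sig_x = _windowed(x * x, k) - mu_x ** 2
    sig_y = _windowed(y * y, k) - mu_y ** 2
    sig_xy = _windowed(x * y, k) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + p.c1) * (2.0 * sig_xy + p.c2)
    den = (mu_x ** 2 + mu_y ** 2 + p.c1) * (sig_x + sig_y + p.c2)
    return float(np.mean(num / den))


def genome_ssim(a: ContactMatrix | np.ndarray, b: ContactMatrix | np.ndarray,
                block_bp: int = 1_000_000, bin_size: int | None = None,
                p: SSIMParams = SSIMParams()) -> float:
    """Mean SSIM over non-overlapping block_bp x block_bp diagonal squares.

    The trailing partial block is dropped; a matrix smaller than one block is
    scored as a single whole-matrix SSIM (with a warning).
    """
    if isinstance(a, ContactMatrix):
        bin_size = a.bin_size
        a = a.values
    if isinstance(b, ContactMatrix):
        b = b.values
    if bin_size is None:
        raise ValueError("bin_size required for plain arrays")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch in genome_ssim")
    block = block_bp // bin_size
    n = a.shape[0]
    if n < block:
        warnings.warn("matrix smaller than one block; scoring whole matrix")
        return ssim(a, b, p)
    scores = [
        ssim(a[s:s + block, s:s + block], b[s:s + block, s:s + block], p)
        for s in range(0, n - block + 1, block)
    ]
    return float(np.mean(scores))


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB for [0, 1]-scaled inputs."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch in psnr")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(1.0 / mse)


@dataclass
class DistanceProfile:
    distances: np.ndarray  # bp
    correlations: np.ndarray  # Pearson r, NaN where a diagonal is constant

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.int64)
        self.correlations = np.asarray(self.correlations, dtype=np.float64)
        if self.distances.shape != self.correlations.shape:
            raise ValueError("distances and correlations must align")

    def median(self) -> float:
        return float(np.nanmedian(self.correlations))


def per_distance_pearson(a: ContactMatrix | np.ndarray,
                         b: ContactMatrix | np.ndarray,
                         d_min: int = 50_000, d_max: int = 1_000_000,
                         bin_size: int | None = None) -> DistanceProfile:
    """Pearson correlation of the two maps' d-th diagonals for each genomic
    distance d in [d_min, d_max] stepping one bin."""
    if isinstance(a, ContactMatrix):
        bin_size = a.bin_size
        a = a.values
    if isinstance(b, ContactMatrix):
        b = b.values
    if bin_size is None:
        raise ValueError("bin_size required for plain arrays")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch in per_distance_pearson")
    n = a.shape[0]
    if d_max // bin_size >= n:
        warnings.warn("d_max exceeds the matrix span; truncating")
        d_max = (n - 1) * bin_size
    distances, corrs = [], []
    for k in range(d_min // bin_size, d_max // bin_size + 1):
        da = np.diagonal(a, k)
        db = np.diagonal(b, k)
        if da.size < 2 or np.all(da == da[0]) or np.all(db == db[0]):
            r = float("nan")
        else:
            r = float(np.corrcoef(da, db)[0, 1])
        distances.append(k * bin_size)
        corrs.append(r)
    return DistanceProfile(distances=np.array(distances),
                           correlations=np.array(corrs))
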