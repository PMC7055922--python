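"""Outlier clipping, [0,1] scaling, diagonal-band tiling and reconstruction.

Training and prediction operate on 40x40-bin tiles (0.4 Mb at 10-kb
resolution) cut from the upper triangle of the scaled contact map, keeping
only tiles whose grid origin lies within 2 Mb of the diagonal: most TADs and
significant interactions fall inside that band, so longer-range values are
never predicted.

Clipping cutoffs follow a fixed table calibrated on deeply sequenced 10-kb
human Hi-C: 255 for full-coverage targets, and 125/100/80/50/25 for inputs
downsampled to 1/10, 1/16, 1/25, 1/50 and 1/100 of the reads.  Any other
matrix falls back to the 99.9th percentile of its nonzero entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ContactMatrix
from .simulate import DownsampleRatio

TILE_SIZE = 40
BAND_BP = 2_000_000
TARGET_CUTOFF_10KB = 255.0

#: input cutoffs per downsampling ratio (10-kb resolution calibration)
INPUT_CUTOFFS = {
    1 / 10: 125.0,
    1 / 16: 100.0,
    1 / 25: 80.0,
    1 / 50: 50.0,
    1 / 100: 25.0,
}


@dataclass
class ScaledMatrix:
    """Min-max normalized contact map in [0, 1] with its clipping cutoff."""

    chrom: str
    bin_size: int
    values: np.ndarray
    cutoff: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.cutoff <= 0:
            raise ValueError("invalid cutoff")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("scaled values must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class TileSet:
    """Non-overlapping t x t tiles from the upper-triangle diagonal band."""

    tiles: list[np.ndarray]
    coords: list[tuple[int, int]]
    tile_size: int
    band_bp: int
    n_bins: int
    bin_size: int
    cutoff: float
    chrom: str = "?"

    def __post_init__(self):
        if len(self.tiles) != len(self.coords):
            raise ValueError("tiles and coords must align")
        if len(set(self.coords)) != len(self.coords):
            raise ValueError("duplicate tile")
        for t in self.tiles:
            if t.shape != (self.tile_size, self.tile_size):
                raise ValueError("every tile must be tile_size x tile_size")
        for (r0, c0) in self.coords:
            if r0 % self.tile_size or c0 % self.tile_size:
                raise ValueError("coords must lie on the tile-size grid")
            if c0 != r0 and (c0 - r0) * self.bin_size >= self.band_bp:
                raise ValueError("tile outside the diagonal band")

    def __len__(self) -> int:
        return len(self.tiles)

    def stack(self) -> np.ndarray:
        """(N, 1, t, t) array for batched network input."""
        return np.stack(self.tiles)[:, None, :, :]


def resolve_cutoff(m: ContactMatrix, role: str,
                   ratio: DownsampleRatio | float | None = None) -> float:
    """Clipping cutoff for a matrix by role.

    Full-coverage 10-kb targets use the fixed value 255; tabled downsampling
    ratios use the fixed per-ratio input cutoffs; anything else uses the
    99.9th percentile of the matrix's nonzero entries.
    """
    if role not in ("target", "input"):
        raise ValueError("role must be 'target' or 'input'")
    if role == "target" and m.bin_size == 10_000:
        return TARGET_CUTOFF_10KB
    if role == "input" and ratio is not None:
        r = ratio.ratio if isinstance(ratio, DownsampleRatio) else float(ratio)
        for key, value in INPUT_CUTOFFS.items():
            if abs(r - key) < 1e-12:
                return value
    nonzero = m.values[m.values > 0]
    if nonzero.size == 0:
        raise ValueError("cannot compute percentile: matrix has no nonzero entries")
    return float(np.percentile(nonzero, 99.9))


def clip_scale(m: ContactMatrix, cutoff: float) -> ScaledMatrix:
    """``out_ij = min(M_ij, cutoff) / cutoff``."""
    if cutoff <= 0:
        raise ValueError("invalid cutoff")
    values = np.minimum(m.values, cutoff) / cutoff
    return ScaledMatrix(chrom=m.chrom, bin_size=m.bin_size, values=values,
                        cutoff=float(cutoff))


def tile(s: ScaledMatrix, tile_size: int = TILE_SIZE,
         band_bp: int = BAND_BP) -> TileSet:
    """Cut the scaled map into the upper-triangle diagonal-band tile grid.

    The matrix is zero-padded to a multiple of ``tile_size``; a grid block
    with origin (r0, c0) is kept iff ``c0 >= r0`` and
    ``(c0 - r0) * bin_size < band_bp``.  Diagonal blocks are always kept.
    Tiles are ordered by (r0, c0).
    """
    if tile_size < 2:
        raise ValueError("tile_size must be >= 2")
    if band_bp < tile_size * s.bin_size:
        warnings.warn("band narrower than one tile; only diagonal tiles kept")
    n = s.n_bins
    n_pad = -(-n // tile_size) * tile_size
    padded = np.zeros((n_pad, n_pad))
    padded[:n, :n] = s.values
    tiles, coords = [], []
    for r0 in range(0, n_pad, tile_size):
        for c0 in range(r0, n_pad, tile_size):
            if c0 > r0 and (c0 - r0) * s.bin_size >= band_bp:
                break
            tiles.append(padded[r0:r0 + tile_size, c0:c0 + tile_size].copy())
            coords.append((r0, c0))
    return TileSet(tiles=tiles, coords=coords, tile_size=tile_size,
                   band_bp=band_bp, n_bins=n, bin_size=s.bin_size,
                   cutoff=s.cutoff, chrom=s.chrom)


def reconstruct(ts: TileSet, background: np.ndarray | None = None
                ) -> ScaledMatrix:
    """Merge tiles back into a symmetric chromosome-wide map.

    Off-diagonal tiles are mirrored across the main diagonal and diagonal
    tiles are symmetrized.  Entries not covered by any tile (outside the
    band) are taken from ``background`` when given (e.g. the scaled input
    map, so no long-range value is fabricated) and are zero otherwise.
    Padding beyond ``n_bins`` is cropped.
    """
    t = ts.tile_size
    n_pad = -(-ts.n_bins // t) * t
    out = np.zeros((n_pad, n_pad))
    covered = np.zeros((n_pad, n_pad), dtype=bool)
    for block, (r0, c0) in zip(ts.tiles, ts.coords):
        if r0 == c0:
            out[r0:r0 + t, c0:c0 + t] = (block + block.T) / 2.0
        else:
            out[r0:r0 + t, c0:c0 + t] = block
            out[c0:c0 + t, r0:r0 + t] = block.T
            covered[c0:c0 + t, r0:r0 + t] = True
        covered[r0:r0 + t, c0:c0 + t] = True
    values = out[:ts.n_bins, :ts.n_bins]
    covered = covered[:ts.n_bins, :ts.n_bins]
    if background is not None:
        bg = (background + background.T) / 2.0
        values = np.where(covered, values, bg)
    return ScaledMatrix(chrom=ts.chrom, bin_size=ts.bin_size,
                        values=np.clip(values, 0.0, 1.0), cutoff=ts.cutoff)


def to_fithic_counts(s: ScaledMatrix) -> ContactMatrix:
    """Integer counts for significant-interaction calling: round-half-up of
    ``255 * value``."""
    counts = np.floor(255.0 * s.values + 0.5)
    return ContactMatrix(chrom=s.chrom, bin_size=s.bin_size, values=counts)
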