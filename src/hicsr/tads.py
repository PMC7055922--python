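"""Insulation-score TAD-boundary calling and segmentation comparison.

The insulation score of bin *i* is the mean contact count in the w x w
square crossing the diagonal at *i* (rows i-w..i-1, columns i+1..i+w,
diagonal excluded), here with w = 5 bins — five times the matrix resolution,
chosen to resolve fine domain structure.  Scores are normalized as
log2(raw_i / mean raw) over valid bins.  The delta score is the mean
insulation of the 5 nearest loci downstream minus the 5 nearest upstream;
insulation minima (candidate boundaries) are then zero-points of delta
inside ascending intervals, i.e. bins where delta crosses from <= 0 to > 0.

TADs are the regions between centers of adjacent boundary bins; any TAD
containing a low-coverage (zero-marginal) bin is discarded.  Two boundary
segmentations S and T are compared by the distance of each split point of S
to its nearest split point of T, and by the best Jaccard overlap of each
S-interval with any T-interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ContactMatrix

WINDOW_BINS = 5
DELTA_SPAN = 5


@dataclass
class InsulationTrack:
    insulation: np.ndarray  # normalized log2 insulation, NaN where invalid
    valid: np.ndarray  # per-bin validity mask
    window_bins: int = WINDOW_BINS
    delta_span: int = DELTA_SPAN
    delta: np.ndarray | None = None  # filled by delta_score
    delta_valid: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.insulation.shape[0]


@dataclass
class Segmentation:
    """Ordered TAD-boundary split points over [0, n_bins]."""

    split_points: np.ndarray
    n_bins: int

    def __post_init__(self):
        self.split_points = np.asarray(self.split_points, dtype=np.int64)
        s = self.split_points
        if s.size and (np.any(np.diff(s) <= 0) or s[0] < 0 or s[-1] > self.n_bins):
            raise ValueError("split points must be strictly increasing in "
                             "[0, n_bins]")

    def intervals(self) -> list[tuple[int, int]]:
        s = self.split_points
        return [(int(a), int(b)) for a, b in zip(s, s[1:])]

    def __len__(self) -> int:
        return int(self.split_points.size)


def low_coverage_mask(m: ContactMatrix, quantile: float = 0.0) -> np.ndarray:
    """Bins with zero marginal count (or below the given quantile of
    marginals) are flagged as low coverage."""
    marginals = m.values.sum(axis=0)
    if quantile > 0:
        thr = np.quantile(marginals, quantile)
        return marginals <= thr
    return marginals == 0


def insulation_score(m: ContactMatrix, window_bins: int = WINDOW_BINS,
                     low_coverage_quantile: float = 0.0) -> InsulationTrack:
    """Normalized insulation track; delta is left unfilled.

    Invalid bins: within ``window_bins`` of either chromosome end,
    low-coverage bins, and bins whose raw window mean is zero (log
    undefined).
    """
    n = m.n_bins
    w = int(window_bins)
    if n <= 2 * w:
        raise ValueError("window too large for this matrix")
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        raw[i] = m.values[i - w:i, i + 1:i + w + 1].mean()
    valid = ~np.isnan(raw)
    valid &= ~low_coverage_mask(m, low_coverage_quantile)
    valid &= ~(raw == 0)  # log2 undefined; effectively a coverage gap
    mean_raw = raw[valid].mean() if valid.any() else np.nan
    insulation = np.full(n, np.nan)
    insulation[valid] = np.log2(raw[valid] / mean_raw)
    return InsulationTrack(insulation=insulation, valid=valid,
                           window_bins=w)


def delta_score(t: InsulationTrack) -> InsulationTrack:
    """Fill ``t.delta``: mean insulation over the ``delta_span`` loci
    downstream minus the mean over the span upstream, masked wherever any
    contributing bin is invalid or out of range."""
    n = t.n_bins
    span = t.delta_span
    delta = np.full(n, np.nan)
    dvalid = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = i - span, i + span
        if lo < 0 or hi >= n:
            continue
        up = slice(i - span, i)
        down = slice(i + 1, i + span + 1)
        if not (t.valid[up].all() and t.valid[down].all()):
            continue
        delta[i] = t.insulation[down].mean() - t.insulation[up].mean()
        dvalid[i] = True
    t.delta = delta
    t.delta_valid = dvalid
    return t


def find_boundaries(t: InsulationTrack) -> Segmentation:
    """Zero-points of delta within ascending intervals.

    A boundary sits at bin i when delta(i) <= 0 < delta(i+1) with both bins
    valid; a run of exact zeros resolves to its last bin.
    """
    if t.delta is None:
        raise ValueError("delta not computed; call delta_score first")
    d, v = t.delta, t.delta_valid
    bounds = [
        i for i in range(t.n_bins - 1)
        if v[i] and v[i + 1] and d[i] <= 0.0 < d[i + 1]
    ]
    return Segmentation(split_points=np.array(bounds, dtype=np.int64),
                        n_bins=t.n_bins)


def call_tads(s: Segmentation, valid: np.ndarray | None = None
              ) -> list[tuple[int, int]]:
    """TADs between centers of adjacent boundary bins; any TAD containing an
    excluded (invalid / low-coverage) bin is dropped."""
    if len(s) < 2:
        return []
    tads = []
    pts = s.split_points
    for a, b in zip(pts, pts[1:]):
        if valid is not None and not np.all(valid[a:b + 1]):
            continue
        tads.append((int(a), int(b)))
    return tads


def boundary_distances(s: Segmentation, t: Segmentation) -> np.ndarray:
    """For each split point of S, the distance (in bins) to the nearest
    split point of T."""
    if len(t) == 0:
        raise ValueError("reference segmentation T is empty")
    if len(s) == 0:
        raise ValueError("segmentation S is empty")
    return np.array([
        int(np.min(np.abs(t.split_points - si))) for si in s.split_points
    ])


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def interval_overlap(s: Segmentation, t: Segmentation) -> np.ndarray:
    """For each S-interval, the best Jaccard index against any T-interval."""
    if len(s) < 2 or len(t) < 2:
        raise ValueError("segmentations need >= 2 split points")
    t_iv = t.intervals()
    out = []
    for iv in s.intervals():
        if iv[1] - iv[0] == 0:
            warnings.warn("degenerate zero-length interval skipped")
            continue
        out.append(max(_jaccard(iv, jv) for jv in t_iv))
    return np.array(out)
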