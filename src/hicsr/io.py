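"""Contact-matrix container and file formats.

A Hi-C experiment is summarised per chromosome as a symmetric matrix
``M[i, j]`` of read-pair counts between fixed-size genomic bins (0-based,
half-open; bin *i* spans ``[i*bin_size, (i+1)*bin_size)``).  Only
intra-chromosomal maps are modelled.

Three on-disk representations are supported, keyed by file extension:

``.cool``
    Single-resolution cooler-schema HDF5 (groups ``chroms``, ``bins``,
    ``pixels``, ``indexes``), written with h5py.  Upper-triangle pixels only.
``.npz``
    Dense archive with one named array per chromosome.
``.txt`` / ``.tsv``
    Whitespace-delimited triplet text ``bin_i bin_j count`` with 0-based bin
    indices; the upper triangle (including the diagonal) is sufficient and is
    what the writer emits.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

_SYM_TOL = 1e-9


@dataclass
class ContactMatrix:
    """Symmetric non-negative intra-chromosomal contact-count matrix."""

    chrom: str
    bin_size: int
    values: np.ndarray
    n_bins: int = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.values.shape[0] < 1:
            raise ValueError("n_bins must be >= 1")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if np.any(self.values < 0):
            raise ValueError("invalid counts: negative entries")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("contact matrix must be symmetric")
        self.n_bins = self.values.shape[0]

    @property
    def is_integer(self) -> bool:
        return bool(np.all(self.values == np.floor(self.values)))

    def total(self) -> float:
        return float(self.values.sum())

    def nonzero_fraction(self) -> float:
        return float(np.count_nonzero(self.values)) / self.values.size


def symmetrize(values: np.ndarray) -> np.ndarray:
    """Mirror the upper triangle (incl. diagonal) onto the lower.

    Idempotent on already-symmetric input.
    """
    upper = np.triu(values)
    return upper + np.triu(values, k=1).T


def _format_of(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".cool":
        return "cool"
    if ext == ".npz":
        return "npz"
    if ext in (".txt", ".tsv"):
        return "triplet"
    raise ValueError(f"unsupported format: {ext!r}")


# ---------------------------------------------------------------------------
# triplet text
# ---------------------------------------------------------------------------

def _read_triplet(path: str, n_bins: int | None) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # empty file is legal
        data = np.loadtxt(path, ndmin=2, dtype=np.float64)
    if data.size == 0:
        if n_bins is None:
            raise ValueError("empty triplet file and no n_bins given")
        return np.zeros((n_bins, n_bins))
    if data.shape[1] != 3:
        raise ValueError("triplet text must have 3 columns: bin_i bin_j count")
    i = data[:, 0].astype(np.int64)
    j = data[:, 1].astype(np.int64)
    c = data[:, 2]
    if np.any(c < 0):
        raise ValueError("invalid counts: negative entries")
    n = int(max(i.max(), j.max())) + 1 if n_bins is None else int(n_bins)
    m = np.zeros((n, n))
    np.add.at(m, (np.minimum(i, j), np.maximum(i, j)), c)
    return symmetrize(m)


def _write_triplet(m: ContactMatrix, path: str) -> None:
    i, j = np.nonzero(np.triu(m.values))
    c = m.values[i, j]
    with open(path, "w") as fh:
        if m.is_integer:
            for a, b, v in zip(i, j, c):
                fh.write(f"{a}\t{b}\t{int(v)}\n")
        else:
            for a, b, v in zip(i, j, c):
                fh.write(f"{a}\t{b}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# dense archive (.npz)
# ---------------------------------------------------------------------------

def _read_npz(path: str, chrom: str, n_bins: int | None) -> np.ndarray:
    with np.load(path) as archive:
        if chrom not in archive.files:
            raise KeyError(f"chromosome not found: {chrom!r}")
        values = np.asarray(archive[chrom], dtype=np.float64)
    if np.any(values < 0):
        raise ValueError("invalid counts: negative entries")
    return symmetrize(values)


def _write_npz(m: ContactMatrix, path: str) -> None:
    arrays = {}
    if os.path.exists(path):  # extend an existing archive
        with np.load(path) as archive:
            arrays = {k: archive[k] for k in archive.files}
    arrays[m.chrom] = m.values
    np.savez(path, **arrays)


# ---------------------------------------------------------------------------
# cooler-schema HDF5 (.cool)
# ---------------------------------------------------------------------------

def _read_cool(path: str, chrom: str) -> tuple[np.ndarray, int]:
    with h5py.File(path, "r") as fh:
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in fh["chroms/name"][:]
        ]
        if chrom not in names:
            raise KeyError(f"chromosome not found: {chrom!r}")
        cid = names.index(chrom)
        bin_chrom = fh["bins/chrom"][:]
        sel = np.nonzero(bin_chrom == cid)[0]
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        n = hi - lo
        starts = fh["bins/start"][lo:lo + 2]
        bin_size = int(starts[1] - starts[0]) if n > 1 else int(
            fh.attrs.get("bin-size", fh["bins/end"][lo] - fh["bins/start"][lo])
        )
        b1 = fh["pixels/bin1_id"][:]
        b2 = fh["pixels/bin2_id"][:]
        cnt = fh["pixels/count"][:].astype(np.float64)
        keep = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        m = np.zeros((n, n))
        i = b1[keep] - lo
        j = b2[keep] - lo
        np.add.at(m, (np.minimum(i, j), np.maximum(i, j)), cnt[keep])
    if np.any(m < 0):
        raise ValueError("invalid counts: negative entries")
    return symmetrize(m), bin_size


def _write_cool(m: ContactMatrix, path: str) -> None:
    i, j = np.nonzero(np.triu(m.values))
    c = m.values[i, j]
    n = m.n_bins
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "HDF5::Cooler"
        fh.attrs["format-version"] = 3
        fh.attrs["bin-type"] = "fixed"
        fh.attrs["bin-size"] = m.bin_size
        fh.attrs["nbins"] = n
        fh.attrs["nchroms"] = 1
        fh.attrs["nnz"] = len(c)
        fh.attrs["symmetric-upper"] = True
        chroms = fh.create_group("chroms")
        chroms.create_dataset("name", data=np.array([m.chrom], dtype="S32"))
        chroms.create_dataset("length", data=np.array([n * m.bin_size], dtype=np.int64))
        bins = fh.create_group("bins")
        bins.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
        bins.create_dataset(
            "start", data=np.arange(n, dtype=np.int64) * m.bin_size
        )
        bins.create_dataset(
            "end", data=(np.arange(n, dtype=np.int64) + 1) * m.bin_size
        )
        pixels = fh.create_group("pixels")
        pixels.create_dataset("bin1_id", data=i.astype(np.int64))
        pixels.create_dataset("bin2_id", data=j.astype(np.int64))
        if m.is_integer:
            pixels.create_dataset("count", data=c.astype(np.int64))
        else:
            pixels.create_dataset("count", data=c)
        indexes = fh.create_group("indexes")
        bin1_offset = np.searchsorted(i, np.arange(n + 1), side="left")
        indexes.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))
        indexes.create_dataset("chrom_offset", data=np.array([0, n], dtype=np.int64))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_contact_matrix(path: str, chrom: str, bin_size: int,
                        n_bins: int | None = None) -> ContactMatrix:
    """Read a contact matrix from any supported format.

    ``n_bins`` forces the matrix dimension for triplet text (where trailing
    empty bins are otherwise unobservable); it is checked against the file
    for the self-describing formats.
    """
    fmt = _format_of(path)
    if fmt == "triplet":
        values = _read_triplet(path, n_bins)
    elif fmt == "npz":
        values = _read_npz(path, chrom, n_bins)
    else:
        values, file_bin_size = _read_cool(path, chrom)
        if bin_size and file_bin_size and bin_size != file_bin_size:
            raise ValueError(
                f"bin_size mismatch: requested {bin_size}, file has {file_bin_size}"
            )
    if n_bins is not None and values.shape[0] != n_bins:
        if values.shape[0] < n_bins:  # pad trailing missing bins with zeros
            padded = np.zeros((n_bins, n_bins))
            padded[: values.shape[0], : values.shape[0]] = values
            values = padded
        else:
            raise ValueError(
                f"matrix has {values.shape[0]} bins, expected {n_bins}"
            )
    return ContactMatrix(chrom=chrom, bin_size=bin_size, values=values)


def write_contact_matrix(m: ContactMatrix, path: str,
                         format: str | None = None) -> None:
    """Write ``m`` to ``path``; the format defaults to the extension."""
    fmt = format if format is not None else _format_of(path)
    if fmt == "triplet":
        _write_triplet(m, path)
    elif fmt == "npz":
        _write_npz(m, path)
    elif fmt == "cool":
        _write_cool(m, path)
    else:
        raise ValueError(f"unsupported format: {fmt!r}")
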