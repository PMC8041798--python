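"""Loading, filtering and normalization of peak-by-cell count matrices.

The central objects are :class:`RawCountMatrix` (sparse non-negative
integer counts, peaks as rows and cells as columns) and
:class:`NormalizedMatrix` (the TF-IDF-transformed real matrix ``Y`` that
the latent-variable model consumes).  All operations preserve the
peaks-by-cells orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PeakSet",
    "RawCountMatrix",
    "NormalizedMatrix",
    "select_features",
    "tfidf_transform",
    "downsample_counts",
]


@dataclass
class PeakSet:
    """A set of genomic intervals (0-based, half-open) used as features.

    Parameters
    ----------
    chrom, start, end
        Coordinate arrays, one entry per peak.
    ids
        Unique peak identifiers; autogenerated as ``chrom:start-end`` when
        omitted.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if not (len(self.chrom) == len(self.start) == len(self.end)):
            raise ValueError("chrom/start/end lengths differ")
        if np.any(self.start >= self.end):
            bad = int(np.argmax(self.start >= self.end))
            raise ValueError(
                f"peak {bad} has start >= end ({self.start[bad]} >= {self.end[bad]})"
            )
        if self.ids is None:
            self.ids = np.array(
                [f"{c}:{s}-{e}" for c, s, e in zip(self.chrom, self.start, self.end)],
                dtype=object,
            )
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if len(self.ids) != len(self.chrom):
                raise ValueError("ids length differs from coordinates")
            if len(set(self.ids)) != len(self.ids):
                raise ValueError("peak ids are not unique")

    def __len__(self) -> int:
        return len(self.chrom)

    def subset(self, mask_or_index) -> "PeakSet":
        idx = np.asarray(mask_or_index)
        return PeakSet(self.chrom[idx], self.start[idx], self.end[idx], self.ids[idx])


@dataclass
class RawCountMatrix:
    """Peaks x cells non-negative integer counts with peak/cell metadata."""

    counts: sp.csr_matrix
    peaks: PeakSet
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        p, n = self.counts.shape
        if len(self.peaks) != p:
            raise ValueError(f"{len(self.peaks)} peaks but {p} count rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids but {n} count columns")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """Real-valued peaks x cells matrix Y (zeros of the counts stay zero)."""

    values: sp.csr_matrix
    source_peaks: PeakSet
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not np.all(np.isfinite(self.values.data)):
            raise ValueError("normalized matrix contains non-finite entries")

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=np.float64)


def select_features(
    counts: RawCountMatrix, min_cell_fraction: float = 0.03
) -> tuple[RawCountMatrix, np.ndarray]:
    """Keep peaks with a nonzero count in at least ``min_cell_fraction`` of cells.

    The bound is inclusive: a peak detected in exactly ``ceil-free``
    fraction ``min_cell_fraction`` of the cells is retained (default 3%).

    Returns
    -------
    (filtered, mask)
        The filtered matrix (peak order preserved) and a boolean mask of
        length ``n_peaks`` marking retained peaks.
    """
    if not (0 < min_cell_fraction <= 1):
        raise ValueError(f"min_cell_fraction must be in (0, 1], got {min_cell_fraction}")
    n = counts.n_cells
    if n < 1:
        raise ValueError("count matrix has no cells")
    df = counts.counts.getnnz(axis=1)
    mask = df / n >= min_cell_fraction
    if not mask.any():
        raise ValueError(
            f"no peak has nonzero counts in >= {min_cell_fraction:.3g} of {n} cells"
        )
    filtered = RawCountMatrix(
        counts.counts[mask], counts.peaks.subset(mask), counts.cell_ids
    )
    return filtered, mask


def tfidf_transform(counts: RawCountMatrix, binarize: bool = True) -> NormalizedMatrix:
    """TF-IDF normalization of a peak count matrix.

    With ``binarize`` (default) the matrix is first reduced to
    peak-accessibility indicators, so ``TF(i, j)`` is 1 over the number of
    accessible peaks in cell ``j`` wherever peak ``i`` is open — the term
    frequency over accessible regions.  Binarization reflects the
    near-binary nature of single-cell accessibility and removes the heavy
    tail that read-count fluctuations at high-weight peaks would otherwise
    inject.  With ``binarize=False``, ``TF(i, j) = count(i, j) /
    depth(j)`` uses the quantitative counts.

    Either way ``IDF(i) = log(1 + n / df(i))`` (natural log; ``df`` the
    number of cells where peak ``i`` is detected) upweights peaks that are
    open in few cells, which tend to discriminate cell types; the ``1 +``
    smoothing keeps ubiquitous peaks at a positive weight.  Zero counts map
    to zero values, and both dialects are invariant to per-cell depth
    scaling.
    """
    mat = counts.counts.tocsc()
    if binarize:
        mat = mat.copy()
        mat.data = np.ones_like(mat.data)
    depth = np.asarray(mat.sum(axis=0)).ravel()
    if np.any(depth == 0):
        bad = counts.cell_ids[depth == 0]
        raise ValueError(
            "cells with zero total count cannot be depth-normalized: "
            + ", ".join(map(str, bad[:10]))
            + ("..." if len(bad) > 10 else "")
        )
    df = mat.getnnz(axis=1)
    if np.any(df == 0):
        raise ValueError(
            f"{int((df == 0).sum())} peaks are detected in no cell; "
            "run select_features first"
        )
    n = counts.n_cells
    idf = np.log1p(n / df)
    tf = mat.astype(np.float64).multiply(1.0 / depth)  # column scaling
    values = sp.csr_matrix(tf.multiply(idf[:, None]))
    return NormalizedMatrix(values, counts.peaks, counts.cell_ids)


def downsample_counts(
    counts: RawCountMatrix, dropout_rate: float, seed: int
) -> RawCountMatrix:
    """Set each nonzero entry to zero independently with ``dropout_rate``.

    Emulates reduced coverage; zero entries are untouched and the result is
    deterministic given ``seed``.
    """
    if not (0 <= dropout_rate <= 1):
        raise ValueError(f"dropout_rate must be in [0, 1], got {dropout_rate}")
    out = counts.counts.copy().tocsr()
    if dropout_rate > 0 and out.nnz:
        rng = np.random.default_rng(seed)
        drop = rng.random(out.nnz) < dropout_rate
        out.data[drop] = 0
        out.eliminate_zeros()
    return RawCountMatrix(out, counts.peaks, counts.cell_ids)
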