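"""Reference construction and the fixed projection basis W1.

A reference is a small samples-by-peaks matrix of accessibility profiles
for known cell types or tissues: scaled bulk counts, overlap counts
derived from BED peak calls, or pseudo-bulk averages of labeled single
cells.  PCA on the reference yields the orthonormal loading matrix ``W1``
that anchors the shared-variation component of the model; projecting
single cells onto ``W1`` alone is the bulk-projection baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ra3.preprocess import PeakSet, RawCountMatrix, NormalizedMatrix
from ra3.io import read_bed

__all__ = [
    "ReferenceSampleSet",
    "ProjectionBasis",
    "scale_by_depth",
    "aggregate_pseudobulk",
    "bed_overlap_reference",
    "learn_projection",
    "bulk_project",
    "map_counts_to_reference_peaks",
]


@dataclass
class ReferenceSampleSet:
    """Reference samples x peaks matrix, peaks matched to the single-cell data."""

    values: np.ndarray  # m x p
    sample_ids: np.ndarray
    provenance: str  # bulk_counts | bed_overlap | pseudo_bulk

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("reference matrix must be 2-D (samples x peaks)")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length differs from row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference matrix contains non-finite entries")
        if self.values.min(initial=0.0) < 0:
            raise ValueError("reference matrix must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class ProjectionBasis:
    """Orthonormal PCA loadings W1 (p x K1) learned from a reference."""

    W1: np.ndarray
    K1: int
    explained_variance: np.ndarray
    full_W: np.ndarray = None  # all min(m-1, p) components, for re-capping
    full_explained_variance: np.ndarray = None

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        g = self.W1.T @ self.W1
        if not np.allclose(g, np.eye(self.K1), atol=1e-8):
            raise ValueError("W1 columns are not orthonormal")

    def with_cap(self, k1_cap: int) -> "ProjectionBasis":
        """Re-derive a basis with a different component cap (no recomputation)."""
        if self.full_W is None:
            raise ValueError("full basis not stored")
        k = min(k1_cap, self.full_W.shape[1])
        return ProjectionBasis(
            self.full_W[:, :k],
            k,
            self.full_explained_variance[:k],
            self.full_W,
            self.full_explained_variance,
        )


def scale_by_depth(
    bulk_counts: np.ndarray,
    total_mapped_reads: np.ndarray,
    sample_ids=None,
) -> ReferenceSampleSet:
    """Scale each bulk sample's peak counts by its total mapped reads."""
    counts = np.asarray(bulk_counts, dtype=np.float64)
    totals = np.asarray(total_mapped_reads, dtype=np.float64)
    if counts.ndim != 2 or len(totals) != counts.shape[0]:
        raise ValueError("need one total per bulk sample row")
    if np.any(totals <= 0):
        raise ValueError("total mapped reads must be positive for every sample")
    if sample_ids is None:
        sample_ids = [f"bulk_{i}" for i in range(counts.shape[0])]
    return ReferenceSampleSet(counts / totals[:, None], sample_ids, "bulk_counts")


def aggregate_pseudobulk(
    sc_counts: RawCountMatrix, labels
) -> ReferenceSampleSet:
    """Average (not sum) labeled single cells per type into pseudo-bulk rows.

    Averaging removes the cell-type abundance bias a summed aggregate would
    carry; duplicating cells of a type leaves its row unchanged.  Sample
    ids are the sorted distinct labels.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != sc_counts.n_cells:
        raise ValueError("one label per cell required")
    uniq = sorted(set(labels))
    rows = []
    for lab in uniq:
        cells = np.flatnonzero(labels == lab)
        if len(cells) == 0:
            raise ValueError(f"label {lab!r} has no cells")
        rows.append(
            np.asarray(sc_counts.counts[:, cells].mean(axis=1)).ravel()
        )
    return ReferenceSampleSet(np.vstack(rows), uniq, "pseudo_bulk")


def _overlap_counts(
    q_chrom, q_start, q_end, s_chrom, s_start, s_end
) -> np.ndarray:
    """For each query interval, count subject intervals overlapping by >= 1 bp.

    Half-open semantics: [a, b) and [c, d) overlap iff a < d and c < b.
    Per chromosome the overlapping subjects are exactly those with
    ``start < q_end`` minus those with ``end <= q_start`` (the latter set is
    contained in the former for sorted arrays), so two searchsorted passes
    suffice.
    """
    out = np.zeros(len(q_start), dtype=np.int64)
    s_chrom = np.asarray(s_chrom, dtype=object)
    for chrom in set(q_chrom):
        qi = np.flatnonzero(np.asarray(q_chrom, dtype=object) == chrom)
        si = np.flatnonzero(s_chrom == chrom)
        if len(si) == 0:
            continue
        starts = np.sort(np.asarray(s_start)[si])
        ends = np.sort(np.asarray(s_end)[si])
        n_start_before = np.searchsorted(starts, np.asarray(q_end)[qi], side="left")
        n_end_before = np.searchsorted(ends, np.asarray(q_start)[qi], side="right")
        out[qi] = n_start_before - n_end_before
    return out


def bed_overlap_reference(
    sc_peaks: PeakSet, sample_bed_paths: list[str | Path], sample_ids=None
) -> ReferenceSampleSet:
    """Build a reference row per BED file by counting its peaks that overlap
    each single-cell peak (>= 1 bp, half-open coordinates, strand ignored)."""
    paths = [Path(p) for p in sample_bed_paths]
    if sample_ids is None:
        sample_ids = [p.stem for p in paths]
    rows = []
    for path in paths:
        bed = read_bed(path)
        rows.append(
            _overlap_counts(
                sc_peaks.chrom, sc_peaks.start, sc_peaks.end,
                bed.chrom, bed.start, bed.end,
            ).astype(np.float64)
        )
    return ReferenceSampleSet(np.vstack(rows), sample_ids, "bed_overlap")


def map_counts_to_reference_peaks(
    sc_fragment_counts: RawCountMatrix, ref_peaks: PeakSet
) -> RawCountMatrix:
    """Re-bin single-cell peak counts onto a reference peak set.

    Each source peak's counts are added to every reference peak it overlaps
    by >= 1 bp; a source peak spanning two reference peaks therefore
    contributes to both (counts are duplicated, not split).
    """
    import scipy.sparse as sp

    src = sc_fragment_counts.peaks
    pairs_r, pairs_s = [], []
    ref_chrom = np.asarray(ref_peaks.chrom, dtype=object)
    for chrom in set(src.chrom):
        si = np.flatnonzero(np.asarray(src.chrom, dtype=object) == chrom)
        ri = np.flatnonzero(ref_chrom == chrom)
        if len(ri) == 0:
            continue
        order = np.argsort(ref_peaks.start[ri])
        ri = ri[order]
        r_start, r_end = ref_peaks.start[ri], ref_peaks.end[ri]
        for s in si:
            lo = np.searchsorted(r_start, src.end[s], side="left")
            hits = np.flatnonzero(r_end[:lo] > src.start[s])
            pairs_r.extend(ri[hits])
            pairs_s.extend([s] * len(hits))
    assign = sp.csr_matrix(
        (np.ones(len(pairs_r)), (pairs_r, pairs_s)),
        shape=(len(ref_peaks), len(src)),
    )
    out = sp.csr_matrix(assign @ sc_fragment_counts.counts)
    return RawCountMatrix(out.astype(np.int64), ref_peaks, sc_fragment_counts.cell_ids)


def learn_projection(ref: ReferenceSampleSet, k1_cap: int = 30) -> ProjectionBasis:
    """PCA on the reference matrix; returns the top-``K1`` loading columns.

    Reference rows are mean-centered per peak across samples before the
    decomposition, so ``K1 = min(m - 1, p, k1_cap)`` (the default cap of 30
    components covers large compendium references).  The full basis is kept
    on the result so the cap can be changed without recomputation.
    """
    m, p = ref.values.shape
    if m < 2:
        raise ValueError("need at least two reference samples for PCA")
    centered = ref.values - ref.values.mean(axis=0, keepdims=True)
    # SVD of the m x p centered matrix; right singular vectors are loadings
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("reference matrix is constant across samples (rank 0)")
    k_full = min(m - 1, p)
    full_W = vt[:k_full].T
    full_ev = s[:k_full] ** 2 / (m - 1)
    k1 = min(k_full, k1_cap)
    return ProjectionBasis(full_W[:, :k1], k1, full_ev[:k1], full_W, full_ev)


def bulk_project(Y: NormalizedMatrix, basis: ProjectionBasis) -> np.ndarray:
    """Project normalized single-cell profiles onto the reference basis: W1' Y.

    This is the bulk-projection baseline: only variation captured by the
    reference survives the projection.
    """
    if Y.values.shape[0] != basis.W1.shape[0]:
        raise ValueError(
            f"peak spaces differ: Y has {Y.values.shape[0]} peaks, "
            f"basis has {basis.W1.shape[0]}"
        )
    return np.asarray((Y.values.T @ basis.W1).T)
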