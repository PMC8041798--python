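"""Readers and writers for the on-disk formats the tool exchanges.

Count matrices travel as a trio: Matrix Market (``.mtx``, peaks x cells),
a BED3+ peak file (0-based, half-open) and a one-barcode-per-line TSV.
References and fitted models are stored in HDF5; latent representations
and cluster labels as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

import ra3.preprocess as pp

__all__ = [
    "read_bed",
    "write_bed",
    "read_count_trio",
    "write_count_trio",
    "read_covariates",
    "read_labels",
    "save_basis",
    "load_basis",
    "save_fit",
    "write_latent_tsv",
]


def read_bed(path: str | Path) -> pp.PeakSet:
    """Parse a BED3+ file into a :class:`~ra3.preprocess.PeakSet`.

    Only the first three columns are required; a fourth column, when
    present, supplies peak ids.  Malformed lines raise with the file and
    1-based line number.
    """
    path = Path(path)
    chroms, starts, ends, ids = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, "
                    f"{fields[2]!r}"
                ) from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            if len(fields) >= 4:
                ids.append(fields[3])
    return pp.PeakSet(
        np.array(chroms, dtype=object),
        np.array(starts),
        np.array(ends),
        np.array(ids, dtype=object) if len(ids) == len(chroms) else None,
    )


def write_bed(peaks: pp.PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e, i in zip(peaks.chrom, peaks.start, peaks.end, peaks.ids):
            fh.write(f"{c}\t{s}\t{e}\t{i}\n")


def read_count_trio(
    mtx: str | Path, bed: str | Path, barcodes: str | Path
) -> pp.RawCountMatrix:
    """Load the (.mtx, .bed, barcode .tsv) trio as a RawCountMatrix."""
    counts = sp.csr_matrix(mmread(str(mtx)))
    peaks = read_bed(bed)
    cells = [ln.strip().split("\t")[0] for ln in open(barcodes) if ln.strip()]
    return pp.RawCountMatrix(counts.astype(np.int64), peaks, np.array(cells, dtype=object))


def write_count_trio(counts: pp.RawCountMatrix, outdir: str | Path, prefix: str = "matrix") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": outdir / f"{prefix}.mtx",
        "bed": outdir / f"{prefix}.peaks.bed",
        "barcodes": outdir / f"{prefix}.barcodes.tsv",
    }
    mmwrite(str(paths["mtx"]), counts.counts.tocoo())
    write_bed(counts.peaks, paths["bed"])
    with open(paths["barcodes"], "w") as fh:
        fh.write("\n".join(map(str, counts.cell_ids)) + "\n")
    return paths


def read_covariates(path: str | Path, cell_ids) -> "np.ndarray":
    """Read a cell_id<TAB>value covariate table and one-hot encode it.

    Returns a q x n design matrix whose first row is the intercept; the
    first level of each categorical covariate is absorbed into it.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"{len(missing)} cells missing from covariate table")
    values = np.array([mapping[c] for c in cell_ids], dtype=object)
    levels = sorted(set(values))
    rows = [np.ones(len(values))]
    names = ["intercept"]
    for lev in levels[1:]:
        rows.append((values == lev).astype(float))
        names.append(str(lev))
    from ra3.model import CovariateMatrix

    return CovariateMatrix(np.vstack(rows), names)


def read_labels(path: str | Path, cell_ids=None) -> np.ndarray:
    """Read a cell_id<TAB>label TSV; order follows ``cell_ids`` when given."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy(dtype=object)
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if cell_ids is None:
        return df.iloc[:, 1].to_numpy(dtype=object)
    return np.array([mapping[c] for c in cell_ids], dtype=object)


def save_basis(basis, peaks: pp.PeakSet, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("W1", data=basis.W1)
        f.create_dataset("explained_variance", data=basis.explained_variance)
        f.create_dataset("full_W", data=basis.full_W)
        f.create_dataset("full_explained_variance", data=basis.full_explained_variance)
        f.attrs["K1"] = basis.K1
        f.create_dataset(
            "peak_ids", data=np.array([str(i) for i in peaks.ids], dtype="S")
        )


def load_basis(path: str | Path):
    import h5py
    from ra3.reference import ProjectionBasis

    with h5py.File(path, "r") as f:
        return (
            ProjectionBasis(
                f["W1"][:],
                int(f.attrs["K1"]),
                f["explained_variance"][:],
                f["full_W"][:],
                f["full_explained_variance"][:],
            ),
            [s.decode() for s in f["peak_ids"][:]],
        )


def save_fit(result, path: str | Path) -> None:
    """Persist a FitResult (all model state + posterior means) to HDF5."""
    import h5py

    st = result.state
    with h5py.File(path, "w") as f:
        for name, arr in [
            ("H1", result.H1), ("H2", result.H2), ("H2_post", result.H2_post),
            ("H3", result.H3), ("objective_trace", np.array(result.objective_trace)),
            ("W1", st.W1), ("W2", st.W2), ("W3", st.W3), ("alpha", st.alpha),
            ("beta", st.beta), ("Gamma", st.Gamma),
        ]:
            f.create_dataset(name, data=arr)
        f.attrs["sigma2"] = st.sigma2
        f.attrs["converged"] = result.converged


def write_latent_tsv(latent: np.ndarray, cell_ids, path: str | Path) -> None:
    """Latent representation as cells x components TSV with named columns."""
    df = pd.DataFrame(
        latent.T,
        index=list(map(str, cell_ids)),
        columns=[f"component_{i + 1}" for i in range(latent.shape[0])],
    )
    df.to_csv(path, sep="\t", index_label="cell_id")
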