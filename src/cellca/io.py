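"""Readers and writers for the on-disk formats the package touches.

Count matrices come in as Matrix Market triplets with features/barcodes
sidecar files (the 10x convention: features as matrix rows, 1-based
indices on disk) or as dense delimited text with feature ids in the
first column and cell ids in the header. Embeddings, scree tables and
scaled-variance tables go out as TSV. All writers are atomic (temp
file + rename) so an interrupted run leaves no truncated artifact.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CAResult, CountMatrix


def _read_ids(path: str | Path, what: str) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    if not ids:
        raise ValueError(f"{what} file {path} is empty")
    return ids


def read_counts_mtx(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    transpose: bool = False,
) -> CountMatrix:
    """Read a Matrix Market count matrix with id sidecar files.

    ``transpose=True`` handles dialects that store cells as matrix
    rows. Duplicate coordinates and negative entries are rejected.
    """
    mat = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(mat):
        coo = mat.tocoo()
        coords = np.stack([coo.row, coo.col])
        if np.unique(coords, axis=1).shape[1] != coords.shape[1]:
            raise ValueError(
                f"{matrix_path}: duplicate coordinate entries"
            )
        dense = np.asarray(coo.todense(), dtype=float)
    else:
        dense = np.asarray(mat, dtype=float)
    if transpose:
        dense = dense.T
    if np.any(dense < 0):
        raise ValueError(f"{matrix_path}: negative values present")
    features = _read_ids(features_path, "features")
    barcodes = _read_ids(barcodes_path, "barcodes")
    if dense.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix is {dense.shape[0]}x{dense.shape[1]} but sidecars list "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    return CountMatrix(dense, features, barcodes)


def read_counts_csv(path: str | Path, sep: str | None = None) -> CountMatrix:
    """Read a dense delimited count table (features x cells).

    First column holds feature ids; the header row holds cell ids. The
    delimiter is sniffed from the suffix (.tsv/.txt -> tab) unless
    given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    values = df.to_numpy(dtype=float)  # raises on non-numeric
    if np.any(values < 0):
        raise ValueError(f"{path}: negative values present")
    return CountMatrix(values, [str(i) for i in df.index],
                       [str(c) for c in df.columns])


def _atomic_write(path: str | Path, write_fn) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_counts_mtx(counts: CountMatrix, out_dir: str | Path) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(counts.values)

    def _write_mtx(tmp: str) -> None:
        # pass a handle: mmwrite would append .mtx to a bare filename
        with open(tmp, "wb") as fh:
            scipy.io.mmwrite(fh, sparse)

    _atomic_write(out_dir / "matrix.mtx", _write_mtx)
    _atomic_write(
        out_dir / "features.tsv",
        lambda tmp: Path(tmp).write_text(
            "".join(f"{f}\n" for f in counts.feature_ids)),
    )
    _atomic_write(
        out_dir / "barcodes.tsv",
        lambda tmp: Path(tmp).write_text(
            "".join(f"{b}\n" for b in counts.cell_ids)),
    )


def write_embedding(
    path: str | Path,
    E: np.ndarray,
    cell_ids: list[str],
    batch: np.ndarray | None = None,
) -> None:
    """TSV embedding: cell_id, PC1..PCk, optional batch column."""
    E = np.asarray(E)
    df = pd.DataFrame(
        E, columns=[f"PC{k + 1}" for k in range(E.shape[1])]
    )
    df.insert(0, "cell_id", cell_ids)
    if batch is not None:
        df["batch"] = batch
    _atomic_write(path, lambda tmp: df.to_csv(tmp, sep="\t", index=False))


def read_embedding(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: missing cell_id column")
    return df


def write_scree(path: str | Path, result: CAResult) -> None:
    """TSV scree table: component, singular_value, pct_inertia."""
    df = pd.DataFrame(
        {
            "component": np.arange(1, result.d.size + 1),
            "singular_value": result.d,
            "pct_inertia": result.pct_inertia,
        }
    )
    _atomic_write(path, lambda tmp: df.to_csv(tmp, sep="\t", index=False))


def write_sv_table(path: str | Path, df: pd.DataFrame) -> None:
    """Long-format scaled-variance table (batch, component, SV)."""
    _atomic_write(path, lambda tmp: df.to_csv(tmp, sep="\t", index=False))
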