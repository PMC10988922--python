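"""Readers and writers for the supported on-disk formats.

Two matrix formats are supported, both genes-in-rows:

* **MTX triplet** — 10x-style directory with ``matrix.mtx`` (MatrixMarket
  coordinate, 1-based indices, integer values), ``features.tsv`` and
  ``barcodes.tsv`` (tab-separated, no header, first column is the id).
* **dense TSV** — header row of sample ids, first column gene ids.

MatrixMarket parsing/serialisation is delegated to :mod:`scipy.io`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ValidationError
from .matrix import GeneExpressionMatrix, LcmReferenceSet, MarkerCatalog

log = logging.getLogger(__name__)

MTX_NAME = "matrix.mtx"
FEATURES_NAME = "features.tsv"
BARCODES_NAME = "barcodes.tsv"


def _read_id_column(path: Path, what: str) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = [i for i in ids if i in seen or seen.add(i)]
        raise ValidationError(f"duplicate {what} id(s) in {path.name}: {dup[:5]}")
    return ids


def read_mtx_triplet(directory: str | Path, layer: str = "raw") -> GeneExpressionMatrix:
    """Read a 10x-style MTX triplet directory (genes x cells)."""
    directory = Path(directory)
    mtx_path = directory / MTX_NAME
    for p in (mtx_path, directory / FEATURES_NAME, directory / BARCODES_NAME):
        if not p.exists():
            raise ValidationError(f"missing file: {p}")
    genes = _read_id_column(directory / FEATURES_NAME, "gene")
    cells = _read_id_column(directory / BARCODES_NAME, "cell")
    mat = scipy.io.mmread(mtx_path)
    if mat.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix.mtx has shape {mat.shape} but features/barcodes imply "
            f"({len(genes)}, {len(cells)})"
        )
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    values = pd.DataFrame(dense, index=genes, columns=cells)
    return GeneExpressionMatrix(values, layer=layer)


def read_dense_tsv(
    path: str | Path, layer: str = "raw", transpose: bool = False
) -> GeneExpressionMatrix:
    """Read a dense TSV (header = sample ids, first column = gene ids).

    ``transpose`` declares that the file is samples-in-rows and should be
    flipped to the package's genes-in-rows orientation.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene id(s) in {path.name}: {dup[:5]}")
    return GeneExpressionMatrix(df, layer=layer)


def read_matrix(
    path: str | Path,
    format: str = "auto",
    layer: str = "raw",
    transpose: bool = False,
) -> GeneExpressionMatrix:
    """Read an expression matrix, dispatching on format.

    ``format`` is ``mtx_triplet``, ``dense_tsv`` or ``auto`` (directory =>
    MTX triplet, file => dense TSV).
    """
    path = Path(path)
    if format == "auto":
        format = "mtx_triplet" if path.is_dir() else "dense_tsv"
    if format == "mtx_triplet":
        if transpose:
            raise ValidationError("transpose only applies to dense TSV input")
        return read_mtx_triplet(path, layer=layer)
    if format == "dense_tsv":
        return read_dense_tsv(path, layer=layer, transpose=transpose)
    raise ValidationError(f"unknown matrix format {format!r}")


def write_mtx_triplet(m: GeneExpressionMatrix, directory: str | Path) -> None:
    """Write an MTX triplet directory for a raw count matrix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arr = m.values.to_numpy()
    sparse = scipy.sparse.coo_matrix(arr)
    field = "integer" if m.layer == "raw" else "real"
    if field == "integer":
        sparse = sparse.astype(np.int64)
    scipy.io.mmwrite(directory / MTX_NAME, sparse, field=field)
    # mmwrite appends .mtx if absent; path above already ends in .mtx
    pd.Series(m.gene_ids).to_csv(
        directory / FEATURES_NAME, sep="\t", header=False, index=False
    )
    pd.Series(m.sample_ids).to_csv(
        directory / BARCODES_NAME, sep="\t", header=False, index=False
    )


def write_dense_tsv(m: GeneExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = m.values
    if m.layer == "raw":
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="gene")


# -- LCM reference set ----------------------------------------------------

def read_lcm_references(
    path: str | Path,
    sample_meta: pd.DataFrame | None = None,
    layer: str = "linear",
) -> LcmReferenceSet:
    """Read an LCM reference table (dense TSV).

    If ``sample_meta`` is not given, sample ids are parsed with the
    ``<cell_type>_r<replicate>`` convention used by the simulator and
    writers.
    """
    m = read_dense_tsv(path, layer=layer)
    if sample_meta is None:
        rows = []
        for sid in m.sample_ids:
            stem, _, rep = sid.rpartition("_r")
            if not stem or not rep.isdigit():
                raise ValidationError(
                    f"cannot parse cell type/replicate from sample id {sid!r}; "
                    "expected '<cell_type>_r<replicate>' or explicit sample_meta"
                )
            rows.append({"cell_type": stem, "replicate": int(rep)})
        sample_meta = pd.DataFrame(rows, index=m.sample_ids)
    return LcmReferenceSet(m, sample_meta)


def write_lcm_references(refs: LcmReferenceSet, path: str | Path) -> None:
    """Write reference profiles as dense TSV with ``<type>_r<rep>`` sample ids."""
    write_dense_tsv(refs.matrix, path)


# -- marker catalog -------------------------------------------------------

def read_marker_catalog(path: str | Path) -> MarkerCatalog:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "claimed_type": str, "source": str})
    return MarkerCatalog(df)


def write_marker_catalog(catalog: MarkerCatalog, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    catalog.table.to_csv(path, sep="\t", index=False)
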