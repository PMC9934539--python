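"""Reading and writing count matrices, embeddings, and result tables.

Counts travel as MatrixMarket triplets (with ``genes.tsv``/``cells.tsv``
sidecars, 1-based indices per the MatrixMarket standard) or as dense CSV/TSV
with a gene index column; latent embeddings as CSV with a cell-id index.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csc_matrix

from .errors import ValidationError

logger = logging.getLogger("rankdecon")

__all__ = ["read_counts", "write_counts", "intersect_genes",
           "read_latent_csv", "write_latent_csv"]


def _read_id_list(path: Path) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return ids


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        warnings.warn(f"collapsed {n_dup} duplicate gene identifier(s) by summation")
        df = df.groupby(level=0, sort=False).sum()
    return df


def read_counts(path) -> pd.DataFrame:
    """Read a gene x cell count matrix.

    Accepts a directory holding ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``,
    a ``.mtx`` file with those sidecars next to it, or a dense CSV/TSV with
    gene rows and an identifier column.  Duplicate gene identifiers are
    collapsed by summation with a warning.
    """
    path = Path(path)
    if path.is_dir() or path.suffix == ".mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        base = mtx_path.parent
        if not mtx_path.exists():
            raise ValidationError(f"no matrix.mtx under {base}")
        try:
            mat = mmread(mtx_path)
        except Exception as exc:  # re-raise with the offending file named
            raise ValidationError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
        genes = _read_id_list(base / "genes.tsv")
        cells = _read_id_list(base / "cells.tsv")
        arr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if arr.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"{mtx_path}: matrix is {arr.shape} but sidecars list "
                f"{len(genes)} genes x {len(cells)} cells")
        df = pd.DataFrame(arr, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(cells, name="cell"))
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.index.name = "gene"
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative entries in count matrix")
    return _collapse_duplicates(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write counts as MTX triplet (directory) or dense CSV/TSV (by suffix)."""
    path = Path(path)
    if path.suffix in (".csv", ".tsv"):
        counts.to_csv(path, sep="\t" if path.suffix == ".tsv" else ",")
        return
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "matrix.mtx", csc_matrix(counts.to_numpy()))
    counts.index.to_series().to_csv(path / "genes.tsv", sep="\t",
                                    header=False, index=False)
    counts.columns.to_series().to_csv(path / "cells.tsv", sep="\t",
                                      header=False, index=False)


def intersect_genes(ref_genes, bulk_genes) -> pd.Index:
    """Ordered (reference-order) intersection of two gene identifier lists."""
    ref = pd.Index(ref_genes)
    bulk_set = set(bulk_genes)
    shared = pd.Index([g for g in ref if g in bulk_set], name="gene")
    if len(shared) == 0:
        raise ValidationError("no genes shared between reference and query")
    logger.info("gene intersection: kept %d (dropped %d from reference, %d from query)",
                len(shared), len(ref) - len(shared), len(set(bulk_genes)) - len(shared))
    return shared


def read_latent_csv(path) -> pd.DataFrame:
    """Cells x dimensions embedding with a cell-id index column."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def write_latent_csv(Z: np.ndarray, cell_ids, path) -> None:
    pd.DataFrame(Z, index=pd.Index(cell_ids, name="cell"),
                 columns=[f"dim{i+1}" for i in range(Z.shape[1])]).to_csv(path)
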