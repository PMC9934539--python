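"""Reference latent space: normalization, variable genes, PCA, kNN aggregation.

The reference pipeline mirrors the standard single-cell workflow: counts are
log-normalized by library size, the most variable genes are selected by a
mean-binned dispersion score, and cells are embedded by PCA of the centered
(and clipped, unit-scaled) expression of those genes.  Per-cell expression
profiles are then smoothed by summing each cell's counts with those of its
``r`` nearest neighbors in the embedding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("rankdecon")

__all__ = [
    "LatentModel",
    "log_normalize",
    "select_variable_genes",
    "pca_embed",
    "knn_aggregate",
    "latent_from_matrix",
]


@dataclass
class LatentModel:
    """Cell loadings ``Z`` (J x D) with their Moore-Penrose inverse.

    ``project`` sends a length-J vector (a correlation or probability profile
    over cells) to its D coordinates in the embedding basis; ``expand`` is the
    adjoint reconstruction.  Columns of ``Z`` are ordered by decreasing
    explained variance.
    """

    Z: np.ndarray  # J x D
    Z_pinv: np.ndarray  # D x J
    cell_ids: pd.Index
    var_genes: pd.Index  # the gene set used to build the embedding
    explained_variance: np.ndarray | None = None
    pca_gene_weights: pd.DataFrame | None = None  # gene x D loadings

    @property
    def n_cells(self) -> int:
        return self.Z.shape[0]

    @property
    def n_dims(self) -> int:
        return self.Z.shape[1]


def log_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """log1p of library-size-normalized counts: log(1 + count/libsize * scale)."""
    if scale <= 0:
        raise ValidationError("scale must be positive")
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValidationError("counts must be nonnegative")
    lib = mat.sum(axis=0)
    empty = np.flatnonzero(lib == 0)
    if empty.size:
        raise ValidationError(
            "cells with zero library size: "
            + ", ".join(str(counts.columns[i]) for i in empty[:10]))
    return pd.DataFrame(np.log1p(mat / lib[np.newaxis, :] * scale),
                        index=counts.index, columns=counts.columns)


def dispersion_scores(normalized: pd.DataFrame, n_bins: int = 20) -> pd.Series:
    """Mean-binned standardized dispersion (variance/mean, z-scored per bin).

    Genes are binned by mean expression into up to ``n_bins`` equal-frequency
    bins and each gene's dispersion is z-scored against its bin, removing the
    mean-variance trend before ranking.  Zero-mean genes score -inf.
    """
    mat = normalized.to_numpy(dtype=float)
    mean = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1) if mat.shape[1] > 1 else np.zeros(len(mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where((mean > 0) & (var > 0), var / mean, -np.inf)

    scores = np.full(len(mean), -np.inf)
    ok = np.isfinite(disp)
    if ok.any():
        n_bins = min(n_bins, max(1, ok.sum()))
        # equal-frequency bins over the expressed genes
        quantiles = np.quantile(mean[ok], np.linspace(0, 1, n_bins + 1))
        bins = np.clip(np.searchsorted(quantiles, mean[ok], side="right") - 1,
                       0, n_bins - 1)
        z = np.empty(ok.sum())
        d = disp[ok]
        for b in range(n_bins):
            in_bin = bins == b
            if not in_bin.any():
                continue
            mu, sd = d[in_bin].mean(), d[in_bin].std(ddof=1) if in_bin.sum() > 1 else 0.0
            z[in_bin] = (d[in_bin] - mu) / sd if sd > 0 else 0.0
        scores[ok] = z
    return pd.Series(scores, index=normalized.index, name="dispersion")


def select_variable_genes(normalized: pd.DataFrame, n_top: int) -> pd.Index:
    """The ``n_top`` most dispersed genes; ties broken by gene identifier."""
    if n_top > normalized.shape[0]:
        raise ValidationError(
            f"requested {n_top} variable genes from {normalized.shape[0]}")
    scores = dispersion_scores(normalized)
    order = sorted(range(len(scores)),
                   key=lambda i: (-scores.iloc[i], scores.index[i]))
    return pd.Index([scores.index[i] for i in order[:n_top]], name="gene")


def pca_embed(normalized: pd.DataFrame, n_dims: int, scale: bool = True,
              clip: float = 10.0) -> LatentModel:
    """PCA embedding of cells from the (centered, optionally scaled) matrix.

    Genes are centered across cells and, when ``scale`` is set, divided by
    their standard deviation with values clipped at ``clip`` standard
    deviations.  ``Z`` holds cell scores (right factors times singular
    values); its pseudoinverse is computed with relative tolerance 1e-10.
    """
    n_genes, n_cells = normalized.shape
    if n_dims > min(n_genes, n_cells):
        raise ValidationError("n_dims exceeds matrix dimensions")
    X = normalized.to_numpy(dtype=float).T.copy()  # cells x genes
    X -= X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X /= sd
        np.clip(X, -clip, clip, out=X)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if n_dims > rank:
        warnings.warn(f"requested {n_dims} dimensions but rank is {rank}; truncating")
        n_dims = rank
    # deterministic sign: largest-magnitude loading of each component positive
    for d in range(n_dims):
        pivot = np.argmax(np.abs(Vt[d]))
        if Vt[d, pivot] < 0:
            Vt[d] *= -1.0
            U[:, d] *= -1.0
    Z = U[:, :n_dims] * S[:n_dims]
    Z_pinv = np.linalg.pinv(Z, rcond=1e-10)
    return LatentModel(
        Z=Z,
        Z_pinv=Z_pinv,
        cell_ids=normalized.columns,
        var_genes=normalized.index,
        explained_variance=(S[:n_dims] ** 2) / max(n_cells - 1, 1),
        pca_gene_weights=pd.DataFrame(Vt[:n_dims].T, index=normalized.index,
                                      columns=[f"PC{d+1}" for d in range(n_dims)]),
    )


def latent_from_matrix(Z, cell_ids, var_genes=None) -> LatentModel:
    """Wrap a user-supplied J x D embedding (e.g. LSI dimensions) verbatim."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValidationError("latent matrix must be 2-dimensional (cells x dims)")
    if len(cell_ids) != Z.shape[0]:
        raise ValidationError("cell_ids length must match the latent row count")
    return LatentModel(Z=Z, Z_pinv=np.linalg.pinv(Z, rcond=1e-10),
                       cell_ids=pd.Index(cell_ids),
                       var_genes=pd.Index(var_genes) if var_genes is not None else pd.Index([]))


def nearest_neighbor_sets(Z: np.ndarray, r: int) -> np.ndarray:
    """Indices (J x r) of each cell's r nearest neighbors, self excluded.

    Euclidean metric; distance ties broken by ascending cell index (stable
    argsort), so the result is fully deterministic.
    """
    J = Z.shape[0]
    sq = np.einsum("ij,ij->i", Z, Z)
    d2 = sq[:, np.newaxis] + sq[np.newaxis, :] - 2.0 * (Z @ Z.T)
    np.fill_diagonal(d2, -np.inf)  # self always sorts first, then dropped
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, 1:r + 1]


def knn_aggregate(counts: pd.DataFrame, latent: LatentModel, r: int = 5) -> pd.DataFrame:
    """Sum each cell's counts with those of its ``r`` nearest latent neighbors.

    Column ``j`` of the result covers ``r + 1`` cells (the cell plus its
    neighbors); ``r=0`` returns the input unchanged.
    """
    J = latent.n_cells
    if r >= J:
        raise ValidationError(f"r={r} must be smaller than the number of cells ({J})")
    if counts.shape[1] != J:
        raise ValidationError("counts and latent model disagree on cell count")
    if r == 0:
        return counts.copy()
    neighbors = nearest_neighbor_sets(latent.Z, r)
    mat = counts.to_numpy()
    agg = mat.copy()
    for j in range(J):
        agg[:, j] += mat[:, neighbors[j]].sum(axis=1)
    return pd.DataFrame(agg, index=counts.index, columns=counts.columns)
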