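"""Rank-geometry diagnostics underpinning the correlation-based features.

The identifiability of abundance distributions from gene-rank information is
governed by the geometry of gene orderings: the normalized Kendall tau
distance metrizes the symmetric group of orderings, a closed-form arcsine
identity links it to the Spearman coefficient for normal populations, and
distance coordinates embed orderings into Euclidean space relative to the
orderings induced by each reference cell.  These operators are exposed for
diagnostics and property testing rather than for routine inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .errors import ValidationError

__all__ = [
    "gene_ordering",
    "kendall_tau_distance",
    "spearman_tau_check",
    "distance_coordinates",
]


def gene_ordering(values: np.ndarray) -> np.ndarray:
    """The permutation of gene ranks induced by an expression vector.

    Ties receive average ranks first and are then resolved by stable
    (first-occurrence) order, so the result is always a bijection.
    """
    values = np.asarray(values, dtype=float)
    avg = rankdata(values, method="average")
    return rankdata(avg, method="ordinal")


def _merge_count(seq: list) -> tuple[list, int]:
    """Sorted copy of ``seq`` and its inversion count, O(n log n)."""
    n = len(seq)
    if n < 2:
        return list(seq), 0
    mid = n // 2
    left, inv_l = _merge_count(seq[:mid])
    right, inv_r = _merge_count(seq[mid:])
    merged = []
    inv = inv_l + inv_r
    i = j = 0
    while i < len(left) and j < len(right):
        if left[i] <= right[j]:
            merged.append(left[i])
            i += 1
        else:
            merged.append(right[j])
            inv += len(left) - i
            j += 1
    merged.extend(left[i:] or right[j:])
    return merged, inv


def _count_inversions(seq) -> int:
    return _merge_count(list(seq))[1]


def kendall_tau_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Normalized Kendall tau distance between two gene orderings.

    ``2 * (# discordant pairs) / (T (T - 1))``: 0 for identical orderings, 1
    for full reversal.  Computed by merge-counting inversions of one ordering
    expressed in the other's coordinates.
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValidationError("orderings must be 1-d and of equal length")
    T = len(s1)
    if T < 2:
        raise ValidationError("orderings must have length >= 2")
    for s in (s1, s2):
        if not np.array_equal(np.sort(s), np.arange(1, T + 1)):
            raise ValidationError("input is not a permutation of 1..T")
    # positions of genes in s1's order, listed in s2's order
    perm = s1[np.argsort(s2, kind="stable")]
    discordant = _count_inversions(perm)
    return 2.0 * discordant / (T * (T - 1))


def spearman_tau_check(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Exact Kendall tau distance vs its arcsine-of-Spearman approximation.

    Returns ``(d_tau, 1/2 - arcsin(rho)/pi, |gap|)``; under bivariate
    normality the approximation error vanishes as the number of genes grows.
    Ties are rejected (jitter them with a recorded seed before calling).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for v in (x, y):
        if len(np.unique(v)) < len(v):
            raise ValidationError("ties present; jitter inputs before comparing")
        if np.all(v == v[0]):
            raise ValidationError("constant input")
    d_tau = kendall_tau_distance(gene_ordering(x), gene_ordering(y))
    rho = float(spearmanr(x, y).statistic)
    approx = 0.5 - np.arcsin(rho) / np.pi
    return d_tau, float(approx), float(abs(d_tau - approx))


def distance_coordinates(G: pd.DataFrame, s: np.ndarray) -> pd.Series:
    """Embed an ordering by its tau distance to each cell's induced ordering.

    Coordinate ``j`` is the Kendall tau distance between ``s`` and the gene
    ordering induced by reference cell ``j``'s expression column.  Constant
    (degenerate) columns yield NaN coordinates.
    """
    if G.shape[0] < 2:
        raise ValidationError("need at least 2 genes")
    s = np.asarray(s)
    coords = np.empty(G.shape[1])
    mat = G.to_numpy(dtype=float)
    for j in range(G.shape[1]):
        col = mat[:, j]
        if np.all(col == col[0]):
            coords[j] = np.nan
            continue
        coords[j] = kendall_tau_distance(gene_ordering(col), s)
    return pd.Series(coords, index=G.columns, name="tau_distance")
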