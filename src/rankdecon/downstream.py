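"""Downstream estimators: type fractions, expectations, metrics, gradients.

Per-cell probabilities become interpretable quantities here: summing over
annotated cell groups gives cell-type fractions; probability-weighted means of
per-cell scalars (pseudotime, signature scores) give per-sample expectations;
agreement with ground truth is summarized by Pearson correlation, Lin's
concordance correlation coefficient, and RMSE; and per-spot scalar fields on a
spatial grid yield smoothed gradient vector fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "aggregate_cell_types",
    "expected_value",
    "pearson",
    "lin_ccc",
    "rmse",
    "PerformanceReport",
    "performance_report",
    "gradient_field",
]


def aggregate_cell_types(p: pd.Series, labels: pd.Series,
                         allow_unassigned: bool = False) -> pd.Series:
    """Sum per-cell probabilities over each label: ``f'_k = sum_{i in C_k} p'_i``."""
    missing = p.index.difference(labels.index)
    if len(missing):
        if not allow_unassigned:
            raise ValidationError(
                f"{len(missing)} cells lack labels (e.g. {missing[0]!r})")
        labels = labels.reindex(p.index, fill_value="unassigned")
    grouped = p.groupby(labels.reindex(p.index)).sum()
    return grouped.rename("fraction")


def expected_value(p: pd.Series, values: pd.Series,
                   subset: pd.Index | None = None,
                   iqr_restrict: bool = True) -> float:
    """Probability-weighted mean of per-cell values, e.g. expected pseudotime.

    Optionally restricts to a cell ``subset`` (a lineage) and, when
    ``iqr_restrict`` is set, to cells whose probability lies within the
    interquartile range [Q1, Q3] of the subset's probability values
    (linear-interpolation quantiles).  Weights are renormalized over the kept
    cells, so the result is the expectation of a conditional distribution and
    is invariant to rescaling ``p`` by a positive constant.
    """
    if subset is not None:
        p = p.loc[subset]
        values = values.loc[subset]
    else:
        values = values.reindex(p.index)
    if values.isna().any():
        raise ValidationError("values undefined for some cells in the subset")
    w = p.to_numpy(dtype=float)
    v = values.to_numpy(dtype=float)
    if iqr_restrict:
        q1, q3 = np.quantile(w, [0.25, 0.75])
        keep = (w >= q1) & (w <= q3)
        w, v = w[keep], v[keep]
    if w.size == 0 or w.sum() <= 0:
        raise ValidationError("no cells (or no probability mass) left after restriction")
    return float(np.dot(w, v) / w.sum())


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def lin_ccc(a: np.ndarray, b: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ``2 cov(a,b) / (var(a) + var(b) + (mean(a) - mean(b))^2)``; penalizes both
    scatter and location/scale shift.  NaN when the denominator is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(), b.var()
    shift = (a.mean() - b.mean()) ** 2
    denom = va + vb + shift
    if denom == 0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(2.0 * cov / denom)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class PerformanceReport:
    """Agreement metrics at entity (cell-type) level and sample level.

    Cell-type level compares each entity's profile across samples; sample
    level compares each sample's composition across entities.  Undefined
    correlations (zero-variance axes) are reported as NaN, never as 0.
    """

    per_entity: pd.DataFrame  # index entity; columns pearson/lin_ccc/rmse
    per_sample: pd.DataFrame

    @property
    def summary(self) -> pd.Series:
        return pd.Series({
            "entity_pearson": self.per_entity["pearson"].mean(),
            "entity_lin_ccc": self.per_entity["lin_ccc"].mean(),
            "entity_rmse": self.per_entity["rmse"].mean(),
            "sample_pearson": self.per_sample["pearson"].mean(),
            "sample_lin_ccc": self.per_sample["lin_ccc"].mean(),
            "sample_rmse": self.per_sample["rmse"].mean(),
        })


def _metric_table(est: pd.DataFrame, truth: pd.DataFrame, axis: int) -> pd.DataFrame:
    labels = est.index if axis == 1 else est.columns
    rows = []
    for lab in labels:
        a = (est.loc[lab] if axis == 1 else est[lab]).to_numpy(dtype=float)
        b = (truth.loc[lab] if axis == 1 else truth[lab]).to_numpy(dtype=float)
        rows.append({"pearson": pearson(a, b), "lin_ccc": lin_ccc(a, b),
                     "rmse": rmse(a, b)})
    return pd.DataFrame(rows, index=labels)


def performance_report(estimates: pd.DataFrame, truth: pd.DataFrame) -> PerformanceReport:
    """Per-entity and per-sample agreement between estimate and truth tables.

    Both tables are entity x sample (e.g. cell types x bulk samples) and must
    share their shape and labels; at least 2 entities and 2 samples are
    required so both axes support a correlation.
    """
    if estimates.shape != truth.shape:
        raise ValidationError("estimate and truth tables differ in shape")
    truth = truth.loc[estimates.index, estimates.columns]
    if estimates.shape[0] < 2 or estimates.shape[1] < 2:
        raise ValidationError("need >= 2 entities and >= 2 samples")
    return PerformanceReport(
        per_entity=_metric_table(estimates, truth, axis=1),
        per_sample=_metric_table(estimates, truth, axis=0),
    )


def gradient_field(spot_values: pd.Series, spatial_xy: pd.DataFrame,
                   smooth_sigma: float = 30.0, truncate: float = 40.0) -> pd.DataFrame:
    """Smoothed spatial gradient of a per-spot scalar (e.g. pseudotime).

    Spots are snapped to the lattice of their unique x and y coordinates;
    gradients use central differences over immediately adjacent lattice
    neighbors (one-sided at borders).  The raw vectors are then smoothed with
    a Gaussian kernel of standard deviation ``smooth_sigma`` truncated at
    radius ``truncate`` (same length units as the coordinates);
    ``smooth_sigma=0`` returns the raw gradient.  Isolated spots get a zero
    vector and an ``isolated`` flag.

    Returns a DataFrame indexed by spot with columns x, y, dx, dy, isolated.
    """
    spots = spot_values.index
    xy = spatial_xy.loc[spots]
    xs = np.asarray(xy.iloc[:, 0], dtype=float)
    ys = np.asarray(xy.iloc[:, 1], dtype=float)
    vals = spot_values.to_numpy(dtype=float)

    ux, ix = np.unique(xs, return_inverse=True)
    uy, iy = np.unique(ys, return_inverse=True)
    grid: dict[tuple[int, int], int] = {(a, b): s for s, (a, b) in enumerate(zip(ix, iy))}

    def _axis_gradient(i: int, col: int, row: int, coords: np.ndarray,
                       along_x: bool) -> float | None:
        pos = col if along_x else row
        lo = grid.get((pos - 1, row) if along_x else (col, pos - 1))
        hi = grid.get((pos + 1, row) if along_x else (col, pos + 1))
        if lo is not None and hi is not None:
            return (vals[hi] - vals[lo]) / (coords[pos + 1] - coords[pos - 1])
        if hi is not None:
            return (vals[hi] - vals[i]) / (coords[pos + 1] - coords[pos])
        if lo is not None:
            return (vals[i] - vals[lo]) / (coords[pos] - coords[pos - 1])
        return None

    dx = np.zeros(len(spots))
    dy = np.zeros(len(spots))
    isolated = np.zeros(len(spots), dtype=bool)
    for i in range(len(spots)):
        gx = _axis_gradient(i, ix[i], iy[i], ux, along_x=True)
        gy = _axis_gradient(i, ix[i], iy[i], uy, along_x=False)
        if gx is None and gy is None:
            isolated[i] = True
        dx[i] = gx if gx is not None else 0.0
        dy[i] = gy if gy is not None else 0.0

    if smooth_sigma > 0:
        pts = np.column_stack([xs, ys])
        sdx = np.empty_like(dx)
        sdy = np.empty_like(dy)
        for i in range(len(spots)):
            d = np.linalg.norm(pts - pts[i], axis=1)
            mask = d <= truncate
            w = np.exp(-0.5 * (d[mask] / smooth_sigma) ** 2)
            sdx[i] = np.dot(w, dx[mask]) / w.sum()
            sdy[i] = np.dot(w, dy[mask]) / w.sum()
        dx, dy = sdx, sdy

    return pd.DataFrame({"x": xs, "y": ys, "dx": dx, "dy": dy,
                         "isolated": isolated}, index=spots)
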