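"""Synthetic single-cell data and pseudo-bulk samples with known ground truth.

The simulator follows a gamma-Poisson hierarchy: gene baseline means are drawn
from a gamma distribution, multiplied per group (or per trajectory position) by
log-normal differential-expression factors, renormalized to expression
proportions, scaled by a log-normal per-cell library size, and finally
observed through Poisson sampling.  Discrete mode produces well-separated cell
groups; trajectory mode produces branching differentiation paths with a
per-cell pseudotime.  Pseudo-bulk builders aggregate sampled cells either by
per-type fractions (discrete) or by a Gaussian kernel on pseudotime
(trajectory), recording the exact ground-truth sampling distribution.

Differential-expression factors are sampled with folded-log-normal magnitude
``exp(|N(loc, scale)|)`` so that a gene designated up-regulated always has a
factor > 1 and a down-regulated gene (probability ``de_down_prob``, reciprocal
factor) always a factor < 1; the stored factor table is the ground truth
against which the simulator is calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, SamplingError, ValidationError

__all__ = [
    "SimConfig",
    "SyntheticSC",
    "BulkTruth",
    "simulate_discrete",
    "simulate_trajectory",
    "make_bulk_discrete",
    "make_bulk_kernel",
    "sample_type_fractions",
    "write_synthetic",
    "write_bulk",
]


def _check_tree(topology: tuple[int, ...]) -> None:
    """Validate a parent-index list as a rooted tree (0 = root/origin).

    Branch ``i`` (1-based) has parent ``topology[i-1]``; a parent of 0 hangs
    off the origin.  Every branch must reach the origin without cycles.
    """
    n = len(topology)
    for i, parent in enumerate(topology, start=1):
        if not (0 <= parent <= n):
            raise ConfigError(f"branch {i} has out-of-range parent {parent}")
        if parent == i:
            raise ConfigError(f"branch {i} is its own parent")
    for i in range(1, n + 1):
        seen = set()
        node = i
        while node != 0:
            if node in seen:
                raise ConfigError(f"topology contains a cycle through branch {node}")
            seen.add(node)
            node = topology[node - 1]


@dataclass
class SimConfig:
    """Parameters of a synthetic single-cell simulation.

    ``group_probs`` sets discrete group sizes (and branch occupancies in
    trajectory mode); ``topology`` lists each branch's parent branch (0 = the
    undifferentiated origin); ``n_steps`` is the number of pseudotime steps
    per branch.  ``mean_shape``/``mean_rate`` parameterize the gamma baseline
    of gene means and ``lib_loc``/``lib_scale`` the log-normal library sizes.
    """

    n_genes: int = 20000
    n_cells: int = 5000
    group_probs: tuple[float, ...] = (1.0,)
    de_prob: float = 0.0025
    de_down_prob: float = 0.1
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.4
    topology: tuple[int, ...] = (0,)
    n_steps: int = 100
    nonlinear_prob: float = 0.3
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    bcv_common: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValidationError("n_genes and n_cells must be positive")
        probs = np.asarray(self.group_probs, dtype=float)
        if np.any(probs <= 0):
            raise ValidationError("group_probs entries must be > 0")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"group_probs must sum to 1 (got {probs.sum():.12f})"
            )
        for name in ("de_prob", "de_down_prob", "nonlinear_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_steps <= 0:
            raise ValidationError("n_steps must be positive")
        _check_tree(tuple(self.topology))


@dataclass
class SyntheticSC:
    """A simulated single-cell dataset with its generative ground truth."""

    counts: pd.DataFrame  # genes x cells, nonnegative integers
    labels: pd.Series  # per-cell group / branch identifier
    pseudotime: pd.Series | None  # trajectory mode only
    de_factors: pd.DataFrame  # genes x groups (or branch endpoints)
    mode: str  # "discrete" | "trajectory"
    config: SimConfig
    # trajectory mode: per-branch log-factor profiles, rows 0..n_steps where
    # row 0 equals the parent branch's final row (continuity at branch points)
    path_log_factors: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass
class BulkTruth:
    """A pseudo-bulk profile together with its ground-truth composition."""

    bulk_counts: pd.Series  # per-gene aggregated counts
    truth_type_fractions: pd.Series | None  # discrete mode
    truth_cell_probs: pd.Series | None  # trajectory (kernel) mode
    sampled_cell_ids: list[str]
    seed: int
    kernel_center: float | None = None
    kernel_sigma: float | None = None


def _de_factors(rng: np.random.Generator, n_genes: int, n_cols: int,
                de_prob: float, de_down_prob: float,
                loc: float, scale: float) -> np.ndarray:
    """Log-normal DE factor table: 1 for non-DE genes; >1 up, <1 down."""
    is_de = rng.random((n_genes, n_cols)) < de_prob
    magnitude = np.exp(np.abs(loc + scale * rng.standard_normal((n_genes, n_cols))))
    down = rng.random((n_genes, n_cols)) < de_down_prob
    factors = np.where(down, 1.0 / magnitude, magnitude)
    return np.where(is_de, factors, 1.0)


def _gene_cell_ids(n_genes: int, n_cells: int) -> tuple[pd.Index, pd.Index]:
    width_g = len(str(n_genes))
    width_c = len(str(n_cells))
    genes = pd.Index([f"gene{i:0{width_g}d}" for i in range(n_genes)], name="gene")
    cells = pd.Index([f"cell{i:0{width_c}d}" for i in range(n_cells)], name="cell")
    return genes, cells


def _poisson_counts(rng: np.random.Generator, proportions: np.ndarray,
                    lib_sizes: np.ndarray, bcv_common: float) -> np.ndarray:
    """Gamma-Poisson counts around library-size-scaled expression proportions.

    Each cell-gene mean is jittered by a gamma variable whose coefficient of
    variation is ``bcv_common + 1/sqrt(mean)`` — the standard biological-CV
    model in which lowly expressed genes are relatively noisier — and the
    observed count is Poisson around the jittered mean, i.e. counts are
    genuinely overdispersed relative to Poisson.
    """
    mean = proportions * lib_sizes[np.newaxis, :]
    positive = mean > 0
    bcv = np.zeros_like(mean)
    np.divide(1.0, np.sqrt(mean, where=positive, out=np.ones_like(mean)),
              where=positive, out=bcv)
    bcv += bcv_common
    shape = np.divide(1.0, bcv ** 2, where=positive, out=np.ones_like(mean))
    jittered = np.zeros_like(mean)
    jittered[positive] = rng.gamma(shape[positive],
                                   mean[positive] / shape[positive])
    return rng.poisson(jittered).astype(np.int32)


def simulate_discrete(config: SimConfig) -> SyntheticSC:
    """Simulate discrete cell groups under the gamma-Poisson model.

    Each gene is independently differentially expressed in each group with
    probability ``de_prob``; the multiplicative factor has log-normal
    magnitude with location ``de_fac_loc`` and is reciprocated (down-regulated)
    with probability ``de_down_prob``.  Group expression profiles are
    normalized to proportions so DE reshapes composition rather than depth.
    """
    rng = np.random.default_rng(config.seed)
    n_groups = len(config.group_probs)
    genes, cells = _gene_cell_ids(config.n_genes, config.n_cells)
    group_names = [f"group{k}" for k in range(n_groups)]

    base_mean = rng.gamma(config.mean_shape, 1.0 / config.mean_rate, config.n_genes)
    factors = _de_factors(rng, config.n_genes, n_groups, config.de_prob,
                          config.de_down_prob, config.de_fac_loc,
                          config.de_fac_scale)
    group_mean = base_mean[:, np.newaxis] * factors
    proportions = group_mean / group_mean.sum(axis=0, keepdims=True)

    label_idx = rng.choice(n_groups, size=config.n_cells, p=np.asarray(config.group_probs))
    lib_sizes = rng.lognormal(config.lib_loc, config.lib_scale, config.n_cells)
    counts = _poisson_counts(rng, proportions[:, label_idx], lib_sizes,
                             config.bcv_common)

    return SyntheticSC(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        labels=pd.Series([group_names[k] for k in label_idx], index=cells, name="label"),
        pseudotime=None,
        de_factors=pd.DataFrame(factors, index=genes, columns=group_names),
        mode="discrete",
        config=config,
    )


def _nonlinear_ramp(n_steps: int, midpoints: np.ndarray, width: float,
                    steps: np.ndarray) -> np.ndarray:
    """Logistic ramp in the step index, normalized to run from 0 to 1."""
    s = steps[:, np.newaxis]  # (n_steps+1, n_genes_nl)
    g = 1.0 / (1.0 + np.exp(-(s - midpoints[np.newaxis, :]) / width))
    g0, g1 = g[0], g[-1]
    return (g - g0) / (g1 - g0)


def simulate_trajectory(config: SimConfig) -> SyntheticSC:
    """Simulate branching differentiation trajectories.

    Every branch interpolates gene log-factors from its parent's endpoint to
    its own log-normal DE endpoint over ``n_steps`` steps; a ``nonlinear_prob``
    fraction of genes follow a logistic (sigmoidal) profile instead of a
    linear one.  Pseudotime is the cumulative step index from the origin.
    """
    rng = np.random.default_rng(config.seed)
    topology = tuple(config.topology)
    n_branches = len(topology)
    genes, cells = _gene_cell_ids(config.n_genes, config.n_cells)
    branch_names = [f"branch{b}" for b in range(1, n_branches + 1)]

    base_mean = rng.gamma(config.mean_shape, 1.0 / config.mean_rate, config.n_genes)
    end_factors = _de_factors(rng, config.n_genes, n_branches, config.de_prob,
                              config.de_down_prob, config.de_fac_loc,
                              config.de_fac_scale)
    end_log = np.log(end_factors)

    steps = np.arange(config.n_steps + 1, dtype=float)
    linear_ramp = (steps / config.n_steps)[:, np.newaxis]
    # depth of each branch's start (cumulative steps of ancestors)
    start_depth = np.zeros(n_branches)
    order = []  # branches in parent-before-child order
    remaining = set(range(1, n_branches + 1))
    while remaining:
        for b in sorted(remaining):
            parent = topology[b - 1]
            if parent == 0 or parent in order:
                order.append(b)
                remaining.discard(b)
                if parent != 0:
                    start_depth[b - 1] = start_depth[parent - 1] + config.n_steps
                break

    path_log: dict[int, np.ndarray] = {}
    for b in order:
        parent = topology[b - 1]
        parent_end = (np.zeros(config.n_genes) if parent == 0
                      else path_log[parent][-1])
        # endpoint factors are absolute (relative to baseline); the branch
        # moves from the parent's endpoint to its own endpoint
        target = end_log[:, b - 1]
        ramp = np.repeat(linear_ramp, config.n_genes, axis=1)
        nl_mask = rng.random(config.n_genes) < config.nonlinear_prob
        if nl_mask.any():
            mids = rng.uniform(0.25, 0.75, nl_mask.sum()) * config.n_steps
            ramp[:, nl_mask] = _nonlinear_ramp(config.n_steps, mids,
                                               config.n_steps / 8.0, steps)
        profile = parent_end[np.newaxis, :] + ramp * (target - parent_end)[np.newaxis, :]
        path_log[b] = profile.astype(np.float32)

    probs = np.asarray(config.group_probs, dtype=float)
    if len(probs) != n_branches:
        probs = np.full(n_branches, 1.0 / n_branches)
    branch_idx = rng.choice(n_branches, size=config.n_cells, p=probs)
    step_idx = rng.integers(1, config.n_steps + 1, size=config.n_cells)
    pseudotime = start_depth[branch_idx] + step_idx

    log_fac = np.empty((config.n_genes, config.n_cells))
    for b in range(1, n_branches + 1):
        mask = branch_idx == b - 1
        if mask.any():
            log_fac[:, mask] = path_log[b][step_idx[mask]].T

    mean = base_mean[:, np.newaxis] * np.exp(log_fac)
    proportions = mean / mean.sum(axis=0, keepdims=True)
    lib_sizes = rng.lognormal(config.lib_loc, config.lib_scale, config.n_cells)
    counts = _poisson_counts(rng, proportions, lib_sizes, config.bcv_common)

    return SyntheticSC(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        labels=pd.Series([branch_names[b] for b in branch_idx], index=cells, name="label"),
        pseudotime=pd.Series(pseudotime, index=cells, name="pseudotime"),
        de_factors=pd.DataFrame(end_factors, index=genes, columns=branch_names),
        mode="trajectory",
        config=config,
        path_log_factors=path_log,
    )


def sample_type_fractions(n_types: int, rng: np.random.Generator,
                          floor: float = 0.05) -> np.ndarray:
    """Random per-type fractions summing to 1 with every entry >= ``floor``."""
    if n_types * floor >= 1.0:
        raise ConfigError("floor too large for the number of types")
    g = rng.dirichlet(np.ones(n_types))
    return floor + (1.0 - n_types * floor) * g


def make_bulk_discrete(sc: SyntheticSC, fractions, seed: int) -> BulkTruth:
    """Pseudo-bulk by per-type sampling without replacement.

    ``n_k = round(f_k * n_cells / I)`` cells are drawn from type ``k`` (``I``
    types in total) and their counts summed; the fraction vector is the
    recorded ground truth.
    """
    rng = np.random.default_rng(seed)
    types = sorted(sc.labels.unique())
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(types):
        raise ValidationError(
            f"got {len(fractions)} fractions for {len(types)} types")
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-6:
        raise ValidationError("fractions must be nonnegative and sum to 1")

    n_types = len(types)
    sampled: list[str] = []
    for k, t in enumerate(types):
        members = sc.labels.index[sc.labels == t]
        n_k = int(round(fractions[k] * sc.n_cells / n_types))
        if n_k > len(members):
            raise SamplingError(
                f"type {t!r}: requested {n_k} cells but only {len(members)} available")
        sampled.extend(rng.choice(members, size=n_k, replace=False))

    bulk = sc.counts[sampled].sum(axis=1)
    return BulkTruth(
        bulk_counts=bulk.rename("bulk"),
        truth_type_fractions=pd.Series(fractions, index=types, name="fraction"),
        truth_cell_probs=None,
        sampled_cell_ids=sampled,
        seed=seed,
    )


def solve_kernel_sigma(pseudotime: np.ndarray, center: float,
                       target_capture: int) -> float:
    """Sigma such that ~``target_capture`` cells lie within 2*sigma of center.

    Solved exactly from the empirical distance quantile: 2*sigma equals the
    distance to the ``target_capture``-th nearest cell in pseudotime (one-cell
    tolerance by construction).
    """
    d = np.sort(np.abs(pseudotime - center))
    target_capture = int(min(max(target_capture, 1), len(d)))
    radius = d[target_capture - 1]
    if radius <= 0:
        positive = d[d > 0]
        if positive.size == 0:
            raise ConfigError("all cells share one pseudotime; kernel undefined")
        radius = positive[0]
    return radius / 2.0


def make_bulk_kernel(sc: SyntheticSC, n_draws: int = 1000,
                     capture_range: tuple[int, int] = (300, 1500),
                     seed: int = 0, sigma: float | None = None) -> BulkTruth:
    """Pseudo-bulk by Gaussian-kernel sampling on pseudotime.

    A center is the pseudotime of a uniformly chosen cell; sigma is solved so
    the number of cells within two standard deviations falls in
    ``capture_range``; ``n_draws`` cells are then sampled with replacement
    proportionally to the Gaussian density at their pseudotime.
    """
    if sc.pseudotime is None:
        raise ValidationError("kernel bulks require a trajectory simulation")
    if n_draws <= 0:
        raise ValidationError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    pt = sc.pseudotime.to_numpy(dtype=float)
    center = float(pt[rng.integers(len(pt))])
    if sigma is None:
        lo, hi = capture_range
        if lo > len(pt):
            raise ConfigError(
                f"capture_range {capture_range} exceeds the {len(pt)}-cell population")
        target = int(rng.integers(lo, min(hi, len(pt)) + 1))
        sigma = solve_kernel_sigma(pt, center, target)

    weights = np.exp(-0.5 * ((pt - center) / sigma) ** 2)
    probs = weights / weights.sum()
    draw_idx = rng.choice(len(pt), size=n_draws, replace=True, p=probs)
    tally = np.bincount(draw_idx, minlength=len(pt))
    bulk = pd.Series(sc.counts.to_numpy() @ tally, index=sc.counts.index, name="bulk")
    sampled = [sc.counts.columns[i] for i in draw_idx]
    return BulkTruth(
        bulk_counts=bulk,
        truth_type_fractions=None,
        truth_cell_probs=pd.Series(probs, index=sc.pseudotime.index, name="prob"),
        sampled_cell_ids=sampled,
        seed=seed,
        kernel_center=center,
        kernel_sigma=float(sigma),
    )


def write_synthetic(sc: SyntheticSC, outdir) -> None:
    """Write counts as 1-based MTX triplet plus gene/cell lists and metadata."""
    from pathlib import Path

    from scipy.io import mmwrite
    from scipy.sparse import csc_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "matrix.mtx", csc_matrix(sc.counts.to_numpy()))
    sc.counts.index.to_series().to_csv(outdir / "genes.tsv", sep="\t",
                                       header=False, index=False)
    sc.counts.columns.to_series().to_csv(outdir / "cells.tsv", sep="\t",
                                         header=False, index=False)
    meta = pd.DataFrame({"label": sc.labels})
    if sc.pseudotime is not None:
        meta["pseudotime"] = sc.pseudotime
    meta.to_csv(outdir / "cell_metadata.tsv", sep="\t")


def write_bulk(bulk: BulkTruth, prefix) -> None:
    """Write a pseudo-bulk as a counts TSV plus a ground-truth TSV."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bulk.bulk_counts.to_frame().to_csv(f"{prefix}_counts.tsv", sep="\t")
    truth = (bulk.truth_type_fractions if bulk.truth_type_fractions is not None
             else bulk.truth_cell_probs)
    truth.to_frame().to_csv(f"{prefix}_truth.tsv", sep="\t")
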