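"""End-to-end simulation studies of recovery accuracy.

Two presets mirror the method's simulation benchmarks: discrete cell-type
mixtures (recovery of per-type sampling fractions, measured after aggregating
per-cell probabilities by type) and branching differentiation trajectories
(recovery of per-cell Gaussian-kernel sampling probabilities).  Both return a
per-bulk results table whose mean Pearson correlation is the study's headline
number.

Desk-scale defaults (2,000 cells, 5,000 genes, 2,000 training distributions,
5 bulks per dataset) keep a full study within minutes on one CPU.  The
differential-expression probability stays at its full-scale value, and the
trajectory kernel's capture window is rescaled with the cell count so it
captures the same 6-30% fraction of the reference.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import infer_abundance, train_model
from .downstream import aggregate_cell_types, pearson, rmse
from .simdata import (SimConfig, make_bulk_discrete, make_bulk_kernel,
                      sample_type_fractions, simulate_discrete,
                      simulate_trajectory)

logger = logging.getLogger("rankdecon")

__all__ = ["run_discrete_benchmark", "run_trajectory_benchmark",
            "FULL_SCALE", "DESK_SCALE"]

# generative conditions of the full-scale simulation study
FULL_SCALE = {
    "n_genes": 20000,
    "n_cells": 5000,
    "de_prob": 0.0025,
    "de_down_prob": 0.1,
    "n_bulks": 25,
    "n_train": 5000,
    "kernel_capture": (300, 1500),
    "kernel_draws": 1000,
}

# reduced problem sizes used by the desk-scale presets
DESK_SCALE = {
    "n_genes": 5000,
    "n_cells": 2000,
    "n_bulks": 5,
    "n_train": 2000,
}


def _scaled_capture(n_cells: int) -> tuple[int, int]:
    """Kernel capture window preserving the full-scale capture fraction."""
    lo, hi = FULL_SCALE["kernel_capture"]
    f = n_cells / FULL_SCALE["n_cells"]
    return max(1, int(round(lo * f))), max(2, int(round(hi * f)))


def run_discrete_benchmark(
    n_groups_list: tuple[int, ...] = (3, 6, 9),
    de_locs: tuple[float, ...] = (0.01, 0.2, 0.6),
    n_bulks: int = DESK_SCALE["n_bulks"],
    n_cells: int = DESK_SCALE["n_cells"],
    n_genes: int = DESK_SCALE["n_genes"],
    n_train: int = DESK_SCALE["n_train"],
    n_var_genes: int = 2000,
    n_dims: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Discrete-mixture recovery study.

    For every (group count, DE strength) configuration: simulate a reference,
    train a model, draw ``n_bulks`` pseudo-bulks with random per-type
    fractions (floor 0.05), infer per-cell probabilities, aggregate by type,
    and record the per-bulk Pearson correlation and RMSE between aggregated
    estimates and the true fractions.
    """
    root = np.random.default_rng(seed)
    rows = []
    for n_groups in n_groups_list:
        for de_loc in de_locs:
            t0 = time.perf_counter()
            sim_seed = int(root.integers(2 ** 31))
            cfg = SimConfig(
                n_genes=n_genes, n_cells=n_cells,
                group_probs=tuple([1.0 / n_groups] * n_groups),
                de_prob=FULL_SCALE["de_prob"],
                de_down_prob=FULL_SCALE["de_down_prob"],
                de_fac_loc=de_loc, seed=sim_seed,
            )
            sc = simulate_discrete(cfg)
            run = RunConfig(n_var_genes=min(n_var_genes, n_genes),
                            n_dims=n_dims, n_train=n_train,
                            seed=int(root.integers(2 ** 31)))
            model = train_model(sc.counts, config=run)
            bulk_rng = np.random.default_rng(int(root.integers(2 ** 31)))
            for b in range(n_bulks):
                fractions = sample_type_fractions(n_groups, bulk_rng)
                bulk = make_bulk_discrete(sc, fractions,
                                          seed=int(bulk_rng.integers(2 ** 31)))
                dist = infer_abundance(model, bulk.bulk_counts)
                est = aggregate_cell_types(dist.p, sc.labels)
                truth = bulk.truth_type_fractions.reindex(est.index)
                rows.append({
                    "n_groups": n_groups, "de_fac_loc": de_loc, "bulk": b,
                    "pearson": pearson(est.to_numpy(), truth.to_numpy()),
                    "rmse": rmse(est.to_numpy(), truth.to_numpy()),
                })
            logger.info("discrete %d groups, de_fac_loc=%.2f: %.1fs",
                        n_groups, de_loc, time.perf_counter() - t0)
    return pd.DataFrame(rows)


TOPOLOGIES = {
    "bifurcation": (0, 1, 1),
    "three_way": (0, 1, 1, 1),
    "double_bifurcation": (0, 1, 1, 3, 3),
}


def run_trajectory_benchmark(
    topologies: dict[str, tuple[int, ...]] | None = None,
    de_locs: tuple[float, ...] = (0.4, 1.0),
    n_bulks: int = DESK_SCALE["n_bulks"],
    n_cells: int = DESK_SCALE["n_cells"],
    n_genes: int = DESK_SCALE["n_genes"],
    n_train: int = DESK_SCALE["n_train"],
    n_var_genes: int = 2000,
    n_dims: int = 10,
    cells_per_step: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Trajectory recovery study.

    For every (topology, DE strength) configuration: simulate a branching
    trajectory (step count chosen so each pseudotime step holds about
    ``cells_per_step`` cells), train a model, draw ``n_bulks`` Gaussian-kernel
    pseudo-bulks on pseudotime, and record the per-bulk Pearson correlation
    between inferred per-cell probabilities and the true kernel weights.
    """
    topologies = topologies if topologies is not None else TOPOLOGIES
    capture = _scaled_capture(n_cells)
    root = np.random.default_rng(seed)
    rows = []
    for name, topo in topologies.items():
        for de_loc in de_locs:
            t0 = time.perf_counter()
            n_branches = len(topo)
            n_steps = max(2, int(round(n_cells / (cells_per_step * n_branches))))
            cfg = SimConfig(
                n_genes=n_genes, n_cells=n_cells,
                group_probs=tuple([1.0 / n_branches] * n_branches),
                de_prob=FULL_SCALE["de_prob"],
                de_down_prob=FULL_SCALE["de_down_prob"],
                de_fac_loc=de_loc, topology=topo, n_steps=n_steps,
                seed=int(root.integers(2 ** 31)),
            )
            sc = simulate_trajectory(cfg)
            run = RunConfig(n_var_genes=min(n_var_genes, n_genes),
                            n_dims=n_dims, n_train=n_train,
                            seed=int(root.integers(2 ** 31)))
            model = train_model(sc.counts, config=run)
            bulk_rng = np.random.default_rng(int(root.integers(2 ** 31)))
            for b in range(n_bulks):
                bulk = make_bulk_kernel(sc, n_draws=FULL_SCALE["kernel_draws"],
                                        capture_range=capture,
                                        seed=int(bulk_rng.integers(2 ** 31)))
                dist = infer_abundance(model, bulk.bulk_counts)
                truth = bulk.truth_cell_probs.reindex(dist.p.index)
                rows.append({
                    "topology": name, "de_fac_loc": de_loc, "bulk": b,
                    "pearson": pearson(dist.p.to_numpy(), truth.to_numpy()),
                    "rmse": rmse(dist.p.to_numpy(), truth.to_numpy()),
                })
            logger.info("trajectory %s, de_fac_loc=%.2f: %.1fs",
                        name, de_loc, time.perf_counter() - t0)
    return pd.DataFrame(rows)
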