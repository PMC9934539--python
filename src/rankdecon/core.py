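"""The deconvolution engine.

The method learns a map ``h`` from the space of rank-correlation profiles to
the space of abundance distributions over reference cells.  Both spaces are
given coordinates by projecting length-J profiles through the pseudoinverse of
the latent cell-loading matrix ``Z`` (J x D).  Training pairs are produced by
sampling Gaussian-mixture abundance distributions on the latent space, drawing
synthetic bulks from them, and computing each bulk's per-cell Spearman
correlation vector against the kNN-aggregated reference.  ``h`` is a degree-s
polynomial fitted by linear least squares; inference applies ``h`` to a query
bulk's correlation coordinates, expands back to per-cell values, and
normalizes the result onto the probability simplex.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.preprocessing import PolynomialFeatures

from .config import RunConfig
from .errors import ValidationError
from .latent import LatentModel, knn_aggregate, log_normalize, pca_embed, select_variable_genes

logger = logging.getLogger("rankdecon")

MODEL_FORMAT_VERSION = "rankdecon-model-1"

__all__ = [
    "CorrelationVector",
    "AbundanceDistribution",
    "MixtureSpec",
    "TrainingSet",
    "DeconModel",
    "rank_correlation_vector",
    "project",
    "expand",
    "sample_abundance_mixture",
    "build_training_set",
    "fit_map",
    "infer_abundance",
    "normalize_probabilities",
    "proximity_score",
    "train_model",
]


@dataclass
class CorrelationVector:
    """Per-cell Spearman correlations of a bulk profile with the reference."""

    c: np.ndarray  # length J, entries in [-1, 1]
    gene_set_used: pd.Index


@dataclass
class AbundanceDistribution:
    """A (normalized) probability vector over reference cells."""

    p: pd.Series
    normalized: bool
    raw: np.ndarray | None = None  # pre-normalization map output
    coords: np.ndarray | None = None  # y-estimate in latent coordinates


@dataclass
class MixtureSpec:
    """One sampled Gaussian-mixture abundance distribution on latent space."""

    n_components: int
    centers: np.ndarray  # component cell indices
    sigmas: np.ndarray
    weights: np.ndarray


@dataclass
class TrainingSet:
    """Projected training pairs: correlation coords X and abundance coords Y."""

    X: np.ndarray  # k x D
    Y: np.ndarray  # k x D
    specs: list[MixtureSpec]
    n_sampled: int


@dataclass
class DeconModel:
    """Fitted polynomial map plus everything needed for inference.

    ``aggregated`` holds the kNN-aggregated reference counts restricted to the
    variable genes; queries are correlated against it over the genes shared
    with the query.  The training coordinates are retained for proximity
    scoring.
    """

    beta: np.ndarray  # n_monomials x D
    degree: int
    latent: LatentModel
    training: TrainingSet
    aggregated: pd.DataFrame  # var genes x cells
    config: RunConfig
    residual_norms: np.ndarray | None = None
    format_version: str = MODEL_FORMAT_VERSION

    def map_coords(self, x: np.ndarray) -> np.ndarray:
        """Apply the fitted polynomial map h to correlation coordinates."""
        x = np.atleast_2d(x)
        return _monomial_design(x, self.degree) @ self.beta

    def save(self, path) -> None:
        save_model(self, path)


# ---------------------------------------------------------------------------
# rank correlations


def _standardized_ranks(mat: np.ndarray, what: str) -> np.ndarray:
    """Column-wise average-tie ranks, centered and scaled to unit norm/sqrt(T).

    Columns with all-tied values get a zero vector (and a warning), so their
    correlation with anything is 0.
    """
    ranks = rankdata(mat, axis=0, method="average")
    ranks -= ranks.mean(axis=0, keepdims=True)
    norm = np.sqrt((ranks ** 2).mean(axis=0, keepdims=True))
    constant = norm[0] == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant {what} profile(s); correlation set to 0")
        norm[0, constant] = 1.0
    return ranks / norm


def rank_correlation_matrix(bulks: np.ndarray, aggregated: np.ndarray) -> np.ndarray:
    """Spearman correlations (average-tie ranks) of each bulk with each cell.

    ``bulks`` is genes x n_bulks, ``aggregated`` genes x J; the result is
    n_bulks x J, computed as one standardized rank-matrix product.
    """
    if bulks.shape[0] != aggregated.shape[0]:
        raise ValidationError("bulk and reference gene axes differ")
    if bulks.shape[0] < 2:
        raise ValidationError("need at least 2 shared genes for rank correlation")
    zb = _standardized_ranks(bulks, "bulk")
    zc = _standardized_ranks(aggregated, "aggregated reference")
    return (zb.T @ zc) / bulks.shape[0]


def rank_correlation_vector(bulk: np.ndarray, aggregated: np.ndarray,
                            genes: pd.Index) -> CorrelationVector:
    """Correlation vector of a single bulk profile over the gene set ``genes``."""
    c = rank_correlation_matrix(np.asarray(bulk, dtype=float)[:, np.newaxis],
                                np.asarray(aggregated, dtype=float))[0]
    return CorrelationVector(c=c, gene_set_used=pd.Index(genes))


# ---------------------------------------------------------------------------
# basis projection


def project(latent: LatentModel, v: np.ndarray) -> np.ndarray:
    """Coordinates of a length-J profile in the latent basis: ``Z_pinv @ v``."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != latent.n_cells:
        raise ValidationError(
            f"profile length {v.shape[-1]} != number of cells {latent.n_cells}")
    return v @ latent.Z_pinv.T


def expand(latent: LatentModel, coords: np.ndarray) -> np.ndarray:
    """Reconstruct a length-J profile from latent coordinates: ``Z @ coords``."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-1] != latent.n_dims:
        raise ValidationError(
            f"coordinate length {coords.shape[-1]} != latent dimension {latent.n_dims}")
    return coords @ latent.Z.T


# ---------------------------------------------------------------------------
# training


def sample_abundance_mixture(latent: LatentModel,
                             m_range: tuple[int, int] = (1, 5),
                             sigma_percentile_range: tuple[float, float] = (5.0, 20.0),
                             seed=0) -> tuple[AbundanceDistribution, MixtureSpec]:
    """One random Gaussian-mixture abundance distribution on the latent space.

    The component count is uniform on ``m_range``; each center is a uniformly
    sampled cell; each isotropic sigma is solved so the fraction of cells
    within two standard deviations of the center hits a target drawn uniformly
    from ``sigma_percentile_range`` (percent); weights are uniform on [0, 1].
    The mixture density is evaluated at every cell and normalized to sum 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = latent.Z
    J, D = Z.shape
    if J == 0:
        raise ValidationError("empty latent model")
    M = int(rng.integers(m_range[0], m_range[1] + 1))
    center_idx = rng.integers(J, size=M)
    targets = rng.uniform(sigma_percentile_range[0], sigma_percentile_range[1], M) / 100.0
    weights = rng.uniform(0.0, 1.0, M)

    density = np.zeros(J)
    sigmas = np.empty(M)
    for m in range(M):
        d = np.linalg.norm(Z - Z[center_idx[m]], axis=1)
        k = int(np.clip(round(targets[m] * J), 1, J))
        radius = np.sort(d)[k - 1]
        if radius <= 0:
            positive = d[d > 0]
            radius = positive.min() if positive.size else 1.0
        sigma = radius / 2.0
        sigmas[m] = sigma
        log_norm = -0.5 * D * np.log(2.0 * np.pi * sigma ** 2)
        density += weights[m] * np.exp(log_norm - 0.5 * (d / sigma) ** 2)

    p = density / density.sum()
    spec = MixtureSpec(n_components=M, centers=center_idx, sigmas=sigmas,
                       weights=weights)
    return AbundanceDistribution(p=pd.Series(p, index=latent.cell_ids),
                                 normalized=True), spec


def build_training_set(latent: LatentModel, counts_var: pd.DataFrame,
                       aggregated_var: pd.DataFrame, n_train: int = 5000,
                       n_sampled: int | None = None,
                       m_range: tuple[int, int] = (1, 5),
                       sigma_percentile_range: tuple[float, float] = (5.0, 20.0),
                       seed=0) -> TrainingSet:
    """Simulate ``n_train`` (abundance, correlation) pairs in latent coordinates.

    For each sampled mixture distribution, ``n_sampled`` cells (default J/2)
    are drawn with replacement, their variable-gene counts summed into a
    synthetic bulk, and the bulk's correlation vector computed against the
    aggregated reference; both profiles are projected through ``Z_pinv``.
    """
    if n_train <= 0:
        raise ValidationError("n_train must be positive")
    J = latent.n_cells
    n = n_sampled if n_sampled is not None else max(1, J // 2)
    if n <= 0:
        raise ValidationError("n_sampled must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    P = np.empty((n_train, J))
    specs: list[MixtureSpec] = []
    for l in range(n_train):
        dist, spec = sample_abundance_mixture(latent, m_range,
                                              sigma_percentile_range, rng)
        P[l] = dist.p.to_numpy()
        specs.append(spec)

    draws = rng.multinomial(n, P)  # n_train x J cell tallies
    bulks = counts_var.to_numpy(dtype=np.float64) @ draws.T  # T x n_train
    C = rank_correlation_matrix(bulks, aggregated_var.to_numpy(dtype=np.float64))
    X = project(latent, C)
    Y = project(latent, P)
    return TrainingSet(X=X, Y=Y, specs=specs, n_sampled=n)


def _monomial_design(X: np.ndarray, degree: int) -> np.ndarray:
    """Monomials of degree <= ``degree`` in the columns of X (with intercept)."""
    return PolynomialFeatures(degree=degree, include_bias=True).fit_transform(X)


def fit_map(training: TrainingSet, degree: int = 1,
            latent: LatentModel | None = None,
            aggregated: pd.DataFrame | None = None,
            config: RunConfig | None = None) -> DeconModel:
    """Least-squares fit of the degree-``degree`` polynomial map h: X -> Y.

    The D output coordinates share one monomial design matrix and are solved
    as independent least-squares problems (minimum-norm solution with a
    warning when the design is rank-deficient).
    """
    design = _monomial_design(training.X, degree)
    k, n_monomials = design.shape
    if k <= n_monomials:
        raise ValidationError(
            f"{k} training pairs cannot determine {n_monomials} monomial coefficients")
    beta, _, rank, _ = np.linalg.lstsq(design, training.Y, rcond=None)
    if rank < n_monomials:
        warnings.warn("rank-deficient design; minimum-norm least squares used")
    residual_norms = np.linalg.norm(design @ beta - training.Y, axis=0)
    return DeconModel(beta=beta, degree=degree, latent=latent,
                      training=training, aggregated=aggregated,
                      config=config if config is not None else RunConfig(),
                      residual_norms=residual_norms)


# ---------------------------------------------------------------------------
# inference


def normalize_probabilities(p: np.ndarray) -> np.ndarray:
    """Shift by the most negative entry (if any) and rescale to the simplex.

    ``p' = (p - delta) / ||p - delta||_1`` with every entry of ``delta`` equal
    to ``min(min(p), 0)``.
    """
    p = np.asarray(p, dtype=float)
    delta = min(float(p.min()), 0.0)
    shifted = p - delta
    total = shifted.sum()
    if total <= 0:
        raise ValidationError(
            "degenerate map output (all entries equal and nonpositive); "
            "the model cannot represent this query")
    return shifted / total


def _query_coords(model: DeconModel, bulk: pd.Series | pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Correlation coordinates x for one or more query bulk profiles."""
    if model.aggregated is None or model.latent is None:
        raise ValidationError("model lacks its reference context")
    frame = bulk.to_frame() if isinstance(bulk, pd.Series) else bulk
    shared = model.aggregated.index.intersection(frame.index)
    if len(shared) < 2:
        raise ValidationError(
            f"only {len(shared)} genes shared between query and reference variable genes")
    dropped = len(model.aggregated.index) - len(shared)
    if dropped:
        logger.info("query shares %d/%d variable genes (%d dropped)",
                    len(shared), len(model.aggregated.index), dropped)
    C = rank_correlation_matrix(frame.loc[shared].to_numpy(dtype=float),
                                model.aggregated.loc[shared].to_numpy(dtype=float))
    return project(model.latent, C), shared


def infer_abundance(model: DeconModel, bulk: pd.Series | pd.DataFrame):
    """Per-cell abundance probabilities for one or more query bulk profiles.

    Returns an :class:`AbundanceDistribution` for a Series input, or a
    cells x samples DataFrame of normalized probabilities for a DataFrame.
    """
    X, _ = _query_coords(model, bulk)
    Yhat = model.map_coords(X)
    P_raw = expand(model.latent, Yhat)
    P = np.stack([normalize_probabilities(row) for row in P_raw])
    cells = model.latent.cell_ids
    if isinstance(bulk, pd.Series):
        return AbundanceDistribution(p=pd.Series(P[0], index=cells, name=bulk.name),
                                     normalized=True, raw=P_raw[0], coords=Yhat[0])
    return pd.DataFrame(P.T, index=cells, columns=bulk.columns)


def proximity_of_coords(Y: np.ndarray, y: np.ndarray, n_nearest: int = 10) -> float:
    """Normalized distance of coordinates ``y`` to the training cloud ``Y``.

    Mean Euclidean distance from ``y`` to its ``n_nearest`` nearest rows of
    ``Y``, divided by the mean pairwise distance among those rows.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < n_nearest + 1:
        raise ValidationError(
            f"proximity scoring needs at least {n_nearest + 1} training points")
    d = np.linalg.norm(Y - np.asarray(y, dtype=float), axis=1)
    nearest = np.argsort(d, kind="stable")[:n_nearest]
    numerator = d[nearest].mean()
    if numerator == 0:
        return 0.0
    pts = Y[nearest]
    diffs = np.linalg.norm(pts[:, np.newaxis, :] - pts[np.newaxis, :, :], axis=-1)
    iu = np.triu_indices(n_nearest, k=1)
    denominator = diffs[iu].mean()
    if denominator == 0:
        return float("inf")
    return float(numerator / denominator)


def proximity_score(model: DeconModel, bulk: pd.Series) -> float:
    """Distance of a query to the training cloud (smaller = more trustworthy).

    Mean Euclidean distance from the query's abundance-coordinate estimate to
    its 10 nearest training points in Y, normalized by the mean pairwise
    distance among those 10 points.
    """
    X, _ = _query_coords(model, bulk)
    y = model.map_coords(X)[0]
    return proximity_of_coords(model.training.Y, y)


# ---------------------------------------------------------------------------
# end-to-end training


def train_model(counts: pd.DataFrame, latent: LatentModel | None = None,
                config: RunConfig | None = None) -> DeconModel:
    """Fit a deconvolution model from a reference gene x cell count matrix.

    Runs the full reference pipeline (log-normalization, variable-gene
    selection, PCA unless ``latent`` is supplied, kNN aggregation, training
    simulation, polynomial fit).  Genes are put in canonical (lexicographic)
    order first, so consistently permuted inputs give bit-identical models.
    """
    config = config if config is not None else RunConfig()
    counts = counts.sort_index()
    if counts.index.has_duplicates:
        raise ValidationError("duplicate gene identifiers; collapse them first")
    norm = log_normalize(counts, config.scale)
    n_var = min(config.n_var_genes, counts.shape[0])
    if n_var < config.n_var_genes:
        logger.info("only %d genes available; using all of them", n_var)
    var_genes = select_variable_genes(norm, n_var)
    if latent is None:
        latent = pca_embed(norm.loc[var_genes], min(config.n_dims, n_var,
                                                    counts.shape[1]))
    counts_var = counts.loc[var_genes]
    aggregated = knn_aggregate(counts_var, latent, config.n_neighbors)
    rng = np.random.default_rng(config.seed)
    training = build_training_set(latent, counts_var, aggregated,
                                  n_train=config.n_train,
                                  n_sampled=config.n_sampled,
                                  m_range=config.m_range,
                                  sigma_percentile_range=config.sigma_percentile_range,
                                  seed=rng)
    return fit_map(training, degree=config.degree, latent=latent,
                   aggregated=aggregated, config=config)


# ---------------------------------------------------------------------------
# model archive


def save_model(model: DeconModel, path) -> None:
    """Serialize a model (arrays + config + format version) to one archive."""
    path = Path(path)
    arrays = {
        "beta": model.beta,
        "Z": model.latent.Z,
        "Z_pinv": model.latent.Z_pinv,
        "training_X": model.training.X,
        "training_Y": model.training.Y,
        "aggregated": model.aggregated.to_numpy(),
        "residual_norms": (model.residual_norms if model.residual_norms is not None
                           else np.array([])),
    }
    meta = {
        "format_version": model.format_version,
        "degree": model.degree,
        "n_sampled": model.training.n_sampled,
        "config": model.config.as_dict(),
        "cell_ids": list(map(str, model.latent.cell_ids)),
        "var_genes": list(map(str, model.aggregated.index)),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        zf.writestr("arrays.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta))


def load_model(path) -> DeconModel:
    """Load a model archive written by :func:`save_model`."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format {meta['format_version']!r}")
        arrays = np.load(io.BytesIO(zf.read("arrays.npz")))
        cell_ids = pd.Index(meta["cell_ids"], name="cell")
        var_genes = pd.Index(meta["var_genes"], name="gene")
        latent = LatentModel(Z=arrays["Z"], Z_pinv=arrays["Z_pinv"],
                             cell_ids=cell_ids, var_genes=var_genes)
        training = TrainingSet(X=arrays["training_X"], Y=arrays["training_Y"],
                               specs=[], n_sampled=meta["n_sampled"])
        cfg = meta["config"]
        for key in ("m_range", "sigma_percentile_range"):
            cfg[key] = tuple(cfg[key])
        return DeconModel(
            beta=arrays["beta"], degree=meta["degree"], latent=latent,
            training=training,
            aggregated=pd.DataFrame(arrays["aggregated"], index=var_genes,
                                    columns=cell_ids),
            config=RunConfig(**cfg),
            residual_norms=(arrays["residual_norms"]
                            if arrays["residual_norms"].size else None),
        )
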