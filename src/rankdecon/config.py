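"""Run-wide tunables with their defaults.

Defaults follow the method's standard configuration: T=2000 variable genes,
D=10 latent dimensions, r=5 neighbors for count aggregation, polynomial degree
s=1, k=5000 training distributions, mixtures of 1-5 Gaussian components whose
2-sigma ball captures 5-20% of the reference cells, uniform [0,1] mixture
weights, and a 1e4 library-size scale for log-normalization.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

logger = logging.getLogger("rankdecon")

DEFAULTS = {
    "scale": 1e4,
    "n_var_genes": 2000,
    "n_dims": 10,
    "n_neighbors": 5,
    "degree": 1,
    "n_train": 5000,
    "m_range": (1, 5),
    "sigma_percentile_range": (5.0, 20.0),
}


@dataclass
class RunConfig:
    """All pipeline tunables in one place.

    ``n_sampled`` (cells aggregated per synthetic training bulk) defaults to
    half the number of reference cells when left as None.
    """

    scale: float = DEFAULTS["scale"]
    n_var_genes: int = DEFAULTS["n_var_genes"]
    n_dims: int = DEFAULTS["n_dims"]
    n_neighbors: int = DEFAULTS["n_neighbors"]
    degree: int = DEFAULTS["degree"]
    n_train: int = DEFAULTS["n_train"]
    n_sampled: int | None = None
    m_range: tuple[int, int] = DEFAULTS["m_range"]
    sigma_percentile_range: tuple[float, float] = DEFAULTS["sigma_percentile_range"]
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scale", "n_var_genes", "n_dims", "n_train"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_neighbors < 0:
            raise ValueError("n_neighbors must be >= 0")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        # log every non-default override so runs are auditable
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            default = f.default
            if f.name in DEFAULTS and val != DEFAULTS[f.name]:
                logger.info("config override: %s=%r (default %r)", f.name, val, default)
            else:
                logger.debug("config: %s=%r", f.name, val)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
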