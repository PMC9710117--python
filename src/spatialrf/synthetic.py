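"""Synthetic areal data with known effects and controllable spatial structure.

The generator emulates the kind of small-area dataset the package targets: a
lattice of contiguous regions, a handful of covariates with known linear
effects, and a spatially autocorrelated error field of controllable strength.
The error follows a simultaneous autoregressive (SAR) process on the
row-standardized rook-contiguity matrix W:

    u = (I - rho * W)^(-1) eps,       eps ~ N(0, noise_sd^2) i.i.d.

so rho = 0 collapses to i.i.d. noise and rho near 1 gives strong smooth
spatial dependence.  Covariates are i.i.d. N(0, 1) by default (spatially
unstructured, so any spatial signal in y is attributable solely to u); a
``smooth_covariates`` option passes them through the same SAR filter for
confounded scenarios.  The response is y = X beta + u (identity link) or its
logistic transform, which lies strictly in (0, 1) and emulates the observed
small-area proportions.

:func:`simulate_cluster_counts` additionally produces Poisson case counts with
an elevated-risk block, the canonical fixture for disease-clustering tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import identity
from scipy.sparse.linalg import spsolve
from scipy.special import expit

from .areal_data import AreaDataset
from .exceptions import ConfigurationError
from .weights import NeighborhoodStructure, lattice_centroids, lattice_rook, row_standardize

import pandas as pd

IDENTITY = "identity"
LOGISTIC = "logistic"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated areal dataset.

    Defaults: a 15 x 15 lattice with rho = 0.7 — spatial dependence strong
    enough that a model ignoring it leaves clearly autocorrelated residuals —
    and two unit-variance covariates with effects (1.0, 0.5) against unit
    noise, so covariate signal and spatial field have comparable variance.
    """

    nrows: int = 15
    ncols: int = 15
    rho: float = 0.7
    beta: tuple[float, ...] = (1.0, 0.5)
    noise_sd: float = 1.0
    n_covariates: int = 2
    link: str = IDENTITY
    seed: int = 0
    smooth_covariates: bool = False

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ConfigurationError("lattice dimensions must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError("rho must be in [0, 1): the SAR inverse "
                                     "is singular at rho = 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_covariates < 1:
            raise ConfigurationError("n_covariates must be >= 1")
        if len(self.beta) != self.n_covariates:
            raise ConfigurationError(
                f"beta has {len(self.beta)} entries for {self.n_covariates} covariates"
            )
        if self.link not in (IDENTITY, LOGISTIC):
            raise ConfigurationError(f"unknown link {self.link!r}")


def sar_field(
    nbrs: NeighborhoodStructure, rho: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """One draw of the SAR error field u = (I - rho W)^(-1) eps on ``nbrs``."""
    eps = rng.normal(0.0, noise_sd, size=nbrs.n)
    if rho == 0.0:
        return eps
    W = row_standardize(nbrs).to_sparse()
    return spsolve((identity(nbrs.n, format="csc") - rho * W.tocsc()).tocsc(), eps)


def simulate_areal(
    config: SimConfig,
) -> tuple[AreaDataset, NeighborhoodStructure, dict]:
    """Generate one areal dataset plus its generating truth.

    Returns the dataset (with lattice centroids), the binary rook structure,
    and a truth dict ``{"u": spatial field, "beta": effects, "rho": rho}`` for
    recovery tests.  Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    nbrs = lattice_rook(config.nrows, config.ncols)
    n = nbrs.n
    u = sar_field(nbrs, config.rho, config.noise_sd, rng)
    X = rng.standard_normal((n, config.n_covariates))
    if config.smooth_covariates and config.rho > 0:
        W = row_standardize(nbrs).to_sparse().tocsc()
        A = (identity(n, format="csc") - config.rho * W).tocsc()
        for j in range(config.n_covariates):
            X[:, j] = spsolve(A, X[:, j])
    beta = np.asarray(config.beta, dtype=float)
    eta = X @ beta + u
    y = eta if config.link == IDENTITY else expit(eta)
    data = AreaDataset(
        region_ids=nbrs.region_ids,
        y=pd.Series(y, name="y"),
        X=pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(config.n_covariates)]),
        centroids=lattice_centroids(config.nrows, config.ncols),
    )
    truth = {"u": u, "beta": beta, "rho": config.rho}
    return data, nbrs, truth


def simulate_cluster_counts(
    nrows: int,
    ncols: int,
    base_rate: float,
    cluster_block,
    relative_risk: float,
    population,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson case counts on a lattice with one elevated-risk block.

    Counts are Poisson with mean population * base_rate, multiplied by
    ``relative_risk`` inside ``cluster_block`` (region positions in row-major
    order).  ``population`` may be a scalar or per-region array.  Returns
    (counts, populations, centroids).
    """
    if relative_risk < 1:
        raise ConfigurationError("relative_risk must be >= 1")
    if not 0.0 < base_rate < 1.0:
        raise ConfigurationError("base_rate must be in (0, 1)")
    n = nrows * ncols
    block = np.asarray(list(cluster_block), dtype=int)
    if block.size and (block.min() < 0 or block.max() >= n):
        raise ConfigurationError("cluster_block is outside the lattice")
    pop = np.broadcast_to(np.asarray(population, dtype=float), (n,)).copy()
    if np.any(pop <= 0):
        raise ConfigurationError("populations must be positive")
    risk = np.ones(n)
    risk[block] = relative_risk
    rng = np.random.default_rng(seed)
    counts = rng.poisson(pop * base_rate * risk)
    return counts, pop, lattice_centroids(nrows, ncols)
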