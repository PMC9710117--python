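"""Global spatial-autocorrelation statistics and Monte-Carlo inference.

Implements Moran's I and Geary's C over a :class:`NeighborhoodStructure`
(default: binary contiguity weights), their random-permutation tests, the
empirical semivariogram, and Tango's C with the maximized excess events test
(MEET) for count data.

Moran's I lies in [-1, 1]: -1 is perfect dissimilarity clustering (a
checkerboard), 0 no spatial autocorrelation, 1 perfect similarity clustering.
Geary's C is nonnegative with null expectation 1; values below 1 indicate
positive autocorrelation.  Inference is by random relabelling of the values
across regions (the permutation null), which stays valid at small n; the
permutation p-value is (1 + #{replicates at least as extreme}) / (B + 1).

Tango's statistic is the quadratic form C(lambda) = (r - p)' A(lambda) (r - p)
with r the observed case proportions, p the population proportions, and
A(lambda)_ij = exp(-4 d_ij^2 / lambda^2) an exponential distance-decay weight.
MEET scans a grid of spatial scales lambda and adjusts for that scanning by
the min-p Monte-Carlo method: the reported p-value is the null probability
(under multinomial resampling of the cases) that the minimum per-lambda
p-value is at least as small as the observed minimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import ConfigurationError, DataError, DegenerateDataError
from .weights import NeighborhoodStructure

logger = logging.getLogger(__name__)

MORAN = "moran"
GEARY = "geary"
TWO_SIDED = "two_sided"
GREATER = "greater"
LESS = "less"


@dataclass(frozen=True)
class AutocorrResult:
    """A global autocorrelation statistic with its Monte-Carlo inference."""

    statistic: float
    expected_null: float
    p_value: float
    n_permutations: int
    weight_mode: str
    alternative: str = TWO_SIDED
    permuted_mean: float = float("nan")


@dataclass(frozen=True)
class Semivariogram:
    """Binned empirical semivariance gamma(h); empty bins carry NaN gamma."""

    bin_edges: np.ndarray  # length n_bins + 1
    gamma: np.ndarray      # length n_bins, NaN where count == 0
    counts: np.ndarray     # pairs per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _validate_field(values, nbrs: NeighborhoodStructure) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size != nbrs.n:
        raise DataError("values must be one real number per region")
    if v.size < 2:
        raise DegenerateDataError("need at least 2 regions")
    if np.ptp(v) == 0.0:
        raise DegenerateDataError("values are constant: statistic undefined")
    if nbrs.s0 == 0:
        raise DataError("structure has no links (all islands)")
    return v


def _moran_batch(V: np.ndarray, W, s0: float) -> np.ndarray:
    """Moran's I for each column of V (n, B)."""
    n = V.shape[0]
    Z = V - V.mean(axis=0, keepdims=True)
    num = (Z * (W @ Z)).sum(axis=0)
    den = (Z ** 2).sum(axis=0)
    return (n / s0) * num / den


def _geary_batch(V: np.ndarray, W, s0: float) -> np.ndarray:
    """Geary's C for each column of V (n, B)."""
    n = V.shape[0]
    Z = V - V.mean(axis=0, keepdims=True)
    row = np.asarray(W.sum(axis=1)).ravel()
    col = np.asarray(W.sum(axis=0)).ravel()
    sq = V ** 2
    ssd = row @ sq + col @ sq - 2.0 * (V * (W @ V)).sum(axis=0)
    return (n - 1) * ssd / (2.0 * s0 * (Z ** 2).sum(axis=0))


def morans_i(values, nbrs: NeighborhoodStructure) -> float:
    """Moran's I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    v = _validate_field(values, nbrs)
    return float(_moran_batch(v[:, None], nbrs.to_sparse(), nbrs.s0)[0])


def gearys_c(values, nbrs: NeighborhoodStructure) -> float:
    """Geary's C = (n-1) sum_ij w_ij (v_i - v_j)^2 / (2 S0 sum_i z_i^2)."""
    v = _validate_field(values, nbrs)
    return float(_geary_batch(v[:, None], nbrs.to_sparse(), nbrs.s0)[0])


def permutation_test(
    values,
    nbrs: NeighborhoodStructure,
    statistic: str = MORAN,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = TWO_SIDED,
) -> AutocorrResult:
    """Random-relabelling test of spatial autocorrelation.

    The observed field is permuted across regions ``n_permutations`` times;
    p-values follow the (1 + extreme) / (B + 1) convention, with the two-sided
    p as min(1, 2 * min(p_greater, p_less)).  The null expectation reported is
    -1/(n-1) for Moran's I and 1 for Geary's C.  Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    if statistic not in (MORAN, GEARY):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    if alternative not in (TWO_SIDED, GREATER, LESS):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    v = _validate_field(values, nbrs)
    n = v.size
    W = nbrs.to_sparse()
    fn = _moran_batch if statistic == MORAN else _geary_batch
    observed = float(fn(v[:, None], W, nbrs.s0)[0])

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    perms = v[order.T]  # (n, B)
    replicates = fn(perms, W, nbrs.s0)

    B = n_permutations
    p_greater = (1 + int((replicates >= observed).sum())) / (B + 1)
    p_less = (1 + int((replicates <= observed).sum())) / (B + 1)
    if alternative == GREATER:
        p = p_greater
    elif alternative == LESS:
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    expected = -1.0 / (n - 1) if statistic == MORAN else 1.0
    return AutocorrResult(
        statistic=observed,
        expected_null=expected,
        p_value=p,
        n_permutations=B,
        weight_mode=nbrs.weight_mode,
        alternative=alternative,
        permuted_mean=float(replicates.mean()),
    )


def semivariogram(
    values,
    centroids,
    n_bins: int = 10,
    max_dist: float | None = None,
) -> Semivariogram:
    """Empirical semivariogram on Euclidean centroid distances.

    gamma(h-bin) = sum_{pairs in bin} (v_i - v_j)^2 / (2 * count), with pairs
    binned into equal-width distance bins on (0, max_dist].  ``max_dist``
    defaults to the largest inter-centroid distance.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or c.shape[0] != v.size:
        raise DataError("centroids must align with values")
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")
    d = pdist(c)
    sqdiff = pdist(v[:, None], metric="sqeuclidean")
    if max_dist is None:
        max_dist = float(d.max()) if d.size else 0.0
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    keep = (d > 0) & (d <= max_dist)
    if not keep.any():
        warnings.warn("no region pairs within max_dist; semivariogram empty", stacklevel=2)
        return Semivariogram(edges, np.full(n_bins, np.nan), np.zeros(n_bins, dtype=int))
    idx = np.clip(np.searchsorted(edges, d[keep], side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sqdiff[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    return Semivariogram(edges, gamma, counts)


@dataclass(frozen=True)
class TangoMEETResult(AutocorrResult):
    """MEET inference: ``statistic`` is the observed minimum per-scale p-value,
    ``p_value`` its resampling-adjusted significance."""

    lambdas: np.ndarray = None
    c_values: np.ndarray = None
    p_per_lambda: np.ndarray = None


def tango_c(counts, populations, centroids, lam: float) -> float:
    """Tango's clustering index C(lambda) for one spatial scale."""
    r, p, d = _tango_inputs(counts, populations, centroids)
    A = np.exp(-4.0 * d ** 2 / lam ** 2)
    u = r - p
    return float(u @ A @ u)


def _tango_inputs(counts, populations, centroids):
    cnt = np.asarray(counts)
    pop = np.asarray(populations, dtype=float)
    cen = np.asarray(centroids, dtype=float)
    if cnt.size < 2:
        raise DataError("Tango's test needs at least 2 regions")
    if np.any(cnt < 0) or not np.allclose(cnt, np.round(cnt)):
        raise DataError("counts must be nonnegative integers")
    if np.any(pop <= 0):
        raise DataError("populations must be positive")
    if cnt.sum() < 1:
        raise DataError("total count must be >= 1")
    if cen.shape != (cnt.size, 2):
        raise DataError("centroids must be an (n, 2) array")
    r = cnt / cnt.sum()
    p = pop / pop.sum()
    d = squareform(pdist(cen))
    return r, p, d


def default_lambdas(centroids) -> np.ndarray:
    """Quartiles of the positive inter-centroid distances."""
    d = pdist(np.asarray(centroids, dtype=float))
    d = d[d > 0]
    if d.size == 0:
        raise DataError("all centroids coincide; no usable spatial scales")
    return np.percentile(d, [25, 50, 75])


def tango_meet(
    counts,
    populations,
    centroids,
    lambdas=None,
    n_mc: int = 999,
    seed: int | None = None,
) -> TangoMEETResult:
    """Tango's maximized excess events test over a grid of spatial scales.

    For each lambda the per-scale p-value is Monte-Carlo, under multinomial
    resampling of the total cases with cell probabilities proportional to the
    populations.  The MEET p-value corrects for scanning lambda: it is the
    resampling probability that the minimum per-scale p-value is <= the
    observed minimum.  Deterministic given ``seed``.
    """
    if n_mc < 99:
        raise ConfigurationError("n_mc must be >= 99")
    r, p, d = _tango_inputs(counts, populations, centroids)
    if lambdas is None:
        lambdas = default_lambdas(centroids)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0 or np.any(lambdas <= 0):
        raise ConfigurationError("lambdas must be a non-empty grid of positive scales")

    N = int(np.asarray(counts).sum())
    rng = np.random.default_rng(seed)
    M = rng.multinomial(N, p, size=n_mc) / N - p  # (B, n) deviations
    u = r - p

    L = lambdas.size
    c_obs = np.empty(L)
    c_rep = np.empty((n_mc, L))
    for k, lam in enumerate(lambdas):
        A = np.exp(-4.0 * d ** 2 / lam ** 2)
        c_obs[k] = u @ A @ u
        c_rep[:, k] = ((M @ A) * M).sum(axis=1)

    B = n_mc
    p_obs = (1 + (c_rep >= c_obs[None, :]).sum(axis=0)) / (B + 1)
    # per-replicate per-scale p-values, each replicate ranked among all B
    p_rep = np.empty_like(c_rep)
    for k in range(L):
        srt = np.sort(c_rep[:, k])
        ge = B - np.searchsorted(srt, c_rep[:, k], side="left")
        p_rep[:, k] = (1 + ge) / (B + 1)
    min_obs = float(p_obs.min())
    min_rep = p_rep.min(axis=1)
    p_meet = (1 + int((min_rep <= min_obs).sum())) / (B + 1)
    return TangoMEETResult(
        statistic=min_obs,
        expected_null=float("nan"),
        p_value=p_meet,
        n_permutations=B,
        weight_mode="exponential_decay",
        alternative=GREATER,
        permuted_mean=float(min_rep.mean()),
        lambdas=lambdas,
        c_values=c_obs,
        p_per_lambda=p_obs,
    )
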