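"""Spatial random forest (SRF) and the geographical random forest baseline.

The SRF is a two-stage regression forest for areal data:

1. define a contiguity neighbourhood for each region;
2. fit a global random forest RF_1 on (y, X);
3. form, for each region i, the neighbourhood-averaged first-stage residual
   r_i = mean over j ~ i of (y_j - yhat_j), with the region's own residual
   excluded by the relation itself;
4. fit RF_2 on (y, X plus the single extra covariate r).

The r covariate carries exactly the information a model ignoring space leaves
on the table — locally coherent over- or under-prediction — so RF_2 can absorb
residual spatial autocorrelation, conceptually mirroring how a conditional
autoregressive model conditions each region on its neighbours.  First-stage
residuals default to OUT-OF-BAG predictions: in-bag forest residuals are
shrunken toward zero by construction and would make r nearly vacuous.

The geographical random forest (GRF) baseline instead fits one local forest
per training region on its ``bandwidth`` nearest neighbours (Euclidean
centroid distance, self included) and predicts each new region with the local
forest of its nearest training region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .areal_data import AreaDataset
from .exceptions import ConfigurationError, DataError
from .weights import NeighborhoodStructure

logger = logging.getLogger(__name__)

OOB = "oob"
IN_BAG = "in_bag"
OBSERVED_NEIGHBORS = "observed_neighbors"

#: name of the residual covariate added for the second stage
RESIDUAL_COVARIATE = "spatial_resid"


@dataclass(frozen=True)
class ForestSpec:
    """Regression-forest hyper-parameters.

    ``max_depth=None`` means unlimited depth; ``max_depth=0`` requests a
    stump forest — no splits, every prediction the training mean — which is
    realised with a single-leaf tree and no bootstrap so it is exactly the
    mean predictor (a deterministic oracle used in tests).  ``mtry=None``
    defaults to ceil(p / 3), the regression-forest convention.
    """

    n_trees: int = 500
    max_depth: int | None = None
    min_leaf: int = 5
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ConfigurationError("min_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ConfigurationError("max_depth must be None, 0, or positive")
        if self.mtry is not None and self.mtry < 1:
            raise ConfigurationError("mtry must be >= 1")


@dataclass(frozen=True)
class ResidualField:
    """Neighbourhood-averaged residuals r_i aligned with a set of regions."""

    r: np.ndarray
    source: str  # one of {oob, in_bag, observed_neighbors}


class RegressionForest:
    """Seeded regression forest with out-of-bag predictions.

    Thin wrapper over :class:`sklearn.ensemble.RandomForestRegressor` that (a)
    realises the stump mode of :class:`ForestSpec`, and (b) recomputes each
    tree's bootstrap membership so every training region gets an out-of-bag
    prediction (regions sampled into every bag — rare beyond a handful of
    trees — fall back to the full-forest prediction, counted in
    ``n_oob_fallback_``).
    """

    def __init__(self, spec: ForestSpec, feature_names: Sequence[str]):
        self.spec = spec
        self.feature_names = list(feature_names)
        self.model: RandomForestRegressor | None = None
        self.oob_prediction_: np.ndarray | None = None
        self.n_oob_fallback_ = 0

    @property
    def stump(self) -> bool:
        return self.spec.max_depth == 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise DataError("X and y are misaligned")
        if np.isnan(X).any() or np.isnan(y).any():
            raise DataError("missing values must be imputed before fitting")
        if y.size < 1:
            raise DataError("cannot fit a forest on an empty sample")
        n, p = X.shape
        mtry = self.spec.mtry if self.spec.mtry is not None else max(1, math.ceil(p / 3))
        common = dict(
            n_estimators=self.spec.n_trees,
            max_features=min(mtry, p),
            random_state=self.spec.seed,
            n_jobs=1,
        )
        if self.stump:
            model = RandomForestRegressor(
                bootstrap=False, min_samples_split=n + 1, min_samples_leaf=1, **common
            )
        else:
            model = RandomForestRegressor(
                bootstrap=True,
                max_depth=self.spec.max_depth,
                min_samples_leaf=self.spec.min_leaf,
                **common,
            )
        model.fit(X, y)
        self.model = model
        self._train_X = X
        self._train_y = y
        self.oob_prediction_ = self._oob_predictions(X)
        return self

    def _oob_predictions(self, X: np.ndarray) -> np.ndarray:
        if self.stump:
            return self.model.predict(X)
        n = X.shape[0]
        pred = np.zeros(n)
        hits = np.zeros(n)
        for est in self.model.estimators_:
            # the exact bootstrap draw sklearn used for this tree
            sampled = np.random.RandomState(est.random_state).randint(0, n, n)
            mask = np.ones(n, dtype=bool)
            mask[sampled] = False
            if mask.any():
                pred[mask] += est.predict(X[mask])
                hits[mask] += 1
        covered = hits > 0
        pred[covered] /= hits[covered]
        if not covered.all():
            self.n_oob_fallback_ = int((~covered).sum())
            logger.warning(
                "%d region(s) were in every bootstrap bag; using full-forest "
                "predictions for them", self.n_oob_fallback_,
            )
            pred[~covered] = self.model.predict(X[~covered])
        return pred

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise DataError("forest is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise DataError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return self.model.predict(X)


@dataclass
class SRFModel:
    """A fitted spatial random forest: the (RF_1, RF_2) pair and its residuals."""

    rf1: RegressionForest
    rf2: RegressionForest
    residual_field: ResidualField
    nbrs: NeighborhoodStructure
    spec: ForestSpec
    train_ids: tuple[str, ...]
    train_residuals: np.ndarray  # raw first-stage residuals y - yhat_1


@dataclass
class GRFModel:
    """A geographical random forest: one local forest per training region."""

    local_forests: list[RegressionForest]
    bandwidth: int
    centroids: np.ndarray
    spec: ForestSpec
    train_ids: tuple[str, ...]
    local_importance: np.ndarray  # (n_train, p) impurity importances per local fit


def fit_rf(data: AreaDataset, spec: ForestSpec) -> RegressionForest:
    """Fit the global regression forest RF_1 on (y, X)."""
    if data.has_missing():
        raise DataError("dataset has missing values; run impute_spatial first")
    if data.n < 2:
        raise DataError("need at least 2 training regions")
    X, names = data.design_matrix()
    return RegressionForest(spec, names).fit(X, data.y.to_numpy(dtype=float))


def compute_residual_field(
    y, y_hat, nbrs: NeighborhoodStructure, source: str = OBSERVED_NEIGHBORS
) -> ResidualField:
    """Neighbourhood average of residuals: r_i = mean_{j ~ i} (y_j - yhat_j).

    The region's own residual is excluded because the relation j ~ i excludes
    self.  Islands get the neutral fallback r_i = 0 (logged).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size != nbrs.n:
        raise DataError("y and y_hat must align with the neighbourhood structure")
    resid = y - y_hat
    r = np.zeros(nbrs.n)
    n_islands = 0
    for i, nb in enumerate(nbrs.neighbors):
        if nb.size:
            r[i] = resid[nb].mean()
        else:
            n_islands += 1
    if n_islands:
        logger.info("%d island region(s) assigned residual fallback r = 0", n_islands)
    return ResidualField(r=r, source=source)


def fit_srf(
    train: AreaDataset,
    nbrs: NeighborhoodStructure,
    spec: ForestSpec,
    residual_source: str = OOB,
) -> SRFModel:
    """Fit the two-stage spatial random forest on an (imputed) training set.

    The neighbourhood structure is restricted to the training regions; the
    first-stage residuals are out-of-bag by default (``residual_source`` may
    be ``"in_bag"`` for sensitivity checks).  RF_2's seed is derived as
    ``spec.seed + 1`` so the two stages use distinct but reproducible streams.
    """
    if residual_source not in (OOB, IN_BAG):
        raise ConfigurationError(f"unknown residual source {residual_source!r}")
    sub = nbrs.subgraph(train.region_ids)
    rf1 = fit_rf(train, spec)
    X1, _ = train.design_matrix()
    y = train.y.to_numpy(dtype=float)
    yhat1 = rf1.oob_prediction_ if residual_source == OOB else rf1.predict(X1)
    field = compute_residual_field(y, yhat1, sub, source=residual_source)

    X2 = np.column_stack([X1, field.r])
    names2 = rf1.feature_names + [RESIDUAL_COVARIATE]
    rf2 = RegressionForest(replace(spec, seed=spec.seed + 1), names2).fit(X2, y)
    return SRFModel(
        rf1=rf1,
        rf2=rf2,
        residual_field=field,
        nbrs=sub,
        spec=spec,
        train_ids=train.region_ids,
        train_residuals=y - yhat1,
    )


def srf_design_matrix(model: SRFModel, data: AreaDataset, r: np.ndarray) -> np.ndarray:
    """Second-stage design matrix for ``data`` with residual covariate ``r``."""
    X, names = data.design_matrix()
    if names != model.rf1.feature_names:
        raise DataError(
            "covariates do not match the fitted model "
            f"(expected {model.rf1.feature_names}, got {names})"
        )
    return np.column_stack([X, r])


def test_residual_covariate(
    model: SRFModel, test: AreaDataset, nbrs_full: NeighborhoodStructure
) -> np.ndarray:
    """Transductive r for unseen regions: the mean stored first-stage residual
    over each test region's TRAINING neighbours; 0 when it has none."""
    train_pos = {rid: k for k, rid in enumerate(model.train_ids)}
    r = np.zeros(test.n)
    n_fallback = 0
    for i, rid in enumerate(test.region_ids):
        pos = nbrs_full.position(rid)  # raises DataError if absent
        donors = [
            train_pos[nbrs_full.region_ids[j]]
            for j in nbrs_full.neighbors[pos]
            if nbrs_full.region_ids[j] in train_pos
        ]
        if donors:
            r[i] = model.train_residuals[donors].mean()
        else:
            n_fallback += 1
    if n_fallback:
        logger.info(
            "%d test region(s) had no training neighbour; residual fallback r = 0",
            n_fallback,
        )
    return r


def predict_srf(
    model: SRFModel,
    test: AreaDataset,
    nbrs_full: NeighborhoodStructure,
    train_y=None,
) -> np.ndarray:
    """Predict unseen regions with RF_2(x, r).

    ``nbrs_full`` must span train and test regions.  ``train_y``, when given,
    is checked against the stored training responses (it is implied by the
    fitted model and kept in the signature for interface clarity).
    """
    if train_y is not None and len(np.asarray(train_y)) != len(model.train_ids):
        raise DataError("train_y does not align with the fitted model")
    r = test_residual_covariate(model, test, nbrs_full)
    return model.rf2.predict(srf_design_matrix(model, test, r))


def fit_grf(
    train: AreaDataset,
    centroids: np.ndarray | None = None,
    bandwidth: int = 100,
    spec: ForestSpec = ForestSpec(),
) -> GRFModel:
    """Fit one local forest per training region on its nearest neighbours.

    Each local training set is the region's ``bandwidth`` nearest training
    regions by Euclidean centroid distance, self included; ties broken by
    region order.  Members are re-sorted into original training order before
    fitting, so ``bandwidth >= n_train`` reproduces the global forest exactly
    for the same seed.
    """
    if bandwidth < 1:
        raise ConfigurationError("bandwidth must be >= 1")
    if centroids is None:
        centroids = train.centroids
    if centroids is None:
        raise DataError("GRF needs centroids for the training regions")
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (train.n, 2):
        raise DataError("centroids must be an (n_train, 2) array")
    if train.has_missing():
        raise DataError("dataset has missing values; run impute_spatial first")
    X, names = train.design_matrix()
    y = train.y.to_numpy(dtype=float)
    k = min(bandwidth, train.n)

    forests: list[RegressionForest] = []
    importances = np.zeros((train.n, X.shape[1]))
    order_ix = np.arange(train.n)
    for i in range(train.n):
        d = np.linalg.norm(centroids - centroids[i], axis=1)
        members = np.lexsort((order_ix, d))[:k]
        members = np.sort(members)  # original training order => seed-stable
        f = RegressionForest(spec, names).fit(X[members], y[members])
        forests.append(f)
        if not f.stump:
            importances[i] = f.model.feature_importances_
    return GRFModel(
        local_forests=forests,
        bandwidth=bandwidth,
        centroids=centroids,
        spec=spec,
        train_ids=train.region_ids,
        local_importance=importances,
    )


def predict_grf(
    model: GRFModel, test: AreaDataset, test_centroids: np.ndarray | None = None
) -> np.ndarray:
    """Predict each test region with the local forest of its nearest training
    region (ties broken by lowest training-region order)."""
    if test_centroids is None:
        test_centroids = test.centroids
    if test_centroids is None:
        raise DataError("GRF prediction needs test-region centroids")
    test_centroids = np.asarray(test_centroids, dtype=float)
    if test_centroids.shape != (test.n, 2):
        raise DataError("test centroids must be an (n_test, 2) array")
    X, names = test.design_matrix()
    if names != model.local_forests[0].feature_names:
        raise DataError("covariates do not match the fitted model")
    order_ix = np.arange(len(model.train_ids))
    out = np.empty(test.n)
    for i in range(test.n):
        d = np.linalg.norm(model.centroids - test_centroids[i], axis=1)
        nearest = np.lexsort((order_ix, d))[0]
        out[i] = model.local_forests[nearest].predict(X[i : i + 1])[0]
    return out
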