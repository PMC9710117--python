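"""Model evaluation: RMSE, R^2, residual Moran's I, variable importance, k-fold CV.

A model is judged on accuracy (RMSE), fit (R^2), and adequacy: whether its
residuals still carry spatial autocorrelation.  A model that has explained the
spatial variation leaves residuals whose Moran's I is indistinguishable from
the permutation null — the diagnostic used to compare spatial and aspatial
models on the small-area data that motivated this package.

Variable importance comes in two flavours: impurity importance (the sum over
all forest nodes of the size-weighted decrease in within-node variance
attributable to splits on the variable, evaluable on held-out data) and iMSE
(the mean increase in MSE after permuting the covariate's column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance

from . import srf as _srf
from .areal_data import AreaDataset
from .autocorr import MORAN, TWO_SIDED, AutocorrResult, permutation_test
from .exceptions import ConfigurationError, DataError, DegenerateDataError
from .srf import ForestSpec, RegressionForest
from .weights import NeighborhoodStructure

logger = logging.getLogger(__name__)


@dataclass
class ImportanceTable:
    """Per-covariate importance, raw and share-normalized.

    ``impurity`` is the summed size-weighted impurity decrease (>= 0);
    ``imse`` the permutation increase in MSE (can be slightly negative for
    irrelevant covariates; shares clip at zero before normalizing).
    """

    covariates: list[str]
    impurity: np.ndarray
    impurity_share: np.ndarray
    imse: np.ndarray
    imse_share: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "impurity": self.impurity,
                "impurity_share": self.impurity_share,
                "imse": self.imse,
                "imse_share": self.imse_share,
            },
            index=pd.Index(self.covariates, name="covariate"),
        )


@dataclass
class FitReport:
    """Headline metrics for one scored sample (train, test, or pooled CV)."""

    r2: float
    rmse: float
    residual_moran: AutocorrResult | None
    importance: ImportanceTable | None
    split: str
    predictions: pd.DataFrame | None = None


def rmse(y, y_hat) -> float:
    """Root mean squared error sqrt(sum (y_i - yhat_i)^2 / n)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise DataError("y and y_hat must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r_squared(y, y_hat) -> float:
    """R^2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2, with ybar the mean of
    the supplied y (may be negative on held-out data)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise DataError("y and y_hat must be equal-length and non-empty")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("constant y: R^2 undefined")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def residual_moran(
    y,
    y_hat,
    nbrs: NeighborhoodStructure,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = TWO_SIDED,
) -> AutocorrResult:
    """Permutation Moran's I test on the residuals y - y_hat."""
    resid = np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float)
    return permutation_test(
        resid, nbrs, statistic=MORAN, n_permutations=n_permutations,
        seed=seed, alternative=alternative,
    )


def node_impurity(values) -> float:
    """Within-node impurity: the population variance (divisor N) of the node."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("empty node")
    return float(np.var(v))


def _impurity_importance_tree(tree, X: np.ndarray, y: np.ndarray, p: int) -> np.ndarray:
    """Size-weighted impurity decreases per feature, evaluated on (X, y).

    Samples are routed down the tree; at each internal node t with children
    l, r the decrease (n_t * delta(t) - n_l * delta(l) - n_r * delta(r)) / N
    is credited to the node's split variable.  Empty nodes contribute 0.
    """
    t = tree.tree_
    indicator = tree.decision_path(X)  # (n, n_nodes) CSR of visited nodes
    counts = np.asarray(indicator.sum(axis=0)).ravel()
    sums = indicator.T @ y
    sumsq = indicator.T @ (y ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(counts > 0, sumsq / np.maximum(counts, 1)
                       - (sums / np.maximum(counts, 1)) ** 2, 0.0)
    var = np.maximum(var, 0.0)  # guard tiny negative round-off
    N = float(X.shape[0])
    imp = np.zeros(p)
    internal = t.children_left >= 0
    for node in np.flatnonzero(internal):
        l, r = t.children_left[node], t.children_right[node]
        dec = (counts[node] * var[node] - counts[l] * var[l] - counts[r] * var[r]) / N
        imp[t.feature[node]] += max(dec, 0.0)
    return imp


def impurity_importance(forest: RegressionForest, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Impurity importance per feature, averaged over trees, on supplied data.

    Evaluated on held-out (X, y) this is the test-data impurity reduction; on
    training data it reproduces the classical mean-decrease-in-impurity up to
    the bootstrap weighting of in-bag samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = len(forest.feature_names)
    if X.shape[1] != p:
        raise DataError("feature count does not match the fitted forest")
    total = np.zeros(p)
    for est in forest.model.estimators_:
        total += _impurity_importance_tree(est, X, y, p)
    return total / len(forest.model.estimators_)


def _shares(raw: np.ndarray) -> np.ndarray:
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0.0:
        # no covariate shows any effect; report uninformative uniform shares
        return np.full(raw.size, 1.0 / raw.size)
    return clipped / total


def importance(
    forest: RegressionForest,
    data: AreaDataset,
    n_shuffles: int = 10,
    seed: int | None = None,
) -> ImportanceTable:
    """Impurity and iMSE importance of every covariate on ``data``.

    Pass a held-out sample for test-based importance (the default protocol);
    training data may be passed for diagnostics.  iMSE permutes each covariate
    column ``n_shuffles`` times and averages the MSE increase.
    """
    if data.has_missing():
        raise DataError("dataset has missing values; impute first")
    X, names = data.design_matrix()
    if names != forest.feature_names:
        raise DataError(
            f"covariates {names} do not match the fitted forest {forest.feature_names}"
        )
    y = data.y.to_numpy(dtype=float)
    imp = impurity_importance(forest, X, y)
    perm = permutation_importance(
        forest.model, X, y,
        scoring="neg_mean_squared_error",
        n_repeats=n_shuffles,
        random_state=seed,
        n_jobs=1,
    )
    imse = perm.importances_mean  # mean increase in MSE
    return ImportanceTable(
        covariates=names,
        impurity=imp,
        impurity_share=_shares(imp),
        imse=imse,
        imse_share=_shares(imse),
    )


def score_predictions(
    y,
    y_hat,
    nbrs: NeighborhoodStructure | None,
    split: str,
    n_permutations: int = 999,
    seed: int | None = None,
    region_ids=None,
) -> FitReport:
    """Bundle RMSE, R^2 and (when a structure is given) residual Moran's I."""
    moran = None
    if nbrs is not None:
        try:
            moran = residual_moran(y, y_hat, nbrs, n_permutations, seed)
        except DegenerateDataError:
            logger.warning("residuals degenerate; residual Moran's I omitted")
    preds = None
    if region_ids is not None:
        preds = pd.DataFrame(
            {"region_id": list(region_ids), "y": np.asarray(y, dtype=float),
             "y_hat": np.asarray(y_hat, dtype=float), "split": split}
        )
    return FitReport(
        r2=r_squared(y, y_hat),
        rmse=rmse(y, y_hat),
        residual_moran=moran,
        importance=None,
        split=split,
        predictions=preds,
    )


def _fold_assignment(n: int, k: int, seed: int | None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def kfold_cv(
    data: AreaDataset,
    nbrs: NeighborhoodStructure,
    model: str,
    k: int,
    spec: ForestSpec,
    seed: int | None = None,
    bandwidth: int = 100,
    n_permutations: int = 999,
) -> FitReport:
    """k-fold cross-validation of an {rf, srf, grf} model.

    Regions are partitioned into k seeded folds; each fold is predicted by a
    model trained on the remaining folds (with neighbourhoods restricted to
    the per-fold training subgraph for the SRF, exactly as at test time).
    Pooled out-of-fold predictions are scored with RMSE, R^2 and residual
    Moran's I.
    """
    if model not in ("rf", "srf", "grf"):
        raise ConfigurationError(f"unknown model {model!r}")
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > data.n:
        raise ConfigurationError(f"k={k} exceeds the number of regions {data.n}")
    folds = _fold_assignment(data.n, k, seed)
    y_hat = np.empty(data.n)
    fold_col = np.empty(data.n, dtype=int)
    for f in range(k):
        test_pos = np.flatnonzero(folds == f)
        train_pos = np.flatnonzero(folds != f)
        train, test = data.subset(train_pos), data.subset(test_pos)
        if model == "rf":
            fitted = _srf.fit_rf(train, spec)
            Xt, _ = test.design_matrix()
            pred = fitted.predict(Xt)
        elif model == "srf":
            fitted = _srf.fit_srf(train, nbrs, spec)
            pred = _srf.predict_srf(fitted, test, nbrs)
        else:
            fitted = _srf.fit_grf(train, train.centroids, bandwidth, spec)
            pred = _srf.predict_grf(fitted, test, test.centroids)
        y_hat[test_pos] = pred
        fold_col[test_pos] = f
    report = score_predictions(
        data.y.to_numpy(dtype=float), y_hat, nbrs, split="cv",
        n_permutations=n_permutations, seed=seed, region_ids=data.region_ids,
    )
    report.predictions["fold"] = fold_col
    return report
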