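import numpy as np
import pandas as pd
import pytest

import spatialrf as s
from spatialrf.exceptions import ConfigurationError, DataError

from conftest import make_dataset


def lattice_dataset(nrows, ncols, y, X=None):
    nb = s.lattice_rook(nrows, ncols)
    n = nb.n
    X = pd.DataFrame({"x1": np.zeros(n)}) if X is None else X
    data = s.AreaDataset(
        nb.region_ids, pd.Series(np.asarray(y, dtype=float)), X,
        centroids=s.lattice_centroids(nrows, ncols),
    )
    return data, nb


class TestRegressionForest:
    def test_stump_predicts_training_mean(self, regression_dataset):
        f = s.fit_rf(regression_dataset, s.ForestSpec(n_trees=1, max_depth=0, seed=0))
        X, _ = regression_dataset.design_matrix()
        mean = regression_dataset.y.mean()
        np.testing.assert_allclose(f.predict(X), mean)
        np.testing.assert_allclose(f.oob_prediction_, mean)

    def test_seed_determinism(self, regression_dataset):
        spec = s.ForestSpec(n_trees=50, seed=11)
        X, _ = regression_dataset.design_matrix()
        a = s.fit_rf(regression_dataset, spec).predict(X)
        b = s.fit_rf(regression_dataset, spec).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_step_function_learned_with_deep_trees(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 2))
        y = np.where(X[:, 0] > 0, 2.0, -1.0)
        data = s.AreaDataset(
            tuple(f"g{i}" for i in range(200)), pd.Series(y),
            pd.DataFrame(X, columns=["x1", "x2"]),
        )
        f = s.fit_rf(data, s.ForestSpec(n_trees=100, min_leaf=1, seed=1))
        assert s.r_squared(y, f.predict(X)) >= 0.95

    def test_oob_matches_sklearn_reference(self):
        from sklearn.ensemble import RandomForestRegressor

        data = make_dataset(n=80, seed=4)
        X, _ = data.design_matrix()
        y = data.y.to_numpy()
        ours = s.RegressionForest(s.ForestSpec(n_trees=100, seed=5), ["x1", "x2"]).fit(X, y)
        ref = RandomForestRegressor(
            n_estimators=100, random_state=5, oob_score=True,
            min_samples_leaf=5, max_features=1, n_jobs=1,
        ).fit(X, y)
        np.testing.assert_allclose(ours.oob_prediction_, ref.oob_prediction_)

    def test_missing_values_rejected(self):
        data = s.AreaDataset(
            ("A", "B", "C"), pd.Series([1.0, np.nan, 2.0]),
            pd.DataFrame({"x1": [1.0, 2.0, 3.0]}),
        )
        with pytest.raises(DataError):
            s.fit_rf(data, s.ForestSpec(n_trees=5))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            s.ForestSpec(n_trees=0)
        with pytest.raises(ConfigurationError):
            s.ForestSpec(min_leaf=0)


class TestResidualField:
    def test_chain_hand_oracle(self, chain4):
        field = s.compute_residual_field(
            np.array([-2.0, -1.0, 0.0, 3.0]), np.zeros(4), chain4
        )
        np.testing.assert_allclose(field.r, [-1.0, -1.0, 1.0, 0.0])

    def test_zero_residuals_give_zero_field(self, chain4):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        field = s.compute_residual_field(y, y, chain4)
        np.testing.assert_array_equal(field.r, np.zeros(4))

    def test_island_gets_zero_fallback(self):
        nb = s.from_edge_list([("A", "B")], ["A", "B", "C"])
        field = s.compute_residual_field(
            np.array([1.0, 2.0, 9.0]), np.zeros(3), nb
        )
        assert field.r[2] == 0.0

    def test_length_mismatch_rejected(self, chain4):
        with pytest.raises(DataError):
            s.compute_residual_field(np.zeros(3), np.zeros(3), chain4)


class TestFitSRF:
    def test_stump_composition_reproduces_neighbourhood_centred_y(self):
        data, nb, _ = s.simulate_areal(s.SimConfig(nrows=5, ncols=5, seed=2))
        model = s.fit_srf(data, nb, s.ForestSpec(n_trees=1, max_depth=0, seed=0))
        y = data.y.to_numpy()
        expected = s.compute_residual_field(y, np.full(y.size, y.mean()), nb)
        np.testing.assert_allclose(model.residual_field.r, expected.r)

    def test_rf2_has_exactly_one_extra_residual_covariate(self):
        data, nb, _ = s.simulate_areal(s.SimConfig(nrows=5, ncols=5, seed=2))
        model = s.fit_srf(data, nb, s.ForestSpec(n_trees=10, seed=0))
        assert model.rf2.feature_names == model.rf1.feature_names + ["spatial_resid"]

    def test_residual_rank_reflects_spatial_structure(self):
        # with no spatial structure r should rarely top the importance ranking;
        # with a purely spatial response it should almost always top it
        top_noise = 0
        top_spatial = 0
        for seed in range(20):
            cfg = s.SimConfig(nrows=8, ncols=8, rho=0.0, beta=(1.0, 0.5), seed=seed)
            data, nb, _ = s.simulate_areal(cfg)
            m = s.fit_srf(data, nb, s.ForestSpec(n_trees=100, seed=seed))
            ranks = np.argsort(m.rf2.model.feature_importances_)[::-1]
            top_noise += ranks[0] == len(m.rf2.feature_names) - 1

            cfg = s.SimConfig(nrows=8, ncols=8, rho=0.9, beta=(0.0, 0.0), seed=seed)
            data, nb, _ = s.simulate_areal(cfg)
            m = s.fit_srf(data, nb, s.ForestSpec(n_trees=100, seed=seed))
            ranks = np.argsort(m.rf2.model.feature_importances_)[::-1]
            top_spatial += ranks[0] == len(m.rf2.feature_names) - 1
        assert top_noise <= 0.2 * 20
        assert top_spatial >= 0.8 * 20

    def test_deterministic_given_seed(self):
        data, nb, _ = s.simulate_areal(s.SimConfig(nrows=6, ncols=6, seed=3))
        a = s.fit_srf(data, nb, s.ForestSpec(n_trees=30, seed=4))
        b = s.fit_srf(data, nb, s.ForestSpec(n_trees=30, seed=4))
        np.testing.assert_array_equal(a.residual_field.r, b.residual_field.r)
        X2 = np.column_stack([data.design_matrix()[0], a.residual_field.r])
        np.testing.assert_array_equal(a.rf2.predict(X2), b.rf2.predict(X2))


class TestPredictSRF:
    def test_zero_training_residuals_imply_r_zero_path(self):
        # stump on constant y: all first-stage residuals are 0
        data, nb = lattice_dataset(2, 3, np.zeros(6))
        y = np.arange(6, dtype=float)  # non-constant response
        data = s.AreaDataset(data.region_ids, pd.Series(y), data.X, data.centroids)
        train = data.subset([0, 1, 2, 3])
        test = data.subset([4, 5])
        model = s.fit_srf(train, nb, s.ForestSpec(n_trees=1, max_depth=0, seed=0))
        # force zero residuals and compare against an explicit r = 0 evaluation
        model.train_residuals[:] = 0.0
        pred = s.predict_srf(model, test, nb)
        Xt, _ = test.design_matrix()
        expected = model.rf2.predict(np.column_stack([Xt, np.zeros(2)]))
        np.testing.assert_allclose(pred, expected)

    def test_island_test_region_gets_finite_prediction(self):
        data = make_dataset(n=8, seed=1)
        ids = list(data.region_ids)
        nbrs = s.from_edge_list([(ids[i], ids[i + 1]) for i in range(6)], ids)
        train, test = data.subset(range(7)), data.subset([7])  # g7 is an island
        model = s.fit_srf(train, nbrs, s.ForestSpec(n_trees=20, seed=0))
        pred = s.predict_srf(model, test, nbrs)
        assert np.isfinite(pred).all()

    def test_unknown_test_region_rejected(self):
        data = make_dataset(n=6, seed=1)
        ids = list(data.region_ids)
        nbrs = s.from_edge_list([(ids[0], ids[1])], ids[:5])
        train, test = data.subset(range(5)), data.subset([5])
        model = s.fit_srf(train, nbrs, s.ForestSpec(n_trees=5, seed=0))
        with pytest.raises(DataError):
            s.predict_srf(model, test, nbrs)


class TestGRF:
    def test_degenerate_bandwidth_equals_global_rf(self):
        data, nb, _ = s.simulate_areal(s.SimConfig(nrows=6, ncols=6, seed=1))
        spec = s.ForestSpec(n_trees=40, seed=9)
        grf = s.fit_grf(data, data.centroids, bandwidth=data.n + 5, spec=spec)
        glob = s.fit_rf(data, spec)
        X, _ = data.design_matrix()
        np.testing.assert_array_equal(s.predict_grf(grf, data, data.centroids),
                                      glob.predict(X))

    def test_bandwidth_one_deep_tree_memorizes_own_response(self):
        data = make_dataset(n=15, seed=2, centroids=True)
        spec = s.ForestSpec(n_trees=1, min_leaf=1, seed=0)
        grf = s.fit_grf(data, data.centroids, bandwidth=1, spec=spec)
        np.testing.assert_allclose(
            s.predict_grf(grf, data, data.centroids), data.y.to_numpy()
        )

    def test_nearest_training_tie_broken_by_region_order(self):
        data = make_dataset(n=4, seed=3)
        cen = np.array([[0.0, 0.0], [2.0, 0.0], [5.0, 5.0], [6.0, 5.0]])
        grf = s.fit_grf(data.subset([0, 1, 2, 3]), cen, bandwidth=1,
                        spec=s.ForestSpec(n_trees=1, min_leaf=1, seed=0))
        # test point equidistant from training regions 0 and 1 -> region 0 wins
        pred = s.predict_grf(grf, data.subset([0]), np.array([[1.0, 0.0]]))
        assert pred[0] == pytest.approx(data.y.iloc[0])

    def test_local_models_beat_global_rf_under_sign_flipped_slopes(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 100
            cen = np.column_stack([rng.uniform(0, 10, n), rng.uniform(0, 1, n)])
            x = rng.standard_normal(n)
            slope = np.where(cen[:, 0] < 5, 2.0, -2.0)
            y = slope * x + 0.3 * rng.standard_normal(n)
            data = s.AreaDataset(
                tuple(f"g{i}" for i in range(n)), pd.Series(y),
                pd.DataFrame({"x1": x}), centroids=cen,
            )
            train, test = s.train_test_split(data, 0.8, seed)
            spec = s.ForestSpec(n_trees=100, seed=seed)
            grf = s.fit_grf(train, train.centroids, bandwidth=20, spec=spec)
            glob = s.fit_rf(train, spec)
            Xt, _ = test.design_matrix()
            yt = test.y.to_numpy()
            wins += s.rmse(yt, s.predict_grf(grf, test, test.centroids)) < \
                s.rmse(yt, glob.predict(Xt))
        assert wins >= 0.7 * 20

    def test_bad_bandwidth_rejected(self):
        data = make_dataset(n=10, centroids=True)
        with pytest.raises(ConfigurationError):
            s.fit_grf(data, data.centroids, bandwidth=0)

    def test_missing_centroids_rejected(self):
        data = make_dataset(n=10)
        with pytest.raises(DataError):
            s.fit_grf(data, None, bandwidth=3)
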