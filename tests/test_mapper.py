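import numpy as np
import pytest

from scplacer import (
    Embedding,
    GeneMatrix,
    MapperConfig,
    MapperModel,
    SpatialSlice,
    estimate_slice_weights,
    fit_coembed,
    fit_mapper,
    predict_locations,
    run_pipeline,
    simulate_layers,
    simulate_toy,
)


def _linear_problem(rng, n=300, noise=0.0):
    """Coordinates as a linear function of 4 standardized genes."""
    genes = [f"g{i}" for i in range(4)]
    X = rng.normal(size=(n, 4))
    X = (X - X.mean(0)) / X.std(0)
    A = np.array([[1.0, 0.0], [0.5, 1.0], [0.0, -1.0], [0.0, 0.0]])
    Y = X @ A + noise * rng.normal(size=(n, 2))
    gm = GeneMatrix(X, [f"c{i}" for i in range(n)], genes, "scaled")
    return SpatialSlice(gm, Y, slice_id="lin"), gm, Y


class TestEstimateSliceWeights:
    def test_single_slice_gets_weight_one(self, rng):
        z = Embedding(rng.normal(size=(200, 2)), [f"s{i}" for i in range(200)], "st")
        q = Embedding(rng.normal(size=(200, 2)), [f"c{i}" for i in range(200)], "sc")
        w, _ = estimate_slice_weights(q, [z], k=50, bandwidth=1.0, seed=0)
        assert w[0] == pytest.approx(1.0, abs=1e-9)

    def test_identical_slices_split_evenly(self, rng):
        zvals = rng.normal(size=(200, 2))
        a = Embedding(zvals, [f"a{i}" for i in range(200)], "a")
        b = Embedding(zvals.copy(), [f"b{i}" for i in range(200)], "b")
        q = Embedding(rng.normal(size=(300, 2)), [f"c{i}" for i in range(300)], "sc")
        w, _ = estimate_slice_weights(q, [a, b], k=50, bandwidth=1.0, seed=0)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-9)

    def test_distribution_matched_slice_outweighs_shifted(self, rng):
        q = Embedding(rng.normal(0.0, 1.0, (400, 2)), [f"c{i}" for i in range(400)], "sc")
        a = Embedding(rng.normal(0.0, 1.0, (300, 2)), [f"a{i}" for i in range(300)], "a")
        b = Embedding(rng.normal(3.0, 1.0, (300, 2)), [f"b{i}" for i in range(300)], "b")
        w, _ = estimate_slice_weights(q, [a, b], k=100, seed=0)
        assert w[0] > w[1]


class TestFitMapper:
    def test_uniform_weights_fit_linear_layers_below_floor(self, rng):
        sl, gm, Y = _linear_problem(rng)
        model = fit_coembed([sl], K=4)
        cfg = MapperConfig(seed=0, dropout=0.0, max_epochs=300)
        mapper = fit_mapper([sl], model, config=cfg)
        pred = predict_locations(mapper, gm)
        # held-out style check on fresh draws from the same linear law
        sl2, gm2, Y2 = _linear_problem(np.random.default_rng(99))
        pred2 = predict_locations(mapper, gm2)
        scale = np.prod(mapper.coord_scaler[1])
        mse = np.mean(np.sum((pred2 - Y2) ** 2, axis=1)) / scale
        assert mse < 0.01

    def test_training_loss_non_increasing_overall(self, toy_run):
        log = toy_run.mapper.train_log
        assert log[-1] <= log[0]

    def test_doubling_weights_leaves_fit_unchanged(self, rng):
        sl, gm, _ = _linear_problem(rng, n=150)
        model = fit_coembed([sl], K=4)
        cfg = MapperConfig(seed=4, dropout=0.0, weight_decay=0.0, max_epochs=60)
        w = np.abs(rng.normal(1.0, 0.3, 150))
        m1 = fit_mapper([sl], model, ratios=[w], config=cfg)
        m2 = fit_mapper([sl], model, ratios=[2.0 * w], config=cfg)
        np.testing.assert_allclose(
            predict_locations(m1, gm), predict_locations(m2, gm), atol=1e-10
        )

    def test_all_weight_on_one_spot_collapses_prediction(self, rng):
        sl, gm, Y = _linear_problem(rng, n=60)
        model = fit_coembed([sl], K=4)
        w = np.zeros(60)
        w[7] = 1.0
        cfg = MapperConfig(seed=0, dropout=0.0, max_epochs=400, patience=400,
                           clip_percentile=100.0)
        mapper = fit_mapper([sl], model, ratios=[w], config=cfg)
        pred = predict_locations(mapper, gm)
        target = Y[7]
        # the only spot carrying loss mass is reproduced almost exactly
        assert np.linalg.norm(pred[7] - target) < 0.05 * np.linalg.norm(
            Y.max(0) - Y.min(0)
        )

    def test_empty_slice_rejected(self, rng):
        sl, _, _ = _linear_problem(rng, n=10)
        model = fit_coembed([sl], K=4)
        empty = SpatialSlice(
            GeneMatrix(np.empty((0, 4)), [], sl.expr.gene_ids, "scaled"),
            np.empty((0, 2)),
            slice_id="empty",
        )
        with pytest.raises(ValueError, match="empty"):
            fit_mapper([empty], model)


class TestPredictLocations:
    def test_training_spots_recovered_after_convergence(self, toy_run, toy):
        pred = predict_locations(toy_run.mapper, toy_run.st_scaled[0].expr)
        span = np.prod(toy_run.mapper.coord_scaler[1])
        mse = np.mean(np.sum((pred - toy.coords) ** 2, axis=1)) / span
        assert mse < 0.05

    def test_identical_cells_get_identical_coordinates(self, toy_run):
        gm = toy_run.sc_scaled
        row = gm.values[5]
        dup = GeneMatrix(
            np.vstack([row, row]), ["a", "b"], gm.gene_ids, "scaled"
        )
        pred = predict_locations(toy_run.mapper, dup)
        np.testing.assert_array_equal(pred[0], pred[1])

    def test_unscaled_stage_rejected(self, toy_run, toy):
        with pytest.raises(ValueError, match="scaled"):
            predict_locations(toy_run.mapper, toy.expression())

    def test_toy_heldout_coordinate_correlation(self):
        # parameter-recovery: train on 80%, check per-axis Pearson r on 20%
        toy = simulate_toy(n=500, R=0.1, W=0.6, seed=11)
        rng = np.random.default_rng(11)
        idx = rng.permutation(500)
        train, test = idx[:400], idx[400:]
        expr = toy.expression()
        train_gm = GeneMatrix(
            expr.values[train], [expr.cell_ids[i] for i in train],
            expr.gene_ids, "lognorm",
        )
        test_gm = GeneMatrix(
            expr.values[test], [expr.cell_ids[i] for i in test],
            expr.gene_ids, "lognorm",
        )
        st = SpatialSlice(train_gm, toy.coords[train], slice_id="toy_train")
        res = run_pipeline([st], test_gm, do_lognorm=False, seed=11)
        for axis in range(2):
            r = np.corrcoef(res.predictions[:, axis], toy.coords[test, axis])[0, 1]
            assert r > 0.9


def test_ratio_weighted_fit_not_worse_under_covariate_shift():
    """With shifted query composition, importance weighting should not hurt
    generalization to the query distribution (mean over 5 seeds)."""
    deltas = []
    for seed in range(5):
        data = simulate_layers(
            n_layers=5, cells_per_layer=120, marker_strength=2.0,
            sc_cells_per_layer=[300, 45, 45, 45, 45], seed=seed,
        )
        mses = {}
        for weighted in (True, False):
            res = run_pipeline(
                [data.st], data.sc_expr, seed=seed, use_ratio_weights=weighted
            )
            mses[weighted] = float(
                np.mean(np.sum((res.predictions - data.sc_coords) ** 2, axis=1))
            )
        deltas.append(mses[True] - mses[False])
    assert np.mean(deltas) <= 0.005  # allow tiny Monte-Carlo slack around 0


def test_model_serialization_roundtrip(tmp_path, toy_run):
    toy_run.mapper.save(tmp_path)
    loaded = MapperModel.load(tmp_path)
    gm = toy_run.sc_scaled
    np.testing.assert_allclose(
        predict_locations(loaded, gm), predict_locations(toy_run.mapper, gm)
    )
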