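import numpy as np
import pytest

from scplacer import (
    GeneMatrix,
    SpatialSlice,
    add_noise,
    coarse_grain,
    morans_i,
    simulate_layers,
    simulate_toy,
)


def _slice_from(coords, values, genes=None):
    n = len(coords)
    genes = genes or ["gA", "gB"]
    gm = GeneMatrix(values, [f"c{i}" for i in range(n)], genes, "raw")
    return SpatialSlice(gm, np.asarray(coords, dtype=float), slice_id="cells")


class TestCoarseGrain:
    def test_single_cell_at_grid_intersection_captured(self):
        # a lone distant cell anchors the bounding box; the cell at (1, 1)
        # sits exactly on a grid intersection for spacing 1
        sl = _slice_from(
            [[0.0, 0.0], [1.0, 1.0]], [[1.0, 2.0], [3.0, 4.0]]
        )
        out = coarse_grain(sl, spacing=1.0)
        assert out.n_spots == 2
        np.testing.assert_array_equal(
            out.expr.values, [[1.0, 2.0], [3.0, 4.0]]
        )

    def test_radius_is_quarter_spacing(self):
        # center spot at (1,1); cell at 0.2*spacing inside, 0.3*spacing outside
        sl = _slice_from(
            [[0.0, 0.0], [2.0, 2.0], [1.0, 1.2], [1.0, 1.3]],
            [[1.0, 0.0], [1.0, 0.0], [0.0, 5.0], [0.0, 7.0]],
        )
        out = coarse_grain(sl, spacing=1.0)
        spot_map = {tuple(c): v for c, v in zip(out.coords, out.expr.values)}
        assert tuple(spot_map[(1.0, 1.0)]) == (0.0, 5.0)  # 0.3 excluded

    def test_spot_sums_match_brute_force_membership(self, rng):
        coords = rng.uniform(0.0, 10.0, (100, 2))
        values = rng.poisson(3.0, (100, 5)).astype(float)
        sl = _slice_from(coords, values, [f"g{i}" for i in range(5)])
        spacing = 1.0
        out = coarse_grain(sl, spacing)
        # brute force: scan every cell against every retained spot center
        for center, spot_expr in zip(out.coords, out.expr.values):
            d = np.linalg.norm(coords - center, axis=1)
            members = d <= spacing / 4.0
            np.testing.assert_allclose(spot_expr, values[members].sum(axis=0))
        # and no dropped spot should have had any member
        assert np.all(out.expr.values.sum(axis=1) > 0)

    def test_expression_conservation_bound(self, rng):
        coords = rng.uniform(0.0, 5.0, (60, 2))
        values = rng.poisson(2.0, (60, 3)).astype(float)
        sl = _slice_from(coords, values, ["a", "b", "c"])
        out = coarse_grain(sl, 1.0)
        assert out.expr.values.sum() <= values.sum()

    def test_oversized_spacing_rejected(self):
        sl = _slice_from([[0.0, 0.0], [1.0, 1.0]], [[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="spacing"):
            coarse_grain(sl, spacing=10.0)


class TestAddNoise:
    def test_sigma_zero_is_identity(self, rng):
        gm = GeneMatrix(
            rng.poisson(4.0, (30, 4)).astype(float),
            [f"c{i}" for i in range(30)],
            list("ABCD"),
            "raw",
        )
        out = add_noise(gm, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, gm.values)

    def test_constant_gene_unchanged_at_any_sigma(self):
        vals = np.column_stack([np.full(20, 7.0), np.arange(20, dtype=float)])
        gm = GeneMatrix(vals, [f"c{i}" for i in range(20)], ["const", "var"], "raw")
        out = add_noise(gm, 2.0, seed=0)
        np.testing.assert_array_equal(out.values[:, 0], vals[:, 0])

    def test_noise_variance_matches_stated_law(self):
        # sigma=1: pre-clipping noise variance should equal Var(X_j) per gene
        rng = np.random.default_rng(42)
        vals = rng.gamma(20.0, 5.0, (5000, 3))  # large values: clipping inactive
        gm = GeneMatrix(vals, [f"c{i}" for i in range(5000)], list("ABC"), "raw")
        out = add_noise(gm, 1.0, seed=9)
        noise = out.values - vals
        assert np.all(out.values >= 0)
        for j in range(3):
            ratio = noise[:, j].var() / vals[:, j].var()
            assert ratio == pytest.approx(1.0, abs=0.1)

    def test_output_non_negative_even_for_sparse_counts(self, rng):
        vals = rng.poisson(0.5, (200, 4)).astype(float)
        gm = GeneMatrix(vals, [f"c{i}" for i in range(200)], list("ABCD"), "raw")
        out = add_noise(gm, 3.0, seed=0)
        assert np.all(out.values >= 0)

    def test_reproducible_given_seed(self, rng):
        vals = rng.poisson(4.0, (50, 3)).astype(float)
        gm = GeneMatrix(vals, [f"c{i}" for i in range(50)], list("ABC"), "raw")
        np.testing.assert_array_equal(
            add_noise(gm, 0.5, seed=3).values, add_noise(gm, 0.5, seed=3).values
        )


class TestSimulateToy:
    def test_bit_reproducible_given_seed(self):
        a = simulate_toy(n=100, seed=5)
        b = simulate_toy(n=100, seed=5)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_noiseless_coordinates_are_deterministic_in_genes(self):
        toy = simulate_toy(n=200, R=0.0, seed=2)
        y1 = 2.0 * np.sin(toy.X[:, 0]) + 1.5 * toy.X[:, 1] ** 2
        y2 = -np.exp(-toy.X[:, 2]) + 2.5 * np.cos(toy.X[:, 3])
        np.testing.assert_allclose(toy.coords[:, 0], y1, atol=1e-12)
        np.testing.assert_allclose(toy.coords[:, 1], y2, atol=1e-12)

    def test_organizing_genes_are_uniform_on_0_2(self):
        toy = simulate_toy(n=2000, seed=0)
        block = toy.X[:, :4]
        assert block.min() >= 0.0 and block.max() <= 2.0
        assert abs(block.mean() - 1.0) < 0.05

    def test_smoothed_genes_have_higher_morans_i(self, toy):
        scores = [morans_i(toy.X[:, g], toy.coords) for g in range(10)]
        assert min(scores[4:]) > max(scores[:4])

    def test_vanishing_correlation_scale_kills_autocorrelation(self):
        toy = simulate_toy(n=500, W=1e-3, seed=0)
        for g in toy.svg_truth:
            assert abs(morans_i(toy.X[:, g], toy.coords)) < 0.1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_toy(n=500, R=-0.1)
        with pytest.raises(ValueError):
            simulate_toy(n=500, W=0.0)


class TestSimulateLayers:
    def test_layout_and_labels(self):
        data = simulate_layers(n_layers=3, cells_per_layer=50, seed=0)
        assert data.st.n_spots == 150
        assert sorted(set(data.st.labels)) == ["L1", "L2", "L3"]
        band = np.asarray(data.st.labels) == "L2"
        ys = data.st.coords[band, 1]
        assert ys.min() >= 1 / 3 and ys.max() <= 2 / 3

    def test_zero_marker_strength_gives_indistinguishable_layers(self):
        data = simulate_layers(
            n_layers=3, cells_per_layer=80, marker_strength=0.0, seed=1
        )
        X = data.st.expr.values
        labels = np.asarray(data.st.labels)
        # per-layer mean expression profiles should be statistically flat
        profiles = np.stack([X[labels == l].mean(axis=0) for l in ("L1", "L2", "L3")])
        assert profiles.std(axis=0).max() < 0.2

    def test_proportion_shift_shapes_query(self):
        data = simulate_layers(
            n_layers=4,
            cells_per_layer=50,
            sc_cells_per_layer=[100, 20, 20, 20],
            seed=0,
        )
        counts = {l: data.sc_labels.count(l) for l in set(data.sc_labels)}
        assert counts["L1"] == 100
        assert data.sc_expr.n_cells == 160

    def test_query_counts_are_sparse(self, laminar):
        assert (laminar.sc_expr.values == 0).mean() > 0.3
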