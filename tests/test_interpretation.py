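"""PDP, H-statistic, interaction amplification, ICE slopes and Z_marg,
checked against closed forms on exact function-models and against the
generating functions of dense ensemble fits."""

import numpy as np
import pandas as pd
import pytest

from forest_vuln import interpretation as it
from forest_vuln import model_training as mt
from forest_vuln import synth
from conftest import FunctionModel, make_records


def uniform_data(n, cols, seed=0, lo=0.0, hi=1.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(lo, hi, size=(n, len(cols))), columns=cols)


class TestPDP:
    def test_constant_model_centred_curve_is_zero(self):
        model = FunctionModel(["a", "b"], lambda M: np.full(len(M), 0.7))
        data = uniform_data(100, ["a", "b"])
        curve = it.pdp(model, "a", data)
        assert np.allclose(curve.pd_values, 0.0)

    def test_centred_curve_mean_zero(self, fitted_model, binned_split):
        train, _ = binned_split
        curve = it.pdp(fitted_model, "tmax", train.bins)
        assert abs(curve.pd_values.mean()) < 1e-10

    def test_grid_spans_data_range(self, fitted_model, binned_split):
        train, _ = binned_split
        curve = it.pdp(fitted_model, "tmax", train.bins, grid_size=50)
        assert len(curve.grid) == 50
        assert curve.grid[0] == pytest.approx(train.bins["tmax"].min())
        assert curve.grid[-1] == pytest.approx(train.bins["tmax"].max())

    def test_additive_decomposition_recovered(self):
        """For f = g1(a) + g2(b), the centred PDP of a equals centred g1."""
        model = FunctionModel(["a", "b"],
                              lambda M: 0.3 * M[:, 0] ** 2 + 0.2 * M[:, 1])
        data = uniform_data(2000, ["a", "b"])
        curve = it.pdp(model, "a", data)
        g1 = 0.3 * curve.grid ** 2
        assert np.max(np.abs(curve.pd_values - (g1 - g1.mean()))) < 1e-12

    def test_unknown_feature_rejected(self, fitted_model, binned_split):
        train, _ = binned_split
        with pytest.raises(ValueError, match="not a model predictor"):
            it.pdp(fitted_model, "slope", train.bins)


class TestHStatistic:
    def test_additive_function_zero_h(self):
        model = FunctionModel(["a", "b"],
                              lambda M: 0.4 * M[:, 0] + 0.3 * M[:, 1] ** 2)
        data = uniform_data(400, ["a", "b"])
        h = it.h_pairwise(model, "a", "b", data)
        assert h < 1e-6

    def test_symmetry(self, fitted_model, binned_split):
        train, _ = binned_split
        h_ij = it.h_pairwise(fitted_model, "tmax", "pcum", train.bins, seed=1)
        h_ji = it.h_pairwise(fitted_model, "pcum", "tmax", train.bins, seed=1)
        assert h_ij == pytest.approx(h_ji, abs=1e-12)

    def test_bounded_unit_interval(self, fitted_model, binned_split):
        train, _ = binned_split
        for pair, h in it.interaction_matrix(fitted_model, train.bins,
                                             seed=2).items():
            assert 0.0 <= h <= 1.0

    def test_pure_product_matches_closed_form(self):
        """f = x*y on centred uniform data: the analytic H of the
        generating function itself (main effects vanish)."""
        model = FunctionModel(["x", "y"], lambda M: M[:, 0] * M[:, 1])
        data = uniform_data(3000, ["x", "y"], lo=-1.0, hi=1.0)
        h = it.h_pairwise(model, "x", "y", data, n_rows=500, seed=0)
        # E[x] = E[y] = 0 so both one-way PDs vanish and H -> 1
        assert h == pytest.approx(1.0, abs=0.1)

    def test_flat_surface_reports_zero_with_warning(self):
        model = FunctionModel(["a", "b"], lambda M: np.zeros(len(M)))
        data = uniform_data(50, ["a", "b"])
        with pytest.warns(UserWarning, match="flat"):
            assert it.h_pairwise(model, "a", "b", data) == 0.0

    def test_dense_rf_fit_of_planted_product(self):
        """An ensemble fitted on a multiplicative surface reports H close
        to the value computed on the generating function directly."""
        truth, recs = make_records(
            11, 12_000, {"tmax": 0.0, "pcum": 0.0},
            interactions=[("tmax", "pcum", 0.15)])
        cols = ["tmax", "pcum"]
        model = mt.fit(mt.as_binned(recs, cols), cols, seed=0, n_trees=150,
                       n_search=0,
                       hyperparams={"max_depth": 12, "max_features": 2})
        fn = FunctionModel(cols, lambda M: synth.response(
            truth, {"tmax": M[:, 0], "pcum": M[:, 1]}))
        data = recs[cols]
        h_fit = it.h_pairwise(model, "tmax", "pcum", data, seed=3)
        h_true = it.h_pairwise(fn, "tmax", "pcum", data, seed=3)
        assert h_fit == pytest.approx(h_true, abs=0.1)


class TestCategoryMeans:
    def test_single_pair(self):
        mat = it.category_interaction_means(
            {("tmax", "slope"): 0.2}, {"tmax": "climate", "slope": "landscape"})
        assert mat.loc["climate", "landscape"] == pytest.approx(0.2)
        assert mat.loc["landscape", "climate"] == pytest.approx(0.2)
        assert np.isnan(mat.loc["forest", "forest"])

    def test_uniform_h_everywhere(self):
        pairs = {("tmax", "pcum"): 0.15, ("tmax", "tree_age"): 0.15,
                 ("pcum", "tree_age"): 0.15}
        cats = {"tmax": "climate", "pcum": "climate", "tree_age": "forest"}
        mat = it.category_interaction_means(pairs, cats)
        filled = mat.values[np.isfinite(mat.values)]
        assert np.allclose(filled, 0.15)

    def test_planted_cross_category_pair_is_maximal(self):
        """A planted forest x climate interaction makes that cell the
        largest category mean."""
        truth, recs = make_records(
            13, 10_000, {"tmax": 0.05, "tree_age": 0.05, "slope": 0.0},
            interactions=[("tmax", "tree_age", 0.15)])
        cols = ["tmax", "tree_age", "slope"]
        fn = FunctionModel(cols, lambda M: synth.response(
            truth, dict(zip(cols, M.T))))
        pairs = it.interaction_matrix(fn, recs[cols], seed=1, n_rows=400)
        from forest_vuln.features import categories_map
        mat = it.category_interaction_means(pairs, categories_map(cols))
        cell = mat.loc["forest", "climate"]
        others = [mat.loc[a, b] for a in mat.index for b in mat.columns
                  if np.isfinite(mat.loc[a, b]) and {a, b} != {"forest",
                                                               "climate"}
                  and "all" not in (a, b)]
        assert all(cell >= o for o in others)


class TestDeltaP:
    def test_additive_function_zero(self):
        model = FunctionModel(["a", "b"],
                              lambda M: 0.2 * M[:, 0] + 0.3 * M[:, 1])
        data = uniform_data(500, ["a", "b"])
        assert it.delta_p(model, "a", "b", data) == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_positive_interaction_amplifies_peak(self):
        model = FunctionModel(
            ["a", "b"],
            lambda M: 0.2 * M[:, 0] + 0.2 * M[:, 1] + 0.3 * M[:, 0] * M[:, 1])
        data = uniform_data(500, ["a", "b"])
        assert it.delta_p(model, "a", "b", data) > 0

    def test_matches_direct_evaluation_on_generator(self):
        """Delta-P of the exact multiplicative surface: peak of the two-way
        centred surface vs the additive reconstruction, hand-computed."""
        a = 0.2
        model = FunctionModel(["x", "y"],
                              lambda M: a * M[:, 0] * M[:, 1])
        data = uniform_data(4000, ["x", "y"], lo=0.0, hi=1.0)
        got = it.delta_p(model, "x", "y", data, n_rows=4000)
        # closed form on U(0,1)^2: PD_x(x) = a*x*E[y], centred;
        # two-way surface a*x*y centred; peaks at the (1,1) corner
        grid = np.linspace(data["x"].min(), data["x"].max(), 50)
        my = data["y"].mean()
        mx = data["x"].mean()
        pdx = a * grid * my
        pdy = a * grid * mx
        add_peak = (pdx - pdx.mean() + pdy - pdy.mean()).max()
        two = a * np.outer(grid, grid)
        two_peak = (two - two.mean()).max()
        expect = 100 * (two_peak - add_peak) / abs(add_peak)
        assert got == pytest.approx(expect, abs=2.0)

    def test_zero_reference_peak_missing(self):
        model = FunctionModel(["a", "b"], lambda M: np.zeros(len(M)))
        data = uniform_data(50, ["a", "b"])
        assert np.isnan(it.delta_p(model, "a", "b", data))


class TestICE:
    def test_linear_model_slope_recovered_exactly(self):
        model = FunctionModel(["a", "b"], lambda M: 2.0 * M[:, 0])
        row = np.array([0.5, 0.5])
        assert it.ice_sensitivity(model, "a", row) == pytest.approx(2.0)

    def test_dense_fit_slope_within_five_percent(self):
        # linear response inside the [0, 1] range so clipping never binds
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.uniform(0, 1, 20_000)})
        df["bl_rel"] = 0.8 * df["a"]
        df["area"], df["year"] = 1.0, 2005
        model = mt.fit(mt.as_binned(df, ["a"]), ["a"], seed=0, n_trees=100,
                       n_search=0,
                       hyperparams={"max_depth": None, "max_features": 1})
        s = it.ice_sensitivity(model, "a", np.array([0.5]),
                               grid=np.linspace(0, 1, 50))
        assert s == pytest.approx(0.8, rel=0.05)

    def test_constant_model_zero_slope(self):
        model = FunctionModel(["a"], lambda M: np.full(len(M), 0.3))
        assert it.ice_sensitivity(model, "a",
                                  np.array([0.1])) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_sign_flip_antisymmetry(self):
        up = FunctionModel(["a"], lambda M: 0.5 * M[:, 0])
        down = FunctionModel(["a"], lambda M: -0.5 * M[:, 0])
        s_up = it.ice_sensitivity(up, "a", np.array([0.5]))
        s_down = it.ice_sensitivity(down, "a", np.array([0.5]))
        assert s_up == pytest.approx(-s_down)


class TestZMarg:
    CATS = {"tree_age": "forest", "tmax": "climate", "slope": "landscape"}

    def test_share_arithmetic(self):
        z = it.z_marg({"tree_age": 2.0, "tmax": 1.0, "slope": 1.0}, self.CATS)
        assert z == {"forest": 50.0, "climate": 25.0, "landscape": 25.0}

    def test_single_category(self):
        z = it.z_marg({"tree_age": 0.0, "tmax": -0.4, "slope": 0.0}, self.CATS)
        assert z["climate"] == 100.0
        assert z["forest"] == 0.0

    def test_random_slopes_sum_to_hundred(self, rng):
        for _ in range(20):
            slopes = dict(zip(self.CATS, rng.normal(size=3)))
            z = it.z_marg(slopes, self.CATS)
            assert sum(z.values()) == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_missing(self):
        z = it.z_marg({"tmax": 0.0}, self.CATS)
        assert all(np.isnan(v) for v in z.values())
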