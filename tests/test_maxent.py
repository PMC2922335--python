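"""Maximum-entropy core: feature construction, fitting against independent
oracles, output transforms and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq, minimize
from scipy.stats import spearmanr

import nichecast as nc
from nichecast.features import auto_feature_classes, build_features
from nichecast.grid import ClimateStack, Grid, PointSet
from nichecast.maxent import (cumulative_from_raw, fit_maxent, logistic_from_raw,
                              predict_raw, read_lambdas, write_lambdas)


def simplex_max_entropy(fb, pbar):
    """Independent oracle: maximize entropy over the probability simplex
    subject to exact moment constraints, via a generic NLP solver."""
    n = fb.shape[0]
    cons = [{"type": "eq", "fun": lambda q: q.sum() - 1}]
    for j in range(fb.shape[1]):
        cons.append({"type": "eq",
                     "fun": (lambda jj: lambda q: q @ fb[:, jj] - pbar[jj])(j)})
    res = minimize(lambda q: (np.clip(q, 1e-12, None)
                              * np.log(np.clip(q, 1e-12, None))).sum(),
                   np.full(n, 1 / n), constraints=cons,
                   bounds=[(1e-12, 1)] * n, method="SLSQP",
                   options={"maxiter": 1000, "ftol": 1e-14})
    assert res.success
    return res.x / res.x.sum()


class TestFeatures:
    def test_auto_classes_by_sample_size(self):
        assert auto_feature_classes(9) == ("linear",)
        assert auto_feature_classes(10) == ("linear", "quadratic")
        assert auto_feature_classes(14) == ("linear", "quadratic")
        assert auto_feature_classes(15) == ("linear", "quadratic", "hinge")
        assert auto_feature_classes(100) == ("linear", "quadratic", "hinge",
                                             "product", "threshold")

    def test_single_linear_feature_scaled_to_unit(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 5, classes=("linear",))
        # one layer -> one linear feature per layer
        assert fs.n_features == tiny_stack.n_layers
        vals = fs.evaluate(tiny_stack.extract(bg.rows, bg.cols), clamp=False)
        assert vals.min() == pytest.approx(0.0)
        assert vals.max() == pytest.approx(1.0)

    def test_product_features_per_unordered_pair(self):
        rng = np.random.default_rng(1)
        grid = Grid(6, 6)
        stack = ClimateStack(grid, rng.normal(size=(4, 6, 6)), list("abcd"))
        bg = PointSet(grid, *np.divmod(np.arange(36), 6), "bg")
        fs = build_features(stack, bg, 100, classes=("product",))
        assert fs.n_features == 6  # C(4, 2)

    def test_constant_layer_features_dropped_with_warning(self):
        grid = Grid(4, 4)
        vals = np.stack([np.ones((4, 4)),
                         np.arange(16, dtype=float).reshape(4, 4)])
        stack = ClimateStack(grid, vals, ["const", "x"])
        bg = PointSet(grid, *np.divmod(np.arange(16), 4), "bg")
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(stack, bg, 12, classes=("linear", "quadratic"))
        assert fs.n_features == 2  # only the varying layer survives

    def test_hinge_knots_inside_background_range(self, tiny_stack, tiny_sets):
        _, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 50,
                            classes=("hinge", "threshold"))
        xb = tiny_stack.extract(bg.rows, bg.cols)
        for f in fs.features:
            li = f.layers[0]
            assert xb[:, li].min() < f.knot < xb[:, li].max()


class TestFitMaxent:
    def test_matched_means_give_uniform_distribution(self, tiny_stack):
        # presences = the whole background -> feature means match exactly
        grid = tiny_stack.grid
        all_cells = PointSet(grid, *np.divmod(np.arange(40), 8), "all")
        fs = build_features(tiny_stack, all_cells, 40, classes=("linear",))
        m = fit_maxent(all_cells, all_cells, fs, regularization=0.0,
                       stack=tiny_stack, tol=1e-12)
        np.testing.assert_allclose(m.weights, 0.0, atol=1e-6)
        np.testing.assert_allclose(m.background_raw, 1 / 40, rtol=1e-6)

    def test_single_feature_weight_matches_root_finding_oracle(self):
        grid = Grid(1, 4, 1.0, (0.0, 1.0))
        stack = ClimateStack(grid, np.array([[[0.0, 1.0, 2.0, 3.0]]]), ["x"])
        bg = PointSet(grid, np.zeros(4, int), np.arange(4), "bg")
        pres = PointSet(grid, np.zeros(2, int), np.array([1, 3]), "sp")
        fs = build_features(stack, bg, 2, classes=("linear",))
        m = fit_maxent(pres, bg, fs, regularization=0.0, stack=stack, tol=1e-14)
        # oracle: solve the 1-D moment condition on the scaled feature x/3
        f = np.array([0, 1, 2, 3]) / 3.0
        lam_star = brentq(
            lambda lam: (f * np.exp(lam * f)).sum() / np.exp(lam * f).sum() - 2 / 3,
            -50, 50, xtol=1e-13)
        assert m.weights[0] == pytest.approx(lam_star, abs=1e-6)

    def test_unpenalized_fit_matches_presence_means(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear", "quadratic"))
        m = fit_maxent(pres, bg, fs, regularization=0.0, stack=tiny_stack,
                       tol=1e-12)
        fb = fs.evaluate(tiny_stack.extract(bg.rows, bg.cols), clamp=False)
        fp = fs.evaluate(tiny_stack.extract(pres.rows, pres.cols), clamp=False)
        np.testing.assert_allclose(fb.T @ m.background_raw,
                                   fp.mean(axis=0), atol=1e-6)

    def test_agreement_with_simplex_oracle(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear", "quadratic"))
        m = fit_maxent(pres, bg, fs, regularization=0.0, stack=tiny_stack,
                       tol=1e-12)
        fb = fs.evaluate(tiny_stack.extract(bg.rows, bg.cols), clamp=False)
        fp = fs.evaluate(tiny_stack.extract(pres.rows, pres.cols), clamp=False)
        q = simplex_max_entropy(fb, fp.mean(axis=0))
        p = m.background_raw
        assert np.sum(p * np.log(p / q)) < 1e-4

    def test_regularization_monotonically_shrinks_weights(self, tiny_stack,
                                                          tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear", "quadratic"))
        norms = []
        for mult in (0.0, 0.5, 1.0, 2.0, 5.0):
            m = fit_maxent(pres, bg, fs, regularization=mult, stack=tiny_stack,
                           tol=1e-10)
            norms.append(np.abs(m.weights).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_background_permutation_equivariance(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear", "quadratic"))
        m1 = fit_maxent(pres, bg, fs, regularization=1.0, stack=tiny_stack)
        perm = np.random.default_rng(5).permutation(len(bg))
        bg2 = PointSet(bg.grid, bg.rows[perm], bg.cols[perm], "bg")
        fs2 = build_features(tiny_stack, bg2, 12, classes=("linear", "quadratic"))
        m2 = fit_maxent(pres, bg2, fs2, regularization=1.0, stack=tiny_stack)
        s1 = predict_raw(m1, tiny_stack)
        s2 = predict_raw(m2, tiny_stack)
        np.testing.assert_allclose(s1.raw, s2.raw, rtol=1e-8)

    def test_nonfinite_covariates_rejected(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear",))
        broken = tiny_stack.copy()
        broken.values[0, pres.rows[0], pres.cols[0]] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_maxent(pres, bg, fs, stack=broken)


class TestPrediction:
    def test_raw_sums_to_one_over_background(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear", "quadratic"))
        m = fit_maxent(pres, bg, fs, stack=tiny_stack)
        surf = predict_raw(m, tiny_stack)
        bg_unique = bg.dedupe()
        assert surf.raw[bg_unique.rows, bg_unique.cols].sum() == \
            pytest.approx(1.0, abs=1e-8)

    def test_zero_weights_give_constant_raw(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear",))
        m = fit_maxent(pres, bg, fs, regularization=1e6, stack=tiny_stack)
        assert np.abs(m.weights).max() == 0.0
        surf = predict_raw(m, tiny_stack)
        np.testing.assert_allclose(surf.raw, surf.raw.ravel()[0])

    def test_zero_delta_projection_identical(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear", "quadratic"))
        m = fit_maxent(pres, bg, fs, stack=tiny_stack)
        same = nc.apply_scenario(tiny_stack,
                                 nc.ScenarioDelta("g", "c", 2020, np.zeros(2)))
        np.testing.assert_array_equal(predict_raw(m, tiny_stack).raw,
                                      predict_raw(m, same).raw)

    def test_clamping_bounds_projection_features(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear",))
        m = fit_maxent(pres, bg, fs, stack=tiny_stack)
        far = nc.apply_scenario(tiny_stack,
                                nc.ScenarioDelta("g", "c", 2080,
                                                 np.array([100.0, 100.0])))
        surf = predict_raw(m, far)
        # with clamping, extreme projections saturate at the training edge
        edge = nc.apply_scenario(tiny_stack,
                                 nc.ScenarioDelta("g", "c", 2080,
                                                  np.array([1000.0, 1000.0])))
        np.testing.assert_allclose(surf.raw, predict_raw(m, edge).raw)


class TestOutputScales:
    def test_cumulative_of_stated_example(self):
        cum = cumulative_from_raw(np.array([0.5, 0.3, 0.2]),
                                  np.array([0.5, 0.3, 0.2]))
        np.testing.assert_allclose(cum, [100.0, 50.0, 20.0])

    def test_cumulative_tie_rule_inclusive(self):
        cum = cumulative_from_raw(np.array([0.25, 0.25, 0.5]),
                                  np.array([0.25, 0.25, 0.5]))
        np.testing.assert_allclose(cum, [50.0, 50.0, 100.0])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_cumulative_max_is_exactly_100(self, raw):
        raw = np.asarray(raw)
        raw = raw / raw.sum()
        cum = cumulative_from_raw(raw, raw)
        assert cum.max() == 100.0

    def test_uniform_raw_gives_logistic_half(self):
        n = 17
        raw = np.full(n, 1 / n)
        h = np.log(n)
        np.testing.assert_allclose(logistic_from_raw(raw, h), 0.5)

    def test_rank_order_preserved_across_scales(self, tiny_stack, tiny_sets):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 12, classes=("linear", "quadratic"))
        m = fit_maxent(pres, bg, fs, stack=tiny_stack)
        surf = predict_raw(m, tiny_stack)
        raw = surf.raw.ravel()
        # logistic is strictly monotone in raw: ranks agree exactly
        assert spearmanr(raw, surf.logistic.ravel()).statistic == \
            pytest.approx(1.0)
        # cumulative is weakly monotone (cells between two adjacent
        # background raw values share a cumulative value)
        order = np.argsort(raw)
        assert (np.diff(surf.cumulative.ravel()[order]) >= 0).all()
        # and strictly rank-preserving on the background cells themselves
        bgu = bg.dedupe()
        bg_raw = surf.raw[bgu.rows, bgu.cols]
        bg_cum = surf.cumulative[bgu.rows, bgu.cols]
        assert spearmanr(bg_raw, bg_cum).statistic == pytest.approx(1.0)


class TestSerialization:
    def test_lambdas_round_trip_reproduces_surface(self, tiny_stack, tiny_sets,
                                                   tmp_path):
        pres, bg = tiny_sets
        fs = build_features(tiny_stack, bg, 50,
                            classes=("linear", "quadratic", "hinge"))
        m = fit_maxent(pres, bg, fs, stack=tiny_stack)
        path = tmp_path / "model.lambdas"
        write_lambdas(m, path)
        m2 = read_lambdas(path)
        s1 = predict_raw(m, tiny_stack)
        s2 = predict_raw(m2, tiny_stack)
        np.testing.assert_array_equal(s1.raw, s2.raw)
        np.testing.assert_array_equal(s1.cumulative, s2.cumulative)
        np.testing.assert_array_equal(s1.logistic, s2.logistic)
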