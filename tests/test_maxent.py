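import itertools

import numpy as np
import pandas as pd
import pytest

import wildscape as ws
from wildscape.maxent import (DEFAULT_FC_GRID, DEFAULT_RM_GRID, Background,
                              predict_values)


def make_background(values, names=None):
    df = pd.DataFrame(values)
    if names:
        df.columns = names
    n = len(df)
    return Background(np.zeros(n), np.zeros(n), df)


def exhaustive_auc(pres, bg):
    """Mann-Whitney probability by explicit pair enumeration; ties count 1/2."""
    total = 0.0
    for p in pres:
        for b in bg:
            total += 1.0 if p > b else (0.5 if p == b else 0.0)
    return total / (len(pres) * len(bg))


def penalized_objective(lam, fp, fb, rm, beta):
    return fp.mean() * lam - np.log(np.mean(np.exp(lam * fb))) - rm * beta * abs(lam)


class TestFeatures:
    def test_linear_only_feature_count(self):
        X = np.random.default_rng(0).uniform(size=(10, 3))
        F, names, _ = ws.build_features(X, "L")
        assert F.shape[1] == 3 and len(names) == 3

    def test_lqp_feature_count(self):
        X = np.random.default_rng(0).uniform(size=(10, 3))
        F, names, _ = ws.build_features(X, "LQP")
        assert F.shape[1] == 3 + 3 + 3  # linear + squares + 3 pairs

    def test_forward_hinge_zero_at_or_below_knot(self):
        X = np.array([[0.0], [0.3], [0.5], [0.9]])
        F, names, _ = ws.build_features(X, "LH", n_knots=1)
        j = names.index("Hf:v0@0.500")
        assert F[0, j] == 0.0 and F[1, j] == 0.0 and F[2, j] == 0.0
        assert F[3, j] == pytest.approx(0.8)

    def test_unknown_class_letter_rejected(self):
        with pytest.raises(ValueError):
            ws.build_features(np.zeros((5, 2)), "LX")


class TestFit:
    def test_one_feature_matches_dense_grid_search(self):
        """Fitted weight within 1e-3 of the brute-force optimum of the
        penalized likelihood over lambda in [-10, 10]."""
        rng = np.random.default_rng(1)
        bg_raw = rng.uniform(0, 1, size=(400, 1))
        pres_raw = rng.uniform(0.5, 1, size=(20, 1))
        bg = make_background(bg_raw, ["z"])
        model = ws.fit_maxent(pd.DataFrame(pres_raw, columns=["z"]), bg,
                              fc="L", rm=0.5, tol=1e-8, max_iter=5000)
        # oracle works on the same scaled feature the model saw
        lo, hi = model.scale_min[0], model.scale_max[0]
        fp = (pres_raw[:, 0] - lo) / (hi - lo)
        fb = (bg_raw[:, 0] - lo) / (hi - lo)
        beta = 1.0 / np.sqrt(len(pres_raw))

        def objective(grid):
            return (fp.mean() * grid
                    - np.log(np.exp(np.outer(fb, grid)).mean(axis=0))
                    - 0.5 * beta * np.abs(grid))

        # coarse-to-fine dense search, final step 4e-6
        grid = np.linspace(-10, 10, 100_001)
        center = grid[np.argmax(objective(grid))]
        fine = np.linspace(center - 2e-4, center + 2e-4, 101)
        lam_star = fine[np.argmax(objective(fine))]
        assert model.weights[0] == pytest.approx(lam_star, abs=1e-3)

    def test_extreme_regularization_shrinks_all_weights(self):
        rng = np.random.default_rng(2)
        bg = make_background(rng.uniform(size=(200, 2)))
        pres = rng.uniform(0.6, 1.0, size=(15, 2))
        model = ws.fit_maxent(pres, bg, fc="LQ", rm=1e6)
        assert np.all(model.weights == 0.0)
        raw = predict_values(model, bg.values, "raw")
        np.testing.assert_allclose(raw, 1.0, atol=1e-12)

    def test_constant_feature_gets_zero_weight(self):
        rng = np.random.default_rng(3)
        bg_vals = np.column_stack([rng.uniform(size=300), np.full(300, 0.7)])
        pres_vals = np.column_stack([rng.uniform(0.5, 1, 25), np.full(25, 0.7)])
        model = ws.fit_maxent(pres_vals, make_background(bg_vals), fc="L", rm=0.5)
        assert model.weights[1] == 0.0

    def test_background_mean_raw_is_one(self, occurrences, stack, background):
        pres = ws.extract_presence_values(occurrences.subset("wolf"), stack)
        model = ws.fit_maxent(pres, background, fc="LQ", rm=1.0)
        raw = predict_values(model, background.values, "raw")
        assert abs(raw.mean() - 1.0) < 1e-6

    def test_nonfinite_values_rejected(self):
        bg = make_background(np.random.default_rng(0).uniform(size=(50, 1)))
        bad = np.array([[0.5], [np.nan], [0.2]])
        with pytest.raises(ValueError):
            ws.fit_maxent(bad, bg, fc="L")

    def test_model_json_round_trip(self, tmp_path, background):
        rng = np.random.default_rng(4)
        pres = pd.DataFrame(rng.uniform(0.5, 1, size=(10, 3)),
                            columns=background.values.columns)
        m = ws.fit_maxent(pres, background, fc="LQH", rm=2.0, n_knots=5)
        m.save(tmp_path / "m.json")
        back = ws.MaxentModel.load(tmp_path / "m.json")
        np.testing.assert_array_equal(back.weights, m.weights)
        x = background.values.to_numpy()[:20]
        np.testing.assert_allclose(back.raw(x), m.raw(x), rtol=1e-12)


class TestPrediction:
    def test_uniform_model_logistic_is_half(self, stack):
        bg = ws.sample_background(stack, 200, seed=1)
        pres = bg.values.iloc[:10]
        model = ws.fit_maxent(pres, bg, fc="L", rm=1e6)  # forced uniform
        suit = ws.predict_suitability(model, stack, "logistic")
        np.testing.assert_allclose(suit.values[np.isfinite(suit.values)], 0.5,
                                   atol=1e-12)

    def test_cloglog_and_logistic_rank_identical(self, occurrences, stack,
                                                 background):
        pres = ws.extract_presence_values(occurrences.subset("wolf"), stack)
        model = ws.fit_maxent(pres, background, fc="LQ", rm=0.5)
        a = ws.predict_suitability(model, stack, "cloglog").values.ravel()
        b = ws.predict_suitability(model, stack, "logistic").values.ravel()
        ok = np.isfinite(a)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(a[ok], b[ok])
        assert rho == pytest.approx(1.0)

    def test_layer_mismatch_is_schema_error(self, stack, background):
        pres = background.values.iloc[:10]
        model = ws.fit_maxent(pres, background, fc="L", rm=1.0)
        wrong = {"other": list(stack.values())[0]}
        with pytest.raises(ValueError, match="do not match"):
            ws.predict_suitability(model, wrong)


class TestAuc:
    def test_hand_counted_four_pairs(self):
        # one discordant pair of four -> 0.75
        assert ws.auc_score(np.array([0.9, 0.4]), np.array([0.5, 0.1])) == 0.75

    def test_all_ties_give_half(self):
        assert ws.auc_score(np.full(5, 0.3), np.full(7, 0.3)) == 0.5

    def test_perfect_separation_gives_one(self):
        assert ws.auc_score(np.array([0.8, 0.9]), np.array([0.1, 0.2])) == 1.0

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            pres = np.round(rng.uniform(size=40), 2)  # rounding forces ties
            bg = np.round(rng.uniform(size=150), 2)
            assert ws.auc_score(pres, bg) == pytest.approx(
                exhaustive_auc(pres, bg), abs=1e-12)


class TestThresholds:
    def test_mtss_separated_example(self):
        res = ws.compute_threshold(np.array([0.8, 0.9]), np.array([0.1, 0.2]))
        assert res.value == 0.8
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_mtss_equals_dense_sweep(self):
        rng = np.random.default_rng(6)
        pres = rng.uniform(0.3, 1.0, 50)
        bg = rng.uniform(0.0, 0.7, 200)
        res = ws.compute_threshold(pres, bg, "MTSS")
        sweep = np.arange(0.0, 1.0, 1e-3)
        ss = [(np.mean(pres >= t) + np.mean(bg < t)) for t in sweep]
        assert res.sensitivity + res.specificity >= max(ss) - 1e-12

    def test_p10_linear_interpolation(self):
        pres = np.arange(0.1, 1.01, 0.1)
        res = ws.compute_threshold(pres, np.array([0.0]), "P10")
        assert res.value == pytest.approx(0.19)


class TestAicc:
    def test_hand_arithmetic(self):
        """AICc = 2K - 2lnL + 2K(K+1)/(n-K-1): K=2, n=10, lnL=-5 -> 15.714."""
        K, n, lnL = 2, 10, -5.0
        assert 2 * K - 2 * lnL + 2 * K * (K + 1) / (n - K - 1) == pytest.approx(
            15.714, abs=1e-3)

    def test_degenerate_sample_size_gives_inf(self, background):
        rng = np.random.default_rng(7)
        pres = pd.DataFrame(rng.uniform(0.6, 1, size=(4, 3)),
                            columns=background.values.columns)
        model = ws.fit_maxent(pres, background, fc="LQH", rm=0.1, n_knots=10)
        if model.n_parameters + 1 >= len(pres):
            with pytest.warns(UserWarning, match="AICc undefined"):
                assert ws.aicc_score(model, pres, background.values) == np.inf

    def test_smaller_model_wins_at_equal_likelihood(self):
        n, lnL = 50, -20.0
        aicc = lambda K: 2 * K - 2 * lnL + 2 * K * (K + 1) / (n - K - 1)
        assert aicc(1) < aicc(3)


class TestCvAndTuning:
    def test_cv_report_shapes_and_bounds(self, occurrences, stack, background):
        pres = ws.extract_presence_values(occurrences.subset("wolf"), stack)
        rep = ws.cv_evaluate(pres, background, fc="L", rm=1.0, k=5, seed=0)
        assert len(rep.folds) == 5
        assert ((rep.folds["test_auc"] >= 0) & (rep.folds["test_auc"] <= 1)).all()
        assert ((rep.folds["omission"] >= 0) & (rep.folds["omission"] <= 1)).all()

    def test_fewer_presences_than_folds_rejected(self, background):
        pres = background.values.iloc[:3]
        with pytest.raises(ValueError):
            ws.cv_evaluate(pres, background, k=5)

    def test_single_cell_grid_selected(self, occurrences, stack, background):
        pres = ws.extract_presence_values(occurrences.subset("wolf"), stack)
        best, table = ws.tune_model(pres, background, rm_grid=[1.0],
                                    fc_grid=["L"], k=3, seed=0)
        assert best == {"rm": 1.0, "fc": "L"}
        assert len(table) == 1

    def test_full_grid_cardinality_is_forty(self, stack):
        """8 regularization multipliers x 5 feature-class sets -> 40 rows."""
        bg = ws.sample_background(stack, 150, seed=2)
        rng = np.random.default_rng(8)
        pres = bg.values.iloc[rng.choice(150, 30, replace=False)]
        _, table = ws.tune_model(pres, bg, rm_grid=DEFAULT_RM_GRID,
                                 fc_grid=DEFAULT_FC_GRID, k=2, seed=0,
                                 n_knots=3, max_iter=120)
        assert len(table) == 8 * 5 == 40
        assert set(table["fc"]) == set(DEFAULT_FC_GRID)


class TestBinarize:
    def test_threshold_zero_marks_all_valid_cells(self, stack):
        g = list(stack.values())[0]
        suit = g.like((g.values - g.values.min()) /
                      (g.values.max() - g.values.min()))
        out = ws.binarize_map(suit, 0.0)
        assert (out.values[np.isfinite(out.values)] == 1).all()

    def test_threshold_above_max_marks_none(self, stack):
        g = list(stack.values())[0]
        suit = g.like(np.clip(g.values, 0, 0.5))
        out = ws.binarize_map(suit, 1.0)
        assert (out.values[np.isfinite(out.values)] == 0).all()

    def test_value_equal_to_threshold_counts_suitable(self):
        g = ws.RasterGrid(np.full((5, 5), 0.406), (0, 0), 100.0)
        out = ws.binarize_map(g, 0.406)
        assert (out.values == 1).all()

    def test_nodata_propagates(self):
        vals = np.array([[0.9, np.nan], [0.1, 0.5]])
        out = ws.binarize_map(ws.RasterGrid(vals, (0, 0), 100.0), 0.5)
        assert np.isnan(out.values[0, 1])
        assert out.values[0, 0] == 1 and out.values[1, 0] == 0


class TestImportance:
    def test_importances_normalized_and_zero_weight_zero_contribution(
            self, occurrences, stack, background):
        pres = ws.extract_presence_values(occurrences.subset("wolf"), stack)
        model = ws.fit_maxent(pres, background, fc="L", rm=0.5)
        rep = ws.importance_suite(model, pres, background, n_permutations=3,
                                  seed=0)
        assert rep["permutation_importance"].sum() == pytest.approx(100, abs=1e-6)
        assert rep["percent_contribution"].sum() == pytest.approx(100, abs=1e-6)
        zero_w = [n for n, w in zip(model.predictor_names, model.weights) if w == 0]
        for name in zero_w:
            row = rep[rep["variable"] == name]
            assert row["percent_contribution"].iloc[0] == 0.0

    def test_single_variable_importance_is_100(self, stack, background):
        rng = np.random.default_rng(9)
        pres = pd.DataFrame({"field_0": rng.uniform(0.5, 2, 20)})
        bg1 = Background(background.x, background.y,
                         background.values[["field_0"]])
        model = ws.fit_maxent(pres, bg1, fc="L", rm=0.5)
        rep = ws.importance_suite(model, pres, bg1, n_permutations=3, seed=0)
        assert rep["permutation_importance"].iloc[0] == 100.0

    def test_duplicated_variable_jackknife_symmetry(self, background):
        rng = np.random.default_rng(10)
        z = rng.uniform(size=300)
        bg = make_background(np.column_stack([z, z]), ["a", "b"])
        pres_z = rng.uniform(0.5, 1, 25)
        pres = pd.DataFrame({"a": pres_z, "b": pres_z})
        model = ws.fit_maxent(pres, bg, fc="L", rm=0.5)
        rep = ws.importance_suite(model, pres, bg, n_permutations=3, seed=0)
        only = rep["jackknife_only_gain"].to_numpy()
        assert abs(only[0] - only[1]) < 1e-3  # copies carry the same signal
        # dropping either copy loses (almost) nothing
        full_gain = np.mean(np.log(model.raw(pres.to_numpy())))
        without = rep["jackknife_without_gain"].to_numpy()
        assert np.all(np.abs(without - full_gain) < 1e-2)


class TestResponseCurve:
    def test_constant_model_flat_curve(self, background):
        pres = background.values.iloc[:10]
        model = ws.fit_maxent(pres, background, fc="L", rm=1e6)
        curve = ws.response_curve(model, model.predictor_names[0], n_points=20)
        assert curve["suitability"].nunique() == 1

    def test_positive_linear_weight_monotone_curve(self):
        rng = np.random.default_rng(11)
        bg = make_background(rng.uniform(size=(300, 1)), ["z"])
        pres = pd.DataFrame({"z": rng.uniform(0.7, 1.0, 30)})
        model = ws.fit_maxent(pres, bg, fc="L", rm=0.5)
        assert model.weights[0] > 0
        curve = ws.response_curve(model, "z", n_points=50)
        assert len(curve) == 50
        assert np.all(np.diff(curve["suitability"]) >= 0)

    def test_unknown_variable_key_error(self, background):
        model = ws.fit_maxent(background.values.iloc[:10], background,
                              fc="L", rm=1.0)
        with pytest.raises(KeyError):
            ws.response_curve(model, "no_such_layer")


class TestBackgroundSampling:
    def test_uniform_bias_every_cell_once(self):
        stack = ws.generate_predictor_stack(12, (0, 0, 2000, 2000), 100.0, 2)
        n_cells = 20 * 20
        bg = ws.sample_background(stack, n_cells, seed=0)
        assert len(np.unique(np.round(bg.x + 1j * bg.y, 6))) == n_cells

    def test_zero_bias_region_never_sampled(self, stack):
        template = list(stack.values())[0]
        bias_vals = np.ones(template.shape)
        bias_vals[:, :20] = 0.0  # west half excluded
        bias = template.like(bias_vals)
        bg = ws.sample_background(stack, 300, bias=bias, seed=0)
        assert (bg.x > 2000.0).all()

    def test_biased_sampling_follows_two_to_one_ratio(self, stack):
        template = list(stack.values())[0]
        bias_vals = np.ones(template.shape)
        bias_vals[:, 20:] = 2.0  # east half twice as likely
        bias = template.like(bias_vals)
        bg = ws.sample_background(stack, 10_000, bias=bias, seed=3, replace=True)
        ratio = np.mean(bg.x > 2000.0) / np.mean(bg.x <= 2000.0)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_all_zero_bias_rejected(self, stack):
        template = list(stack.values())[0]
        bias = template.like(np.zeros(template.shape))
        with pytest.raises(ValueError):
            ws.sample_background(stack, 10, bias=bias)

    def test_oversampling_without_replacement_rejected(self, stack):
        with pytest.raises(ValueError):
            ws.sample_background(stack, 10**6, seed=0, replace=False)
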