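import numpy as np
import pytest
from scipy.special import logsumexp

from maxsdm import (EnvStack, FeatureSpec, GridDef, build_features,
                    default_fixture, fit, jackknife, optimal_range,
                    percent_contribution, predict, response_curve,
                    sample_occurrences, training_gain)
from maxsdm.synth import generate_env_stack, make_truth


def grid_search_objective(F_pr, F_bg, cvec, lam_grids):
    """Dense grid maximisation of the penalised objective (<= 2 features),
    vectorised over candidate coefficient vectors."""
    mesh = np.meshgrid(*lam_grids, indexing="ij")
    flat = np.column_stack([m.ravel() for m in mesh])       # (K, p)
    pbar = F_pr.mean(axis=0)
    best_val, best_lam = -np.inf, None
    for chunk in np.array_split(flat, max(1, len(flat) // 20000)):
        eta = F_bg @ chunk.T                                # (N, k)
        obj = (chunk @ pbar - logsumexp(eta, axis=0)
               - np.abs(chunk) @ cvec)
        i = int(np.argmax(obj))
        if obj[i] > best_val:
            best_val, best_lam = float(obj[i]), chunk[i]
    return best_lam, best_val


def simple_fit(pr_vals, bg_vals, names, classes="L", rm=1.0, **kw):
    spec = FeatureSpec(classes, hinge_knots=kw.pop("hinge_knots", 5))
    bg = build_features(bg_vals, spec, names)
    pr = build_features(pr_vals, spec, names, scaling=bg.scaling)
    return fit(pr, bg, rm=rm, **kw), pr, bg


class TestFit:
    def test_total_shrinkage_limit(self, presence_background):
        presence, background, names = presence_background
        mod, pr, _ = simple_fit(presence, background, names, "LQH", rm=1e6)
        assert mod.n_params == 0
        assert training_gain(mod, pr) == pytest.approx(0.0, abs=1e-12)
        assert mod.entropy == pytest.approx(np.log(mod.n_background))

    def test_one_feature_matches_grid_search(self):
        # binary feature: 80% of presences at 1, background half at 1;
        # the optimum solves E_q[f] = 0.8 - c, tractable by dense search
        bg_vals = np.array([[0.0]] * 50 + [[1.0]] * 50)
        pr_vals = np.array([[1.0]] * 8 + [[0.0]] * 2)
        for rm in (0.0, 0.5):
            mod, pr, bg = simple_fit(pr_vals, bg_vals, ["x"], "L", rm=rm,
                                     tol=1e-10)
            cvec = rm * mod.betas
            grid = [np.linspace(-3, 5, 160001)]
            lam_star, _ = grid_search_objective(pr.values, bg.values, cvec,
                                                grid)
            assert mod.lambdas[0] == pytest.approx(lam_star[0], abs=1e-3)

    def test_two_features_match_grid_search(self, rng):
        bg_vals = rng.random((80, 2))
        pr_idx = rng.choice(80, size=25)
        pr_vals = bg_vals[pr_idx] * 0.8 + 0.2  # biased presences
        mod, pr, bg = simple_fit(pr_vals, bg_vals, ["x", "y"], "L", rm=0.2,
                                 tol=1e-10)
        cvec = 0.2 * mod.betas
        grids = [np.linspace(-4, 6, 801), np.linspace(-4, 6, 801)]
        lam_coarse, _ = grid_search_objective(pr.values, bg.values, cvec,
                                              grids)
        grids = [np.linspace(l - 0.05, l + 0.05, 401) for l in lam_coarse]
        lam_star, _ = grid_search_objective(pr.values, bg.values, cvec, grids)
        np.testing.assert_allclose(mod.lambdas, lam_star, atol=1e-3)

    def test_background_normalization(self, fitted_lqh):
        mod, pr, bg = fitted_lqh
        q = np.exp(bg.values @ mod.lambdas - mod.log_partition)
        assert q.sum() == pytest.approx(1.0, abs=1e-8)

    def test_regularization_monotonicity(self, presence_background):
        presence, background, names = presence_background
        lo, _, _ = simple_fit(presence, background, names, "LQH", rm=0.5)
        hi, _, _ = simple_fit(presence, background, names, "LQH", rm=4.0)
        assert hi.n_params <= lo.n_params

    def test_parameter_recovery_from_truth(self):
        stack, truth, _ = default_fixture(seed=3)
        names = stack.layer_names[:3]
        occ = sample_occurrences(truth, n=5000, cluster_sd=0.0, seed=7)
        rows, cols = stack.grid.locate(occ.lons, occ.lats)
        pr_vals = stack.values_at_cells(rows, cols, names)
        bg_vals = stack.valid_values(names)
        mod, _, _ = simple_fit(pr_vals, bg_vals, names, "L", rm=0.01)
        raw = predict(mod, stack.subset(names), output="raw")
        r = np.corrcoef(raw[stack.mask], truth.suitability[stack.mask])[0, 1]
        assert r > 0.95

    def test_no_presence_errors(self, presence_background):
        presence, background, names = presence_background
        spec = FeatureSpec("L")
        bg = build_features(background, spec, names)
        pr = build_features(presence[:0], spec, names, scaling=bg.scaling)
        with pytest.raises(ValueError):
            fit(pr, bg)


class TestPredict:
    def test_uniform_model_logistic_half(self, presence_background):
        stack, _, _ = default_fixture(seed=0)
        presence, background, names = presence_background
        mod, _, _ = simple_fit(presence, background, names, "LQH", rm=1e6)
        logi = predict(mod, stack, output="logistic")
        np.testing.assert_allclose(logi[stack.mask], 0.5, atol=1e-12)

    def test_logistic_bounds(self, fitted_lqh):
        stack, _, _ = default_fixture(seed=0)
        mod, _, _ = fitted_lqh
        logi = predict(mod, stack, output="logistic")
        vals = logi[stack.mask]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_raw_sums_to_one_over_domain(self, fitted_lqh):
        stack, _, _ = default_fixture(seed=0)
        mod, _, _ = fitted_lqh
        raw = predict(mod, stack, output="raw")
        assert np.nansum(raw) == pytest.approx(1.0, abs=1e-8)

    def test_toy_logistic_hand_computation(self):
        # 3x3 single-variable toy, L feature with a printed coefficient
        g = GridDef(3, 3, 0.0, 3.0, 1.0)
        vals = np.arange(9, dtype=float).reshape(3, 3)
        stack = EnvStack(g, {"x": vals})
        bg_vals = vals.reshape(-1, 1)
        pr_vals = np.array([[6.0], [7.0], [8.0]])
        mod, _, _ = simple_fit(pr_vals, bg_vals, ["x"], "L", rm=1.0)
        lam = mod.lambdas[0]
        scaled = vals.ravel() / 8.0
        eta = lam * scaled
        z = logsumexp(eta)
        q = np.exp(eta - z)
        h = -np.sum(q * np.log(q))
        expected = (q * np.e ** h) / (1 + q * np.e ** h)
        got = predict(mod, stack, output="logistic").ravel()
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_cumulative_percentiles(self, fitted_lqh):
        stack, _, _ = default_fixture(seed=0)
        mod, _, _ = fitted_lqh
        cum = predict(mod, stack, output="cumulative")
        vals = cum[stack.mask]
        assert np.all((vals >= 0) & (vals <= 100))
        assert vals.max() == pytest.approx(100.0)

    def test_clamping_truncates_projection(self, fitted_lqh, rng):
        stack, _, _ = default_fixture(seed=0)
        mod, _, _ = fitted_lqh
        hot = EnvStack(stack.grid,
                       {n: v + 10 * np.ptp(v) for n, v in stack.layers.items()},
                       stack.mask)
        clamped = predict(mod, hot, output="logistic", clamp=True)
        # every variable pegged at its training max -> constant prediction
        assert np.nanstd(clamped) == pytest.approx(0.0, abs=1e-12)

    def test_missing_variable_named_in_error(self, fitted_lqh):
        stack, _, _ = default_fixture(seed=0)
        mod, _, _ = fitted_lqh
        partial = stack.subset(stack.layer_names[:2])
        with pytest.raises(KeyError, match="env3"):
            predict(mod, partial)


class TestDiagnostics:
    def test_training_gain_nonnegative_and_formula(self, fitted_lqh):
        mod, pr, bg = fitted_lqh
        gain = training_gain(mod, pr)
        assert gain >= 0
        # brute-force evaluation of the stated formula
        logq = pr.values @ mod.lambdas - mod.log_partition
        pen = mod.reg_multiplier * float(mod.betas @ np.abs(mod.lambdas))
        expected = logq.mean() + np.log(mod.n_background) - pen
        assert gain == pytest.approx(expected, rel=1e-12)

    def test_contributions_sum_to_100(self, fitted_lqh):
        mod, _, _ = fitted_lqh
        pc = percent_contribution(mod)
        assert pc.sum() == pytest.approx(100.0, abs=0.1)
        assert (pc >= 0).all()

    def test_single_active_variable_gets_all_credit(self, rng):
        bg_vals = np.column_stack([rng.random(200), np.full(200, 0.5)])
        idx = rng.random(200) < bg_vals[:, 0]
        pr_vals = bg_vals[idx][:50]
        mod, _, _ = simple_fit(pr_vals, bg_vals, ["signal", "const"], "L",
                               rm=0.5)
        pc = percent_contribution(mod)
        assert pc["signal"] == pytest.approx(100.0, abs=1e-9)

    def test_symmetric_variables_share_credit(self, rng):
        # two exchangeable informative variables -> contributions ~50/50
        n = 4000
        bg_vals = rng.random((n, 2))
        accept = rng.random(n) < (bg_vals[:, 0] + bg_vals[:, 1]) / 2
        pr_vals = bg_vals[accept][:800]
        mod, _, _ = simple_fit(pr_vals, bg_vals, ["a", "b"], "L", rm=0.1)
        pc = percent_contribution(mod)
        assert pc["a"] == pytest.approx(50.0, abs=5.0)

    def test_jackknife_redundant_variable(self, rng):
        bg = rng.random((300, 1))
        bg_vals = np.column_stack([bg[:, 0], bg[:, 0]])  # duplicated variable
        idx = rng.random(300) < bg[:, 0]
        pr_vals = bg_vals[idx][:60]
        table = jackknife(pr_vals, bg_vals, ["v1", "v2"], FeatureSpec("L"),
                          rm=0.5)
        full = table["gain_full"].iloc[0]
        assert table.loc["v1", "gain_without"] == pytest.approx(full, abs=0.02)
        assert (table[["gain_only", "gain_without", "gain_full"]] >= -1e-9
                ).all().all()

    def test_jackknife_planted_signal(self, rng):
        n = 500
        bg_vals = rng.random((n, 3))
        accept = rng.random(n) < bg_vals[:, 1] ** 2
        pr_vals = bg_vals[accept][:80]
        table = jackknife(pr_vals, bg_vals, ["noise1", "signal", "noise2"],
                          FeatureSpec("LQ"), rm=0.5)
        assert table["gain_only"].idxmax() == "signal"


class TestResponseCurves:
    def test_monotone_for_positive_linear_model(self, rng):
        bg_vals = rng.random((300, 2))
        accept = rng.random(300) < bg_vals[:, 0]
        pr_vals = bg_vals[accept][:60]
        mod, _, _ = simple_fit(pr_vals, bg_vals, ["x", "y"], "L", rm=0.5)
        assert mod.lambdas[0] > 0
        curve = response_curve(mod, "x", n_points=50)
        assert np.all(np.diff(curve["suitability"]) >= 0)
        assert curve["suitability"].between(0, 1).all()

    def test_peak_recovered_for_quadratic_truth(self, rng):
        # presences drawn around x0 = 0.6 -> response peak near 0.6
        n = 6000
        bg_vals = rng.random((n, 1))
        accept = rng.random(n) < np.exp(-((bg_vals[:, 0] - 0.6) / 0.1) ** 2)
        pr_vals = bg_vals[accept]
        mod, _, _ = simple_fit(pr_vals, bg_vals, ["x"], "LQ", rm=0.1)
        curve = response_curve(mod, "x", n_points=201)
        peak = curve["value"][curve["suitability"].idxmax()]
        assert peak == pytest.approx(0.6, abs=0.05)


class TestOptimalRange:
    def test_never_reaching_threshold_is_empty(self):
        import pandas as pd
        curve = pd.DataFrame({"value": [0, 1, 2],
                              "suitability": [0.1, 0.2, 0.3]})
        assert optimal_range(curve, 0.5) is None

    def test_piecewise_linear_hand_solution(self):
        import pandas as pd
        curve = pd.DataFrame({"value": [0.0, 1.0, 2.0, 3.0],
                              "suitability": [0.0, 0.8, 0.8, 0.0]})
        lo, hi = optimal_range(curve, 0.5)
        # crossings by linear interpolation: 0.5/0.8 and 3 - 0.5/0.8
        assert lo == pytest.approx(0.625)
        assert hi == pytest.approx(2.375)

    def test_symmetric_curve_symmetric_range(self):
        import pandas as pd
        x = np.linspace(0, 1, 101)
        y = np.exp(-((x - 0.5) / 0.15) ** 2)
        curve = pd.DataFrame({"value": x, "suitability": y})
        lo, hi = optimal_range(curve, 0.5)
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=0.01)


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, fitted_lqh, tmp_path):
        from maxsdm import MaxEntModel
        stack, _, _ = default_fixture(seed=0)
        mod, _, _ = fitted_lqh
        path = tmp_path / "model.json"
        mod.to_json(path)
        back = MaxEntModel.from_json(path)
        a = predict(mod, stack, output="logistic")
        b = predict(back, stack, output="logistic")
        np.testing.assert_allclose(a[stack.mask], b[stack.mask], rtol=1e-12)
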