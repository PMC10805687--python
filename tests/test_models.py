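import math

import numpy as np
import pytest

from survrank.clinical_io import FeatureSpec, SurvivalTable
from survrank.metrics import concordance_index, nelson_aalen
from survrank.models import (
    ConvergenceError,
    cox_partial_loglik,
    fit_cox,
    fit_deepsurv,
    fit_model,
    fit_rsf,
    logrank_split_statistic,
    predict_risk,
    predict_survival,
)
from survrank.synthetic import generate

from conftest import gaussian_cohort_spec


def _independent_breslow_loglik(x, time, event, beta):
    """Loop-based Breslow partial log-likelihood (test oracle)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk_set = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk_set))
    return ll


class TestCox:
    def test_symmetric_groups_give_zero_coefficient(self):
        # both covariate levels share the same (time, event) multiset
        feats = [FeatureSpec("g", "binary", coding={"no": 0, "yes": 1})]
        X = {"g": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]}
        table = SurvivalTable(feats, X, [1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        model = fit_cox(table)
        assert abs(model.beta[0]) < 1e-8

    def test_matches_grid_search_maximizer(self, toy_table):
        model = fit_cox(toy_table)
        x = toy_table.X["treated"].to_numpy()
        grid = np.arange(-5.0, 5.0 + 1e-9, 1e-4)
        lls = [
            _independent_breslow_loglik(x, toy_table.time, toy_table.event, b)
            for b in grid
        ]
        best = grid[int(np.argmax(lls))]
        assert model.beta[0] == pytest.approx(best, abs=1e-4)

    def test_parameter_recovery_on_weibull_ph_cohort(self, recovery_table):
        model = fit_cox(recovery_table)
        assert model.beta[0] == pytest.approx(1.0, abs=0.1)
        assert model.beta[1] == pytest.approx(-0.5, abs=0.1)

    def test_loglik_at_estimate_beats_null(self, recovery_table):
        model = fit_cox(recovery_table)
        X = recovery_table.X.to_numpy()
        ll_hat = cox_partial_loglik(X, recovery_table.time,
                                    recovery_table.event, model.beta)
        ll_null = cox_partial_loglik(X, recovery_table.time,
                                     recovery_table.event,
                                     np.zeros_like(model.beta))
        assert ll_hat >= ll_null

    def test_complete_separation_advises_ridge(self):
        # the covariate perfectly orders survival: beta escapes to infinity
        feats = [FeatureSpec("x", "numeric")]
        n = 20
        times = np.arange(1.0, n + 1)
        table = SurvivalTable(feats, {"x": -times}, times, np.ones(n, int))
        with pytest.raises(ConvergenceError, match="ridge"):
            fit_cox(table)
        ridged = fit_cox(table, ridge=1.0)   # penalised fit succeeds
        assert np.isfinite(ridged.beta[0])

    def test_null_model_has_identical_curves(self):
        feats = [FeatureSpec("g", "binary", coding={"no": 0, "yes": 1})]
        X = {"g": [0.0, 0.0, 1.0, 1.0]}
        table = SurvivalTable(feats, X, [1, 2, 1, 2], [1, 1, 1, 1])
        model = fit_cox(table)
        curves = predict_survival(model, table.X)
        for c in curves[1:]:
            np.testing.assert_allclose(c.values, curves[0].values, atol=1e-8)

    def test_higher_linear_predictor_lower_survival(self, recovery_table):
        model = fit_cox(recovery_table)
        sub = recovery_table.X.iloc[:50]
        lp = predict_risk(model, sub)
        curves = predict_survival(model, sub)
        order = np.argsort(lp)
        for lo, hi in zip(order[:-1], order[1:]):
            assert np.all(curves[hi].values <= curves[lo].values + 1e-12)


class TestLogrankSplit:
    def test_identical_survival_experience_scores_zero(self):
        time = [1, 2, 3, 1, 2, 3]
        event = [1, 1, 0, 1, 1, 0]
        group = [0, 0, 0, 1, 1, 1]
        assert logrank_split_statistic(time, event, group) == 0.0

    def test_matches_hand_tabulation(self):
        # textbook two-group toy, oracle = explicit O/E/V accumulation
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 1, 0, 1])
        group = np.array([1, 1, 0, 1, 0, 0])
        O = E = V = 0.0
        for t in np.unique(time[event == 1]):
            at_risk = time >= t
            n, n1 = at_risk.sum(), (at_risk & (group == 1)).sum()
            d = ((time == t) & (event == 1)).sum()
            d1 = ((time == t) & (event == 1) & (group == 1)).sum()
            O += d1
            E += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected = (O - E) ** 2 / V
        assert logrank_split_statistic(time, event, group) == pytest.approx(
            expected, rel=1e-12
        )

    def test_invariant_to_label_swap(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 30) + 0.1
        e = (rng.random(30) < 0.7).astype(int)
        g = rng.integers(0, 2, 30)
        a = logrank_split_statistic(t, e, g)
        b = logrank_split_statistic(t, e, 1 - g)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_split_statistic([1, 2], [1, 1], [1, 1])


class TestRandomSurvivalForest:
    def _separable_table(self):
        # binary feature splits the cohort into early-event vs late-event halves
        feats = [FeatureSpec("noise", "numeric"),
                 FeatureSpec("split", "binary", coding={"no": 0, "yes": 1})]
        rng = np.random.default_rng(1)
        n = 40
        split = np.repeat([0.0, 1.0], n // 2)
        time = np.where(split == 0, rng.uniform(1, 5, n), rng.uniform(20, 30, n))
        X = {"noise": rng.normal(size=n), "split": split}
        return SurvivalTable(feats, X, time, np.ones(n, int))

    def test_root_splits_on_perfectly_separating_feature(self):
        table = self._separable_table()
        model = fit_rsf(table, n_trees=1, mtry=2, min_leaf=3, max_depth=1,
                        bootstrap=False, seed=0)
        tree = model.trees[0]
        assert tree.feature[0] == 1          # the binary "split" column
        assert tree.threshold[0] == pytest.approx(0.5)

    def test_leaf_curve_is_nelson_aalen_of_leaf_samples(self):
        table = self._separable_table()
        model = fit_rsf(table, n_trees=1, mtry=2, min_leaf=3, max_depth=1,
                        bootstrap=False, seed=0)
        mask = table.X["split"].to_numpy() == 0.0
        na = nelson_aalen(table.time[mask], table.event[mask])
        chf = model.predict_chf(table.X[mask])
        np.testing.assert_allclose(chf[0], na(model.event_grid), atol=1e-12)

    def test_ensemble_chf_non_decreasing(self, signal_table):
        model = fit_rsf(signal_table.subset(np.arange(150)), n_trees=10,
                        seed=3)
        chf = model.predict_chf(signal_table.X.iloc[150:200])
        assert np.all(np.diff(chf, axis=1) >= -1e-12)

    def test_null_covariates_score_near_chance(self):
        # out-of-sample C stays in [0.4, 0.6] across seeds on pure noise
        for seed in range(20):
            spec = gaussian_cohort_spec(500, [0.0, 0.0, 0.0], seed=100 + seed,
                                        censoring_rate=0.03)
            table = generate(spec)
            train, test = table.subset(np.arange(350)), table.subset(np.arange(350, 500))
            model = fit_rsf(train, n_trees=25, max_depth=4, seed=seed)
            c = concordance_index(test.time, test.event,
                                  predict_risk(model, test.X)).value
            assert 0.4 <= c <= 0.6

    def test_single_strong_covariate_recovered(self):
        for seed in range(20):
            spec = gaussian_cohort_spec(500, [1.5, 0.0, 0.0], seed=200 + seed,
                                        censoring_rate=0.03)
            table = generate(spec)
            train, test = table.subset(np.arange(350)), table.subset(np.arange(350, 500))
            model = fit_rsf(train, n_trees=25, max_depth=4, seed=seed)
            c = concordance_index(test.time, test.event,
                                  predict_risk(model, test.X)).value
            assert c > 0.6

    def test_invalid_params_rejected(self, signal_table):
        with pytest.raises(ValueError, match="n_trees"):
            fit_rsf(signal_table, n_trees=0)
        with pytest.raises(ValueError, match="mtry"):
            fit_rsf(signal_table, mtry=99)

    def test_deterministic_given_seed(self, signal_table):
        sub = signal_table.subset(np.arange(120))
        a = fit_rsf(sub, n_trees=5, seed=7)
        b = fit_rsf(sub, n_trees=5, seed=7)
        np.testing.assert_array_equal(
            predict_risk(a, signal_table.X.iloc[120:180]),
            predict_risk(b, signal_table.X.iloc[120:180]),
        )


class TestDeepSurv:
    def test_degenerate_linear_config_recovers_cox_direction(self, recovery_table):
        cox = fit_cox(recovery_table)
        ds = fit_deepsurv(recovery_table, hidden_sizes=(), epochs=800,
                          learning_rate=0.5, seed=0)
        w = ds.weights[0].ravel() / ds.scale_
        cos = float(w @ cox.beta / (np.linalg.norm(w) * np.linalg.norm(cox.beta)))
        assert math.acos(min(cos, 1.0)) < 0.05

    def test_nonlinear_risk_beats_linear_cox(self):
        # risk depends on |x1|: invisible to a linear score
        from survrank.synthetic import (
            apply_censoring,
            sample_covariates,
            sample_event_times,
            _rng,
        )

        spec = gaussian_cohort_spec(2000, [0.0, 0.0], seed=21)
        X = sample_covariates(spec, _rng(21, 0))
        T = sample_event_times(np.abs(X.to_numpy()), np.array([1.2, 0.0]),
                               1.5, 10.0, _rng(21, 1))
        time, event = apply_censoring(T, spec.censoring, _rng(21, 2))
        feats = [FeatureSpec("f0", "numeric"), FeatureSpec("f1", "numeric")]
        table = SurvivalTable(feats, X, time, event)
        train, test = table.subset(np.arange(1400)), table.subset(np.arange(1400, 2000))
        cox = fit_cox(train)
        ds = fit_deepsurv(train, hidden_sizes=(32,), epochs=400,
                          learning_rate=0.2, seed=1)
        c_cox = concordance_index(test.time, test.event,
                                  predict_risk(cox, test.X)).value
        c_ds = concordance_index(test.time, test.event,
                                 predict_risk(ds, test.X)).value
        assert c_ds > c_cox

    def test_bit_identical_refit(self, signal_table):
        sub = signal_table.subset(np.arange(200))
        a = fit_deepsurv(sub, epochs=50, seed=9)
        b = fit_deepsurv(sub, epochs=50, seed=9)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        assert a.loss_trajectory == b.loss_trajectory

    def test_loss_trajectory_non_increasing(self, signal_table):
        model = fit_deepsurv(signal_table.subset(np.arange(200)), epochs=100,
                             seed=2)
        traj = np.array(model.loss_trajectory)
        assert np.all(np.diff(traj) <= 1e-12)


class TestSharedContract:
    @pytest.mark.parametrize("kind,params", [
        ("cox", None),
        ("rsf", {"n_trees": 10, "max_depth": 4}),
        ("deepsurv", {"epochs": 40, "hidden_sizes": (8,)}),
    ])
    def test_risk_invariant_to_row_order(self, signal_table, kind, params):
        model = fit_model(signal_table.subset(np.arange(200)), kind, params,
                          seed=5)
        X = signal_table.X.iloc[200:260]
        risk = predict_risk(model, X)
        perm = np.random.default_rng(0).permutation(len(X))
        risk_perm = predict_risk(model, X.iloc[perm])
        np.testing.assert_allclose(risk_perm, risk[perm], rtol=1e-12)
        assert np.all(np.isfinite(risk))

    @pytest.mark.parametrize("kind,params", [
        ("cox", None),
        ("rsf", {"n_trees": 10, "max_depth": 4}),
        ("deepsurv", {"epochs": 40, "hidden_sizes": (8,)}),
    ])
    def test_survival_curves_obey_invariants(self, signal_table, kind, params):
        model = fit_model(signal_table.subset(np.arange(200)), kind, params,
                          seed=5)
        curves = predict_survival(model, signal_table.X.iloc[200:210])
        for c in curves:
            assert c.value_before_first == 1.0
            assert np.all(c.values <= 1.0 + 1e-12)
            assert np.all(np.diff(c.values) <= 1e-12)

    def test_feature_mismatch_named(self, signal_table):
        model = fit_cox(signal_table)
        bad = signal_table.X.rename(columns={"f0": "wrong"})
        with pytest.raises(ValueError, match="f0"):
            predict_risk(model, bad)

    def test_unknown_kind_rejected(self, signal_table):
        with pytest.raises(ValueError, match="kind"):
            fit_model(signal_table, "svm")
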