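"""Maximum-entropy model: features, fitting, transforms, diagnostics."""
import numpy as np
import pytest
from scipy.stats import spearmanr

from enmpipe.grid import EnvStack, GridSpec
from enmpipe.maxent import (
    FeatureExpander,
    expand_features,
    fit_maxent,
    permutation_importance,
    predict_raw,
    raw_to_cloglog,
    raw_to_logistic,
    select_variables,
    train_maxent,
    vif,
)


def two_cell_model(beta=0.2, n_pres=10):
    """All presences in cell B of an {A, B} domain with one binary feature."""
    Fp = np.ones((n_pres, 1))
    Fb = np.array([[0.0], [1.0]] * 5)
    return fit_maxent(Fp, Fb, beta=beta)


class TestFeatureExpansion:
    def test_lq_feature_count(self, rng):
        X = rng.uniform(size=(50, 2))
        _, Fb, exp = expand_features(X[:10], X, ["a", "b"], "lq")
        assert Fb.shape[1] == 4 and exp.n_features == 4

    def test_lp_feature_count_three_vars(self, rng):
        X = rng.uniform(size=(50, 3))
        _, Fb, exp = expand_features(X[:10], X, ["a", "b", "c"], "lp")
        assert Fb.shape[1] == 3 + 3  # 3 linear + C(3,2) products

    def test_hinge_formula_pointwise(self, rng):
        """Hinge feature at knot k on scaled x equals max(0, (x-k)/(1-k))."""
        X = rng.uniform(0, 10, size=(200, 1))
        exp = FeatureExpander(["v"], "h", n_knots=10).fit(X)
        F = exp.transform(X)
        scaled = (X[:, 0] - X.min()) / (X.max() - X.min())
        for i, k in enumerate(exp.hinge_knots):
            expect = np.maximum(0.0, (scaled - k) / (1.0 - k))
            assert np.allclose(F[:, i], expect, atol=1e-12)

    def test_feature_values_bounded_and_presence_clamped(self, rng):
        Xb = rng.uniform(0, 1, size=(100, 2))
        Xp = np.array([[-5.0, 9.0]])  # outside the background envelope
        Fp, Fb, _ = expand_features(Xp, Xb, ["a", "b"], "lqpth")
        assert Fb.min() >= 0 and Fb.max() <= 1
        assert Fp.min() >= 0 and Fp.max() <= 1

    def test_constant_variable_dropped_with_warning(self, rng):
        X = np.column_stack([rng.uniform(size=50), np.full(50, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            exp = FeatureExpander(["a", "b"], "l").fit(X)
        assert exp.feature_names == ["l:a"]


class TestFit:
    def test_matched_means_give_zero_weights_and_uniform_raw(self, rng):
        X = rng.uniform(size=(40, 3))
        Fp = X.copy()  # presence sample identical to background
        model = fit_maxent(Fp, X, rm=1.0)
        assert np.allclose(model.lam, 0.0, atol=1e-5)
        raw = predict_raw(model, X)
        assert np.allclose(raw, 1.0 / 40, atol=1e-4)

    def test_two_cell_closed_form(self):
        """Stationarity 1/(1+e^lam) = beta gives lam = ln 4 and raw(B) = 0.8
        at an effective penalty of 0.2."""
        model = two_cell_model(beta=0.2)
        assert model.lam[0] == pytest.approx(np.log(4), abs=1e-5)
        raw = predict_raw(model, np.array([[0.0], [1.0]]))
        assert raw == pytest.approx([0.2, 0.8], abs=1e-5)

    def test_stronger_regularization_shrinks_weights(self, rng):
        X = rng.uniform(size=(500, 3))
        pres = X[(X[:, 0] + 0.3 * rng.standard_normal(500)) > 0.7]
        m1 = fit_maxent(pres, X, rm=1.0)
        m10 = fit_maxent(pres, X, rm=10.0)
        assert np.abs(m10.lam).sum() < np.abs(m1.lam).sum()

    def test_background_weights_shift_the_distribution(self):
        Fb = np.array([[0.0], [1.0]] * 10)
        Fp = np.ones((5, 1))
        w = np.where(Fb[:, 0] > 0, 4.0, 1.0)  # availability skewed toward B
        m_flat = fit_maxent(Fp, Fb, beta=0.2)
        m_wt = fit_maxent(Fp, Fb, beta=0.2, weights=w)
        # with B already 4x more available, less weight is needed to explain
        # the presences there
        assert m_wt.lam[0] < m_flat.lam[0]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_maxent(np.ones((5, 1)), np.ones((5, 1)))  # background too small
        with pytest.raises(ValueError):
            fit_maxent(np.ones((5, 1)), np.zeros((20, 1)), rm=-1)


class TestPrediction:
    def make_stack(self, rng, nrows=6, ncols=6):
        spec = GridSpec(nrows, ncols, 0.0, 0.0, 0.5)
        return EnvStack(spec, {"a": rng.uniform(size=(nrows, ncols)),
                               "b": rng.uniform(size=(nrows, ncols))})

    def test_scores_sum_to_one_over_grid(self, rng):
        env = self.make_stack(rng)
        pres = env.table()[:5]
        model = train_maxent(pres, env.table(), ["a", "b"], classes="lq")
        raw = predict_raw(model, env)
        assert np.nansum(raw) == pytest.approx(1.0)
        assert np.nanmin(raw) >= 0

    def test_missing_variable_is_named(self, rng):
        env = self.make_stack(rng)
        model = train_maxent(env.table()[:5], env.table(), ["a", "b"])
        bad = EnvStack(env.spec, {"a": env.layers["a"]})
        with pytest.raises(KeyError, match="b"):
            predict_raw(model, bad)

    def test_prediction_invariant_to_variable_order(self, rng):
        env = self.make_stack(rng)
        X = env.table(["a", "b"])
        m_ab = train_maxent(X[:8], X, ["a", "b"], classes="lq")
        Xr = env.table(["b", "a"])
        m_ba = train_maxent(Xr[:8], Xr, ["b", "a"], classes="lq")
        assert np.allclose(predict_raw(m_ab, env), predict_raw(m_ba, env), atol=1e-5)


class TestTransforms:
    def test_zero_raw_maps_to_zero(self):
        assert raw_to_cloglog(np.array(0.0), 1.0) == 0.0
        assert raw_to_logistic(np.array(0.0), 1.0) == 0.0

    def test_uniform_raw_cloglog_closed_form(self):
        n = 128
        raw = np.full(n, 1.0 / n)
        out = raw_to_cloglog(raw, np.log(n))
        assert np.allclose(out, 1.0 - np.exp(-1.0))

    def test_cloglog_dominates_logistic(self, rng):
        raw = rng.uniform(0, 0.05, size=200)
        H = 3.0
        assert (raw_to_cloglog(raw, H) >= raw_to_logistic(raw, H) - 1e-12).all()

    def test_monotone_in_raw(self, rng):
        raw = np.sort(rng.uniform(0, 0.01, size=50))
        assert (np.diff(raw_to_cloglog(raw, 4.0)) >= 0).all()
        assert (np.diff(raw_to_logistic(raw, 4.0)) >= 0).all()

    def test_negative_raw_rejected(self):
        with pytest.raises(ValueError):
            raw_to_cloglog(np.array([-0.1]), 1.0)


class TestDiagnostics:
    def test_single_variable_importance_is_100(self, rng):
        X = rng.uniform(size=(200, 1))
        pres = X[X[:, 0] > 0.6]
        model = train_maxent(pres, X, ["only"], classes="l")
        imp = permutation_importance(model, pres, X, seed=0)
        assert imp == pytest.approx([100.0])

    def test_importance_sums_to_100_and_noise_is_small(self, rng):
        N = 1500
        driver = rng.standard_normal(N)
        noise = rng.standard_normal(N)
        X = np.column_stack([driver, noise])
        suit = 1 / (1 + np.exp(-2.0 * driver))
        pres = X[rng.uniform(size=N) < suit][:300]
        model = train_maxent(pres, X, ["driver", "noise"], classes="lq")
        imp = permutation_importance(model, pres, X, seed=1)
        assert imp.sum() == pytest.approx(100.0, abs=1e-6)
        assert imp[1] < 5.0

    def test_vif_orthogonal_near_one(self, rng):
        X = rng.standard_normal((10_000, 2))
        assert np.allclose(vif(X), 1.0, atol=0.05)

    def test_vif_duplicate_is_infinite(self, rng):
        x = rng.standard_normal(100)
        out = vif(np.column_stack([x, x, rng.standard_normal(100)]))
        assert np.isinf(out[0]) and np.isinf(out[1])

    def test_vif_matches_regression_oracle(self, rng):
        """Six correlated variables: VIF equals 1/(1-R^2) from an independent
        normal-equations solve."""
        base = rng.standard_normal((400, 3))
        mix = rng.uniform(-1, 1, size=(3, 6))
        X = base @ mix + 0.3 * rng.standard_normal((400, 6))
        got = vif(X)
        for j in range(6):
            others = np.column_stack([np.ones(400), np.delete(X, j, axis=1)])
            beta = np.linalg.solve(others.T @ others, others.T @ X[:, j])
            resid = X[:, j] - others @ beta
            r2 = 1 - resid @ resid / np.sum((X[:, j] - X[:, j].mean()) ** 2)
            assert got[j] == pytest.approx(1 / (1 - r2), abs=1e-8)

    def test_vif_input_validation(self, rng):
        with pytest.raises(ValueError):
            vif(rng.standard_normal((100, 1)))
        with pytest.raises(ValueError):
            vif(rng.standard_normal((4, 3)))


class TestSelectVariables:
    @staticmethod
    def make_sample(seed, r=0.99, n_pres=800, coef=2.0, N=2000):
        rng = np.random.default_rng(seed)
        driver = rng.standard_normal(N)
        shadow = r * driver + np.sqrt(1 - r**2) * rng.standard_normal(N)
        noise = rng.standard_normal(N)
        X = np.column_stack([driver, shadow, noise])
        suit = 1 / (1 + np.exp(-coef * driver))
        pres = X[rng.choice(N, size=n_pres, replace=True, p=suit / suit.sum())]
        return pres, X

    def test_orthogonal_informative_variables_all_retained(self, rng):
        N = 3000
        a, b = rng.standard_normal(N), rng.standard_normal(N)
        X = np.column_stack([a, b])
        suit = 1 / (1 + np.exp(-(1.5 * a + 1.5 * b)))
        pres = X[rng.choice(N, size=500, replace=True, p=suit / suit.sum())]
        kept = select_variables(pres, X, ["a", "b"], seed=0)
        assert set(kept) == {"a", "b"}

    def test_returned_set_always_below_vif_threshold(self):
        for seed in range(5):
            pres, X = self.make_sample(seed, r=0.95, n_pres=300)
            kept = select_variables(pres, X, ["driver", "shadow", "noise"], seed=seed)
            if len(kept) >= 2:
                cols = [["driver", "shadow", "noise"].index(v) for v in kept]
                assert vif(X[:, cols]).max() < 10

    def test_true_driver_recovered_from_correlated_shadow(self):
        """0.99-correlated pair where only one drives suitability: the driver
        is retained and the shadow dropped in >= 90% of 20 seeded worlds."""
        wins = 0
        for seed in range(20):
            pres, X = self.make_sample(seed)
            kept = select_variables(pres, X, ["driver", "shadow", "noise"], seed=seed)
            wins += ("driver" in kept) and ("shadow" not in kept)
        assert wins >= 18


def test_planted_world_cloglog_correlates_with_truth(world1, rng):
    """On the synthetic logistic world, the fitted cloglog surface ranks
    held-out cells like the true suitability (Spearman >= 0.8)."""
    from enmpipe.synth import sample_presences

    pres = sample_presences(world1, 400, seed=9)
    env = world1.env
    variables = ["bio1", "topo1"]
    Xp = env.values_at(pres[:, 0], pres[:, 1], variables)
    model = train_maxent(Xp, env.table(variables), variables, classes="lq")
    raw = predict_raw(model, env.subset(variables))
    surface = raw_to_cloglog(np.nan_to_num(raw, nan=0.0), model.H)
    holdout = rng.choice(surface.size, size=2000, replace=False)
    rho = spearmanr(surface.ravel()[holdout], world1.suitability.ravel()[holdout]).statistic
    assert rho >= 0.8
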