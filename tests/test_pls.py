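"""NIPALS PLS1, component selection, CV, VIP, permutation test, reduction."""

import numpy as np
import pandas as pd
import pytest

from hypoxmet.datamodel import ValidationError
from hypoxmet.pls import (
    compute_vip,
    cross_validate,
    fit_pls1,
    permutation_test,
    reduce_and_refit,
    select_components_loo,
    vip_stability,
)


def _ols_fitted(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ beta


class TestFitPLS1:
    def test_single_feature_exact_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 1))
        y = 2 * X[:, 0]
        m = fit_pls1(X, y, 1)
        assert np.allclose(m.fitted, y, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        m = fit_pls1(X, y, 5)
        assert np.allclose(m.fitted, _ols_fitted(X, y), atol=1e-8)

    def test_near_orthogonal_y_gives_null_model(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        # project y (almost) orthogonal to centered, scaled X columns
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        y = y - y.mean()
        y -= Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        y += 1e-8 * Xc[:, 0]
        m = fit_pls1(X, y + 50.0, 1)
        assert abs(m.q[0]) < 1e-8
        ss_res = np.sum((y + 50.0 - m.fitted) ** 2)
        ss_tot = np.sum(y**2)
        assert 1 - ss_res / ss_tot == pytest.approx(0.0, abs=1e-8)

    def test_scores_orthogonal_and_weights_unit_norm(self):
        rng = np.random.default_rng(4)
        m = fit_pls1(rng.normal(size=(25, 10)), rng.normal(size=25), 5)
        G = m.T.T @ m.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))
        assert np.allclose(np.linalg.norm(m.W, axis=0), 1.0, atol=1e-12)

    def test_matches_sklearn_fitted_values(self):
        sk = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 8))
        y = 2 * X[:, 0] + rng.normal(scale=0.5, size=30)
        m = fit_pls1(X, y, 3)
        ref = sk.PLSRegression(n_components=3, scale=True).fit(X, y)
        assert np.allclose(m.fitted, ref.predict(X).ravel(), atol=1e-8)

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 3))
        X[:, 1] = 7.0
        m = fit_pls1(pd.DataFrame(X, columns=["a", "b", "c"]), rng.normal(size=12), 1)
        assert m.dropped_features == ["b"]
        assert m.feature_ids == ["a", "c"]


class TestComponentSelection:
    def test_latent_single_component_structure_selects_one(self):
        # X driven by one latent factor: the LOO minimum sits at A = 1 in the
        # clear majority of runs (min-rule CV occasionally overshoots)
        picks = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            t = rng.normal(size=30)
            X = np.outer(t, rng.uniform(0.5, 2, size=21)) + 0.1 * rng.normal(size=(30, 21))
            y = 3 * t + rng.normal(size=30)
            picks.append(select_components_loo(X, y, A_max=6))
        assert sum(a == 1 for a in picks) >= 13
        assert np.bincount(picks).argmax() == 1

    def test_pure_noise_tie_breaks_to_one(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        assert select_components_loo(X, y, A_max=5) == 1

    def test_a_max_one(self):
        rng = np.random.default_rng(8)
        assert select_components_loo(rng.normal(size=(10, 3)), rng.normal(size=10), A_max=1) == 1

    def test_invalid_a_max_rejected(self):
        with pytest.raises(ValidationError):
            select_components_loo(np.zeros((10, 2)), np.zeros(10), A_max=0)


class TestCrossValidate:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 1))
        y = 5 * X[:, 0] + 2
        q2, rmse = cross_validate(X, y, 1, n_folds=10, seed=0)
        assert q2 == pytest.approx(1.0, abs=1e-8)
        assert rmse == pytest.approx(0.0, abs=1e-6)

    def test_null_q2_nonpositive_majority(self):
        neg = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = rng.normal(size=(30, 10))
            y = rng.permutation(3 * X[:, 0])
            q2, _ = cross_validate(X, y, 2, n_folds=10, seed=seed)
            neg += q2 <= 0
        assert neg > 10

    def test_constant_y_rejected(self):
        with pytest.raises(ValidationError):
            cross_validate(np.random.default_rng(0).normal(size=(12, 3)), np.ones(12), 1)

    def test_no_leakage_under_permutation(self):
        # scaling is refit inside folds, so permuted y rarely shows q2 > 0.3
        high = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            X = rng.normal(size=(25, 40))
            y = rng.permutation(np.arange(25.0))
            q2, _ = cross_validate(X, y, 2, n_folds=5, seed=seed)
            high += q2 > 0.3
        assert high <= 1


class TestVIP:
    def test_single_feature_vip_is_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(15, 1))
        m = fit_pls1(X, 2 * X[:, 0] + 0.1 * rng.normal(size=15), 1)
        assert compute_vip(m).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_orthogonal_features_one_predictive(self):
        n = 40
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 2 * x1
        m = fit_pls1(np.column_stack([x1, x2]), y, 1)
        vip = compute_vip(m)
        assert vip.iloc[0] == pytest.approx(np.sqrt(2.0), abs=1e-10)
        assert vip.iloc[1] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_bruteforce_formula(self, seed):
        rng = np.random.default_rng(seed)
        m = fit_pls1(rng.normal(size=(15, 6)), rng.normal(size=15), 3)
        vip = compute_vip(m).to_numpy()
        p = 6
        ss = np.array([m.q[a] ** 2 * (m.T[:, a] @ m.T[:, a]) for a in range(m.n_components)])
        brute = np.sqrt(p * sum(ss[a] * (m.W[:, a] / np.linalg.norm(m.W[:, a])) ** 2 for a in range(m.n_components)) / ss.sum())
        assert np.allclose(vip, brute, atol=1e-8)
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)


class TestPermutationTest:
    def test_perfect_separation_gives_add_one_floor(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 1))
        y = 4 * X[:, 0]
        p = permutation_test(X, y, n_perm=200, seed=0, A=1)
        assert p == pytest.approx(1.0 / 201.0)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValidationError):
            permutation_test(np.zeros((10, 2)), np.arange(10.0), n_perm=0)


class TestReduceAndRefit:
    def test_threshold_zero_keeps_everything(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("abcdef"))
        y = 2 * X["a"].to_numpy() + 0.2 * rng.normal(size=25)
        rep = reduce_and_refit(X, y, vip_threshold=0.0, n_perm=19, seed=0, compute_stability=False)
        assert set(rep.selected_features) == set("abcdef")
        assert rep.r2 == pytest.approx(rep.full_r2, abs=1e-10)

    def test_identical_copies_tie_under_strict_rule(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=30)
        X = pd.DataFrame({f"c{j}": x for j in range(5)})
        y = 2 * x + 0.1 * rng.normal(size=30)
        m = fit_pls1(X, y, 1)
        vip = compute_vip(m)
        assert np.allclose(vip, 1.0, atol=1e-10)
        with pytest.raises(ValidationError, match="threshold"):
            reduce_and_refit(X, y, vip_threshold=1.0, n_perm=19, seed=0)

    def test_planted_features_recovered(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(30, 50)), columns=[f"f{j}" for j in range(50)])
        signal = ["f3", "f17", "f31"]
        y = X[signal].sum(axis=1).to_numpy() + 0.3 * rng.normal(size=30)
        rep = reduce_and_refit(X, y, n_perm=99, seed=0, compute_stability=False)
        assert set(signal) <= set(rep.selected_features)
        assert rep.q2 > 0.3
        assert rep.empirical_p < 0.05


class TestVIPStability:
    def test_noise_free_single_predictor_has_zero_width_band(self):
        rng = np.random.default_rng(15)
        X = np.column_stack([np.linspace(-1, 1, 20), rng.normal(size=20) * 0])  # second feature constant -> dropped
        X[:, 1] = np.linspace(5, 6, 20)  # give it variance but no signal beyond collinearity with x1
        y = 3 * X[:, 0]
        out = vip_stability(X, y, A=1, n_folds=5, seed=0)
        assert np.allclose(out["vip_lo"], out["vip_median"], atol=1e-8)
        assert np.allclose(out["vip_hi"], out["vip_median"], atol=1e-8)

    def test_loo_boundary(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(12, 4))
        y = X[:, 0] + 0.1 * rng.normal(size=12)
        out = vip_stability(X, y, A=1, n_folds=12, seed=0)
        assert out.shape == (4, 3)

    def test_resampling_parameterization(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(20, 5))
        y = X[:, 0] + 0.2 * rng.normal(size=20)
        out = vip_stability(X, y, A=1, seed=0, quantiles=(0.2, 0.8), n_resamples=30)
        assert (out["vip_lo"] <= out["vip_hi"] + 1e-12).all()
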