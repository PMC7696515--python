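"""Partial likelihood, weighted elastic-net solver, path and prediction."""

import numpy as np
import pandas as pd
import pytest

from tcox import WeightedCoxnet, partial_log_likelihood, select_lambda
from tcox.solver import partial_loglik_and_gradient

from conftest import make_survival


def hand_partial_loglik(beta, X, time, status):
    """Direct term-by-term expansion of the event sum with risk sets
    {j : t_j >= t_i} (Breslow convention for ties)."""
    eta = X @ np.atleast_1d(beta)
    total = 0.0
    for i in range(len(time)):
        if status[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            total += eta[i] - np.log(sum(np.exp(eta[j]) for j in risk))
    return total


class TestPartialLogLikelihood:
    def test_null_beta_counts_risk_sets(self):
        X = np.zeros((3, 1))
        ll = partial_log_likelihood(np.zeros(1), X, np.array([1.0, 2, 3]), np.array([1, 1, 1]))
        assert ll == pytest.approx(-np.log(6.0), abs=1e-12)

    def test_no_events_gives_zero(self):
        X = np.ones((4, 2))
        ll = partial_log_likelihood(np.ones(2), X, np.arange(1.0, 5.0), np.zeros(4, int))
        assert ll == 0.0

    def test_matches_scalar_expansion(self):
        X = np.array([[1.0], [0.0], [2.0]])
        t, s = np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])
        beta = np.array([0.5])
        ll = partial_log_likelihood(beta, X, t, s)
        assert ll == pytest.approx(hand_partial_loglik(beta, X, t, s), abs=1e-12)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_gradient_matches_finite_differences(self, ties):
        rng = np.random.default_rng(4)
        n, p = 30, 3
        X = rng.standard_normal((n, p))
        t = np.ceil(rng.exponential(4.0, n))  # heavy ties
        s = rng.integers(0, 2, n)
        s[0] = 1
        beta = rng.standard_normal(p) * 0.4
        _, g = partial_loglik_and_gradient(beta, X, t, s, ties=ties)
        eps = 1e-6
        for j in range(p):
            e = np.zeros(p)
            e[j] = eps
            fd = (
                partial_log_likelihood(beta + e, X, t, s, ties)
                - partial_log_likelihood(beta - e, X, t, s, ties)
            ) / (2 * eps)
            assert g[j] == pytest.approx(fd, abs=1e-6)

    def test_breslow_handles_ties_with_shared_risk_set(self):
        X = np.array([[1.0], [2.0], [0.5], [0.0]])
        t = np.array([2.0, 2.0, 3.0, 5.0])
        s = np.array([1, 1, 1, 0])
        beta = np.array([0.3])
        assert partial_log_likelihood(beta, X, t, s) == pytest.approx(
            hand_partial_loglik(beta, X, t, s), abs=1e-12
        )


class TestFit:
    def test_beta_zero_at_and_above_lambda_max(self, small_survival):
        m = WeightedCoxnet(small_survival, alpha=0.5)
        lmax = m.lambda_max()
        for lam in (lmax, 2 * lmax):
            assert np.all(m.fit(lambdas=[lam]).coef() == 0.0)
        # just below lambda_max something enters
        assert len(m.fit(lambdas=[0.95 * lmax]).support()) >= 1

    def test_l1_homogeneity_uniform_factor(self, small_survival):
        """Uniform factors c at level lambda = all-ones factors at level c*lambda (alpha=1)."""
        c, lam = 2.5, 0.05
        m1 = WeightedCoxnet(small_survival, alpha=1.0, penalty_factors=np.full(4, c))
        m2 = WeightedCoxnet(small_survival, alpha=1.0)
        b1 = m1.fit(lambdas=[lam]).coef()
        b2 = m2.fit(lambdas=[c * lam]).coef()
        np.testing.assert_allclose(b1, b2, atol=1e-6)

    def test_lambda_zero_matches_newton_mle(self):
        """Unpenalized fit agrees with lifelines' Newton-Raphson Cox MLE."""
        from lifelines import CoxPHFitter

        data = make_survival(n=40, p=3, beta=[1.0, -0.6, 0.2], seed=3)
        res = WeightedCoxnet(data, alpha=1.0).fit(lambdas=[0.0])
        df = pd.DataFrame(data.X, columns=data.gene_ids)
        df["time"], df["status"] = data.time, data.status
        cph = CoxPHFitter().fit(df, "time", "status")
        np.testing.assert_allclose(res.coef(), cph.params_.values, atol=1e-4)

    def test_partial_loglik_not_below_null_at_lambda_zero(self, small_survival):
        res = WeightedCoxnet(small_survival).fit(lambdas=[0.0])
        ll_hat = res.partial_log_likelihood()
        ll_null = partial_log_likelihood(
            np.zeros(4), small_survival.X, small_survival.time, small_survival.status
        )
        assert ll_hat >= ll_null

    @pytest.mark.parametrize("seed", range(10))
    def test_reduction_and_direct_routes_agree(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(25, 50))
        p = int(rng.integers(3, 10))
        data = make_survival(n=n, p=p, beta=rng.standard_normal(p) * 0.5, seed=seed + 100)
        w = rng.uniform(0.2, 4.0, p)
        alpha = float(rng.uniform(0.1, 1.0))
        m = WeightedCoxnet(data, alpha=alpha, penalty_factors=w)
        lam = 0.3 * m.lambda_max()
        b_red = m.fit(lambdas=[lam], solver="reduction").coef()
        b_dir = m.fit(lambdas=[lam], solver="direct").coef()
        np.testing.assert_allclose(b_red, b_dir, atol=1e-5)

    def test_all_ones_factors_reproduce_plain_en_path(self, small_survival):
        lams = WeightedCoxnet(small_survival, alpha=0.3).lambda_path(20)
        r_plain = WeightedCoxnet(small_survival, alpha=0.3).fit(lambdas=lams)
        r_ones = WeightedCoxnet(
            small_survival, alpha=0.3, penalty_factors=np.ones(4)
        ).fit(lambdas=lams)
        np.testing.assert_allclose(r_plain.beta, r_ones.beta, atol=1e-8)

    def test_plain_lasso_matches_sksurv_coxnet(self):
        """Independent cross-check of the unweighted special case against the
        glmnet-style coordinate-descent solver in scikit-survival."""
        sksurv = pytest.importorskip("sksurv.linear_model")
        data = make_survival(n=80, p=6, beta=[1, -0.8, 0, 0, 0, 0], seed=5)
        m = WeightedCoxnet(data, alpha=1.0, standardize=False)
        lam = 0.3 * m.lambda_max()
        mine = m.fit(lambdas=[lam]).coef()
        y = np.array(
            [(bool(s), t) for s, t in zip(data.status, data.time)],
            dtype=[("event", bool), ("time", float)],
        )
        cx = sksurv.CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=[lam], normalize=False, tol=1e-12, max_iter=10**6
        )
        cx.fit(data.X, y)
        np.testing.assert_allclose(mine, cx.coef_.ravel(), atol=1e-5)

    def test_linear_penalty_mode_matches_sksurv_elastic_net(self):
        """The glmnet-compatibility mode (linear factors, halved ridge term)
        agrees with scikit-survival at alpha < 1 too."""
        sksurv = pytest.importorskip("sksurv.linear_model")
        data = make_survival(n=70, p=5, beta=[0.9, -0.7, 0.4, 0, 0], seed=6)
        m = WeightedCoxnet(data, alpha=0.4, standardize=False, penalty_mode="linear")
        lam = 0.2 * m.lambda_max()
        mine = m.fit(lambdas=[lam], solver="direct").coef()
        y = np.array(
            [(bool(s), t) for s, t in zip(data.status, data.time)],
            dtype=[("event", bool), ("time", float)],
        )
        cx = sksurv.CoxnetSurvivalAnalysis(
            l1_ratio=0.4, alphas=[lam], normalize=False, tol=1e-12, max_iter=10**6
        )
        cx.fit(data.X, y)
        np.testing.assert_allclose(mine, cx.coef_.ravel(), atol=1e-5)

    def test_excluded_genes_never_enter_support(self, small_survival):
        excluded = np.array([False, True, False, True])
        m = WeightedCoxnet(small_survival, alpha=0.2, excluded=excluded)
        res = m.fit(n_lambdas=15)
        assert np.all(res.beta[:, excluded] == 0.0)

    def test_infinite_factor_on_active_gene_rejected(self, small_survival):
        w = np.array([1.0, np.inf, 1.0, 1.0])
        with pytest.raises(ValueError, match="finite"):
            WeightedCoxnet(small_survival, penalty_factors=w)

    def test_alpha_out_of_range_rejected(self, small_survival):
        with pytest.raises(ValueError, match="alpha"):
            WeightedCoxnet(small_survival, alpha=1.5)

    def test_from_dataframe_equivalent(self, small_survival):
        df = pd.DataFrame(small_survival.X, columns=small_survival.gene_ids)
        df["time"], df["status"] = small_survival.time, small_survival.status
        m = WeightedCoxnet.from_dataframe(df, alpha=0.5)
        m2 = WeightedCoxnet(small_survival, alpha=0.5)
        np.testing.assert_allclose(
            m.fit(lambdas=[0.1]).coef(), m2.fit(lambdas=[0.1]).coef(), atol=1e-10
        )

    def test_summary_mentions_support_and_alpha(self, small_survival):
        res = WeightedCoxnet(small_survival, alpha=0.5).fit(n_lambdas=10)
        text = res.summary()
        assert "alpha" in text and "support size" in text


class TestPredictRelativeRisk:
    def test_null_model_predicts_unit_risk(self, small_survival):
        m = WeightedCoxnet(small_survival)
        res = m.fit(lambdas=[2 * m.lambda_max()])
        np.testing.assert_array_equal(
            res.predict_relative_risk(small_survival.X), np.ones(60)
        )

    def test_exponential_form_doubles_risk(self, small_survival):
        res = WeightedCoxnet(small_survival, alpha=1.0).fit(lambdas=[0.0])
        beta = res.coef().copy()
        j = int(np.argmax(np.abs(beta)))
        X = np.zeros((2, 4))
        X[1, j] = np.log(2.0) / beta[j]
        risks = res.predict_relative_risk(X)
        assert risks[1] / risks[0] == pytest.approx(2.0, rel=1e-10)

    def test_matches_hand_computed_linear_predictor(self):
        data = make_survival(n=30, p=2, beta=[0.5, -0.5], seed=9)
        res = WeightedCoxnet(data, alpha=1.0).fit(lambdas=[0.02])
        X = np.array([[1.0, 2.0], [0.0, 0.0], [-1.0, 3.0], [2.0, -2.0], [0.5, 0.5]])
        beta = res.coef()
        expected = np.exp([sum(x * b for x, b in zip(row, beta)) for row in X])
        np.testing.assert_allclose(res.predict_relative_risk(X), expected, atol=1e-12)
        assert np.all(res.predict_relative_risk(X) > 0)

    def test_permutation_equivariance(self, small_survival):
        res = WeightedCoxnet(small_survival).fit(n_lambdas=5)
        X = small_survival.X
        perm = np.random.default_rng(1).permutation(len(X))
        np.testing.assert_array_equal(
            res.predict_relative_risk(X)[perm], res.predict_relative_risk(X[perm])
        )

    def test_off_path_lambda_rejected(self, small_survival):
        res = WeightedCoxnet(small_survival).fit(lambdas=[0.1, 0.2])
        with pytest.raises(ValueError, match="not on the fitted path"):
            res.predict_relative_risk(small_survival.X, at_lambda=0.15)


class TestSelectLambda:
    def test_singleton_path_returned(self, small_survival):
        res = WeightedCoxnet(small_survival).fit(lambdas=[0.07])
        lam, _ = select_lambda(res, folds=3, seed=0)
        assert lam == pytest.approx(0.07)

    def test_duplicate_lambda_choice_is_seed_invariant(self, small_survival):
        res = WeightedCoxnet(small_survival).fit(lambdas=[0.05, 0.05, 0.05])
        chosen = {select_lambda(res, folds=3, seed=s)[0] for s in range(4)}
        assert chosen == {0.05}

    def test_strong_signal_gene_recovered_across_seeds(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            data = make_survival(n=300, p=5, beta=[2.0, 0, 0, 0, 0], censor_frac=0.2, seed=seed)
            m = WeightedCoxnet(data, alpha=0.5)
            res = m.fit(n_lambdas=25, cv_folds=3, seed=seed)
            if 0 in set(res.support()):
                hits += 1
        assert hits >= 18

    def test_deterministic_given_seed(self, small_survival):
        res = WeightedCoxnet(small_survival).fit(n_lambdas=12)
        a = select_lambda(res, folds=4, seed=42)
        b = select_lambda(res, folds=4, seed=42)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])
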