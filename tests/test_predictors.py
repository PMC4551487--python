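"""Whole-genome regression methods: closed forms, equivalences, samplers."""

import numpy as np
import pytest

from ricegs.predictors import (GBLUP, RRBLUP, BayesianLasso, BayesianRidge,
                               LassoConfig, LassoGS, McmcConfig, predict_gebv,
                               vanraden_g)


def make_xy(n=120, p=300, n_qtl=15, h2=0.5, seed=0):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.9, p)
    X0 = ((rng.random((n, p)) < freqs).astype(int)
          + (rng.random((n, p)) < freqs).astype(int)).astype(float)
    pfreq = X0.mean(axis=0) / 2
    X = X0 - X0.mean(axis=0)
    beta = np.zeros(p)
    beta[rng.choice(p, n_qtl, replace=False)] = rng.normal(0, 1, n_qtl)
    g = X @ beta
    vg = np.var(g) or 1.0
    y = g + rng.normal(0, np.sqrt(vg * (1 - h2) / max(h2, 1e-9)), n)
    return X, y, beta, pfreq


class TestRRBLUP:
    def test_huge_lambda_shrinks_to_mean(self):
        X, y, _, _ = make_xy(seed=1)
        res = RRBLUP(y, X).fit(fixed_lambda=1e12)
        assert np.abs(res.beta).max() < 1e-6
        assert np.allclose(res.predict(X), y.mean(), atol=1e-4)

    def test_single_column_closed_form_ridge(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60)
        x = (x - x.mean())
        x /= np.linalg.norm(x)  # x'x = 1
        y = 2.0 * x.ravel() + rng.normal(0, 0.1, 60)
        lam = 0.7
        res = RRBLUP(y, x[:, None]).fit(fixed_lambda=lam)
        assert np.isclose(res.beta[0], x @ (y - y.mean()) / (1 + lam), atol=1e-10)

    def test_noiseless_prediction_on_held_out_lines(self):
        X, y, beta, _ = make_xy(n=160, p=80, n_qtl=80, h2=1.0, seed=3)
        tr, va = np.arange(120), np.arange(120, 160)
        res = RRBLUP(y[tr], X[tr]).fit()
        pred = predict_gebv(res, X_new=X[va])
        assert np.corrcoef(pred, y[va])[0, 1] > 0.99

    def test_constant_response_degenerates(self):
        X, _, _, _ = make_xy(seed=4)
        res = RRBLUP(np.ones(X.shape[0]), X).fit()
        assert res.degenerate and np.all(res.beta == 0)


class TestGBLUP:
    def test_identity_g_closed_form_shrinkage(self):
        rng = np.random.default_rng(5)
        y = rng.normal(10, 2, 40)
        s2g, s2e = 3.0, 1.0
        h2 = s2g / (s2g + s2e)
        res = GBLUP(y, np.eye(40)).fit(fixed_variances=(s2g, s2e))
        assert np.allclose(res.u, h2 * (y - y.mean()), atol=1e-8)

    def test_equivalence_with_rrblup_under_matched_scaling(self):
        X, y, _, pfreq = make_xy(n=200, p=800, h2=0.6, seed=6)
        rr = RRBLUP(y, X).fit()
        gb = GBLUP.from_markers(y, X, p_freq=pfreq).fit()
        assert np.abs((rr.mu + X @ rr.beta) - (gb.mu + gb.u)).max() < 1e-6

    def test_permutation_equivariance(self):
        X, y, _, pfreq = make_xy(n=60, p=100, seed=7)
        G = vanraden_g(X, pfreq)
        res = GBLUP(y, G).fit()
        perm = np.random.default_rng(8).permutation(60)
        res_p = GBLUP(y[perm], G[np.ix_(perm, perm)]).fit()
        assert np.allclose(res_p.u, res.u[perm], atol=1e-6)

    def test_non_psd_rejected_with_loading_hint(self):
        G = np.eye(12)
        G[0, 0] = -1.0
        with pytest.raises(ValueError, match="loading"):
            GBLUP(np.random.default_rng(9).normal(size=12), G)


class TestLasso:
    def test_lambda_above_max_zeroes_all_effects(self):
        X, y, _, _ = make_xy(n=80, p=50, seed=10)
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / y.size
        res = LassoGS(y, X).fit(lambda_=lam_max * 1.001)
        assert np.all(res.beta == 0)

    def test_orthonormal_soft_threshold_closed_form(self):
        rng = np.random.default_rng(11)
        n, p = 64, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q * np.sqrt(n)  # X'X = n I
        y = rng.normal(0, 1, n)
        lam = 0.15
        res = LassoGS(y, X).fit(lambda_=lam)
        rho = X.T @ (y - y.mean()) / n
        expected = np.sign(rho) * np.maximum(np.abs(rho) - lam, 0.0)
        assert np.allclose(res.beta, expected, atol=1e-8)

    def test_duplicated_column_keeps_at_most_one(self):
        X, y, _, _ = make_xy(n=100, p=40, n_qtl=10, h2=0.9, seed=12)
        Xd = np.column_stack([X, X[:, 0]])
        res = LassoGS(y, Xd, LassoConfig(seed=1, n_lambda=20)).fit()
        assert (res.beta[0] == 0) or (res.beta[-1] == 0)

    def test_objective_monotone_over_sweeps(self):
        X, y, _, _ = make_xy(n=90, p=120, seed=13)
        res = LassoGS(y, X).fit(lambda_=0.05)
        obj = res.extra["objective_path"]
        assert np.all(np.diff(obj) <= 1e-12)

    def test_matches_sklearn_solution(self):
        from sklearn.linear_model import Lasso

        X, y, _, _ = make_xy(n=100, p=60, seed=14)
        lam = 0.1
        mine = LassoGS(y, X, LassoConfig(tol=1e-10, max_sweeps=5000)).fit(lambda_=lam)
        sk = Lasso(alpha=lam, fit_intercept=True, tol=1e-10, max_iter=100000)
        sk.fit(X, y)
        assert np.allclose(mine.beta, sk.coef_, atol=1e-6)

    def test_inner_cv_selects_sensible_lambda(self):
        X, y, _, _ = make_xy(n=120, p=100, n_qtl=5, h2=0.8, seed=15)
        res = LassoGS(y, X, LassoConfig(seed=2, n_lambda=25)).fit()
        grid = res.extra["lambda_grid"]
        assert grid.min() <= res.extra["cv_lambda"] <= grid.max()
        assert np.count_nonzero(res.beta) > 0


FAST_MCMC = dict(n_iter=1500, burn_in=500, thin=2)


class TestBayesian:
    def test_brr_seed_determinism(self):
        X, y, _, _ = make_xy(n=80, p=60, seed=16)
        a = BayesianRidge(y, X, McmcConfig(seed=3, **FAST_MCMC)).fit()
        b = BayesianRidge(y, X, McmcConfig(seed=3, **FAST_MCMC)).fit()
        c = BayesianRidge(y, X, McmcConfig(seed=4, **FAST_MCMC)).fit()
        assert np.array_equal(a.beta, b.beta)
        assert not np.array_equal(a.beta, c.beta)

    def test_bl_seed_determinism(self):
        X, y, _, _ = make_xy(n=80, p=60, seed=17)
        a = BayesianLasso(y, X, McmcConfig(seed=5, **FAST_MCMC)).fit()
        b = BayesianLasso(y, X, McmcConfig(seed=5, **FAST_MCMC)).fit()
        assert np.array_equal(a.beta, b.beta)

    def test_brr_fixed_variances_matches_ridge_posterior(self):
        """With variances frozen, the BRR posterior mean is the ridge
        solution at lambda = s2e/s2b (conjugate-normal oracle); agreement
        within Monte-Carlo error."""
        X, y, _, _ = make_xy(n=90, p=40, h2=0.6, seed=18)
        s2e = float(np.var(y)) * 0.5
        s2b = s2e / 50.0  # lambda = 50
        res = BayesianRidge(y, X, McmcConfig(n_iter=6000, burn_in=1000, thin=2,
                                             seed=6)).fit(fixed_variances=(s2b, s2e))
        ridge = RRBLUP(y, X).fit(fixed_lambda=50.0)
        mcse = res.extra["beta_sd"] / np.sqrt(res.extra["n_kept"] / 5.0)
        assert np.all(np.abs(res.beta - ridge.beta) < 4 * mcse + 1e-4)

    def test_brr_null_data_calibration(self):
        """y independent of X: at least 95% of markers have |posterior mean|
        below 3 posterior SDs."""
        rng = np.random.default_rng(19)
        X, _, _, _ = make_xy(n=100, p=200, seed=19)
        y = rng.normal(0, 1, 100)
        res = BayesianRidge(y, X, McmcConfig(seed=7, **FAST_MCMC)).fit()
        frac = np.mean(np.abs(res.beta) < 3 * res.extra["beta_sd"])
        assert frac >= 0.95

    def test_bl_shrinks_nulls_harder_and_signals_less_than_brr(self):
        """Sparse trait (5 large + many null effects): BL shrinks null
        markers more and large markers less than BRR, on average over
        replicates."""
        wins_null, wins_sig = 0, 0
        reps = 6
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            n, p = 120, 400
            X = rng.normal(0, 1, (n, p))
            sig = rng.choice(p, 5, replace=False)
            beta = np.zeros(p)
            beta[sig] = rng.choice([-3.0, 3.0], 5)
            y = X @ beta + rng.normal(0, 1.5, n)
            cfg = dict(n_iter=1200, burn_in=400, thin=2)
            brr = BayesianRidge(y, X, McmcConfig(seed=rep, **cfg)).fit()
            bl = BayesianLasso(y, X, McmcConfig(seed=rep, **cfg)).fit()
            null = np.setdiff1d(np.arange(p), sig)
            wins_null += np.abs(bl.beta[null]).mean() < np.abs(brr.beta[null]).mean()
            wins_sig += np.abs(bl.beta[sig]).mean() > np.abs(brr.beta[sig]).mean()
        assert wins_null >= reps - 1
        assert wins_sig >= reps - 1

    def test_bl_huge_lambda_kills_all_effects(self):
        X, y, _, _ = make_xy(n=80, p=50, seed=20)
        res = BayesianLasso(y, X, McmcConfig(seed=8, **FAST_MCMC)).fit(
            fixed_lambda2=1e10)
        assert np.abs(res.beta).max() < 1e-3 * np.std(y)

    def test_sigma2e_posterior_mean_matches_conjugate_toy(self):
        """Markerless conjugate toy: y = mu + e with a scaled-inv-chi2 prior
        on s2e; the Gibbs posterior mean matches the analytic posterior mean
        within Monte-Carlo error."""
        rng = np.random.default_rng(21)
        n = 60
        y = rng.normal(5.0, 2.0, n)
        X = np.zeros((n, 1))
        cfg = McmcConfig(n_iter=20000, burn_in=2000, thin=2, seed=9,
                         prior_r2=0.5, df_e=5.0)
        res = BayesianRidge(y, X, cfg).fit()
        vy = np.var(y)
        S_e = vy * 0.5 * (5.0 + 2.0) / 5.0  # prior scale used by the sampler
        ss = ((y - y.mean()) ** 2).sum()
        nu_post = 5.0 + n - 1
        mean_post = (5.0 * S_e + ss) / (nu_post - 2)
        kept = res.extra["n_kept"]
        mcse = mean_post * np.sqrt(2.0 / (nu_post - 4)) / np.sqrt(kept / 5)
        assert abs(res.extra["sigma2_e"] - mean_post) < 4 * mcse


class TestPrediction:
    def test_training_design_reproduces_fitted_values(self):
        X, y, _, _ = make_xy(seed=22)
        res = RRBLUP(y, X).fit()
        assert np.allclose(res.predict(X), res.mu + X @ res.beta)

    def test_centering_invariance_through_incidence_matrix(self, small_population):
        """Shifting a raw dosage column identically in training and
        prediction leaves GEBVs unchanged (the stored centering absorbs it)."""
        from ricegs.markers import build_incidence_matrix

        pop = small_population
        inc = build_incidence_matrix(pop, 0.05, 0.9)
        rng = np.random.default_rng(23)
        y = rng.normal(0, 1, pop.n_lines)
        res = RRBLUP(y, inc.X, incidence=inc).fit()
        base = res.predict_dosage(pop.dosage)
        # shift: emulate a recoded marker by editing dosage and centering
        inc_shift = type(inc)(loci=inc.loci, X=inc.X, center=inc.center + 1.0,
                              scale=inc.scale, provenance=inc.provenance)
        res2 = RRBLUP(y, inc_shift.X, incidence=inc_shift).fit()
        shifted = res2.predict_dosage(pop.dosage + 1)
        assert np.allclose(shifted, base, atol=1e-8)

    def test_locus_mismatch_rejected(self):
        X, y, _, _ = make_xy(seed=24)
        res = RRBLUP(y, X).fit()
        with pytest.raises(ValueError, match="columns"):
            res.predict(X[:, :-1])

    def test_accuracy_nondecreasing_in_h2(self):
        """Holding the architecture fixed, prediction accuracy rises with
        simulated heritability (Spearman rho > 0 across the h2 grid)."""
        from scipy.stats import spearmanr

        h2_grid = [0.1, 0.3, 0.6, 0.9]
        acc = {h: [] for h in h2_grid}
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            X, _, beta, _ = make_xy(n=160, p=120, n_qtl=30, h2=0.5,
                                    seed=300 + rep)
            g = X @ beta
            vg = np.var(g)
            for h in h2_grid:
                y = g + rng.normal(0, np.sqrt(vg * (1 - h) / h), 160)
                tr, va = np.arange(120), np.arange(120, 160)
                res = RRBLUP(y[tr], X[tr]).fit()
                acc[h].append(np.corrcoef(res.predict(X[va]), g[va])[0, 1])
        means = [np.mean(acc[h]) for h in h2_grid]
        rho, _ = spearmanr(h2_grid, means)
        assert rho > 0
        assert all(-1 <= a <= 1 for v in acc.values() for a in v)
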