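"""Compiled inner loops: lasso coordinate descent and the Gibbs samplers.

These are the only hot sequential loops in the package (single-site updates
cannot be vectorized); everything else is plain numpy.  All kernels are
deterministic under their seed argument (numba's legacy np.random state is
seeded inside the jitted function).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lasso_cd(X, y, lam, beta, max_sweeps, tol):
    """Cyclic coordinate descent for (1/2n)||y - X b||^2 + lam * ||b||_1.

    ``y`` must already be intercept-free (centered); ``beta`` is the warm
    start and is updated in place.  Returns (objective per sweep, sweeps run).
    """
    n, p = X.shape
    xx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xx[j] = s / n
    r = y - X @ beta
    obj = np.empty(max_sweeps)
    sweeps = 0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if xx[j] == 0.0:
                continue
            bj = beta[j]
            # partial residual correlation
            rho = 0.0
            for i in range(n):
                rho += X[i, j] * r[i]
            rho = rho / n + xx[j] * bj
            # soft threshold
            if rho > lam:
                bnew = (rho - lam) / xx[j]
            elif rho < -lam:
                bnew = (rho + lam) / xx[j]
            else:
                bnew = 0.0
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                beta[j] = bnew
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        s = 0.0
        for i in range(n):
            s += r[i] * r[i]
        l1 = 0.0
        for j in range(p):
            l1 += abs(beta[j])
        obj[sweep] = s / (2.0 * n) + lam * l1
        sweeps = sweep + 1
        if max_delta < tol:
            break
    return obj[:sweeps], sweeps


@njit(cache=True)
def _rinvgauss(mu, lam):
    """One inverse-Gaussian draw (Michael-Schucany-Haas)."""
    v = np.random.normal()
    w = v * v
    x = mu + mu * mu * w / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def brr_gibbs(X, y, n_iter, burn_in, thin, seed, df_e, S_e, df_b, S_b):
    """Bayesian ridge regression Gibbs sampler.

    Gaussian prior with a single marker variance s2_beta; scaled-inverse-chi2
    hyper-priors on s2_beta and s2_e.  Returns posterior means (mu, beta),
    element-wise posterior second moments of beta (for posterior SDs) and
    posterior means of (s2_beta, s2_e).
    """
    np.random.seed(seed)
    n, p = X.shape
    xx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xx[j] = s
    vy = np.var(y)
    if vy <= 0.0:
        vy = 1.0
    mu = np.mean(y)
    beta = np.zeros(p)
    s2e = vy * 0.5
    s2b = vy * 0.5 / max(np.sum(xx) / n, 1.0)
    r = y - mu  # residual
    beta_sum = np.zeros(p)
    beta_sq = np.zeros(p)
    mu_sum = 0.0
    s2e_sum = 0.0
    s2b_sum = 0.0
    kept = 0
    for it in range(n_iter):
        # marker effects, single site
        for j in range(p):
            if xx[j] == 0.0:
                continue
            bj = beta[j]
            rho = 0.0
            for i in range(n):
                rho += X[i, j] * r[i]
            rho += xx[j] * bj
            cj = xx[j] + s2e / s2b
            bnew = np.random.normal(rho / cj, np.sqrt(s2e / cj))
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                beta[j] = bnew
        # intercept
        mean_r = 0.0
        for i in range(n):
            mean_r += r[i]
        mean_r /= n
        mu_new = np.random.normal(mu + mean_r, np.sqrt(s2e / n))
        d = mu_new - mu
        for i in range(n):
            r[i] -= d
        mu = mu_new
        # variances
        ssb = 0.0
        for j in range(p):
            ssb += beta[j] * beta[j]
        s2b = (ssb + df_b * S_b) / np.random.chisquare(p + df_b)
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        s2e = (sse + df_e * S_e) / np.random.chisquare(n + df_e)
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            mu_sum += mu
            s2e_sum += s2e
            s2b_sum += s2b
            for j in range(p):
                beta_sum[j] += beta[j]
                beta_sq[j] += beta[j] * beta[j]
    return (mu_sum / kept, beta_sum / kept, beta_sq / kept,
            s2b_sum / kept, s2e_sum / kept, kept)


@njit(cache=True)
def bl_gibbs(X, y, n_iter, burn_in, thin, seed, df_e, S_e,
             lambda2_shape, lambda2_rate, fix_lambda2):
    """Bayesian LASSO Gibbs sampler (double-exponential prior as a
    scale-mixture of normals; Gamma hyper-prior on lambda^2).

    ``fix_lambda2`` > 0 freezes lambda^2 at that value (no hyper update).
    Returns posterior means (mu, beta), second moments of beta, and posterior
    means of (lambda2, s2_e).
    """
    np.random.seed(seed)
    n, p = X.shape
    xx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xx[j] = s
    vy = np.var(y)
    if vy <= 0.0:
        vy = 1.0
    mu = np.mean(y)
    beta = np.zeros(p)
    tau2 = np.ones(p)
    s2e = vy * 0.5
    lam2 = fix_lambda2 if fix_lambda2 > 0.0 else lambda2_shape / lambda2_rate
    r = y - mu
    beta_sum = np.zeros(p)
    beta_sq = np.zeros(p)
    mu_sum = 0.0
    s2e_sum = 0.0
    lam2_sum = 0.0
    kept = 0
    for it in range(n_iter):
        for j in range(p):
            if xx[j] == 0.0:
                continue
            bj = beta[j]
            rho = 0.0
            for i in range(n):
                rho += X[i, j] * r[i]
            rho += xx[j] * bj
            cj = xx[j] + 1.0 / tau2[j]
            bnew = np.random.normal(rho / cj, np.sqrt(s2e / cj))
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                beta[j] = bnew
        # scale mixture: 1/tau2_j ~ InvGauss(sqrt(lam2*s2e/beta_j^2), lam2)
        for j in range(p):
            b2 = beta[j] * beta[j]
            if b2 < 1e-20:
                b2 = 1e-20
            inv = _rinvgauss(np.sqrt(lam2 * s2e / b2), lam2)
            tau2[j] = 1.0 / inv
        if fix_lambda2 <= 0.0:
            st = 0.0
            for j in range(p):
                st += tau2[j]
            lam2 = np.random.gamma(p + lambda2_shape, 1.0 / (lambda2_rate + st / 2.0))
        # intercept
        mean_r = 0.0
        for i in range(n):
            mean_r += r[i]
        mean_r /= n
        mu_new = np.random.normal(mu + mean_r, np.sqrt(s2e / n))
        d = mu_new - mu
        for i in range(n):
            r[i] -= d
        mu = mu_new
        # residual variance (beta | s2e: scale enters the conditional)
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        ssb = 0.0
        for j in range(p):
            ssb += beta[j] * beta[j] / tau2[j]
        s2e = (sse + ssb + df_e * S_e) / np.random.chisquare(n + p + df_e)
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            mu_sum += mu
            s2e_sum += s2e
            lam2_sum += lam2
            for j in range(p):
                beta_sum[j] += beta[j]
                beta_sq[j] += beta[j] * beta[j]
    return (mu_sum / kept, beta_sum / kept, beta_sq / kept,
            lam2_sum / kept, s2e_sum / kept, kept)
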