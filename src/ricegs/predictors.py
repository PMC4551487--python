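"""Whole-genome regression methods for GEBV prediction.

Five methods under a common Model/Results interface:

* ``RRBLUP`` — ridge regression BLUP; the shrinkage parameter
  lambda = s2_e/s2_u is estimated by REML through a single spectral
  decomposition of XX' followed by a 1-D profile-likelihood optimization.
* ``GBLUP`` — individual-level mixed model on a genomic relationship matrix
  (VanRaden method 1 when built from markers); exactly equivalent to RR-BLUP
  under matched scaling.
* ``LASSO`` — l1-penalized regression solved by cyclic coordinate descent,
  with the penalty chosen by inner K-fold cross-validation on the training
  set only.
* ``BRR`` — Bayesian ridge regression (Gaussian prior, common marker
  variance) by Gibbs sampling.
* ``BL`` — Bayesian LASSO (double-exponential prior via a normal
  scale-mixture, Gamma hyper-prior on lambda^2) by Gibbs sampling.

All models are fitted to an intercept plus a centered marker design X and a
response vector y (typically line BLUPs); ``GenomicResults.predict`` returns
GEBVs for new design rows, re-applying the training centering when the model
carries an :class:`~ricegs.markers.IncidenceMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import _samplers

__all__ = [
    "McmcConfig",
    "LassoConfig",
    "PredictorConfig",
    "GenomicResults",
    "RRBLUP",
    "GBLUP",
    "LassoGS",
    "BayesianRidge",
    "BayesianLasso",
    "fit_rrblup",
    "fit_gblup",
    "fit_lasso",
    "fit_brr",
    "fit_bl",
    "predict_gebv",
    "vanraden_g",
    "METHODS",
]

_MIN_TRAIN = 10


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs-sampler settings; prior scales target ``prior_r2`` of the
    response variance explained by markers (hyper-parameter guideline)."""

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    prior_r2: float = 0.5
    df_e: float = 5.0
    df_b: float = 5.0
    lambda2_shape: float = 1.1

    def __post_init__(self) -> None:
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class LassoConfig:
    """Inner-CV lasso settings: 50 log-spaced penalties spanning 4 decades
    below lambda_max, 5 inner folds by default."""

    n_lambda: int = 50
    lambda_decades: float = 4.0
    cv_folds: int = 5
    seed: int = 0
    lambda_grid: tuple | None = None
    max_sweeps: int = 1000
    tol: float = 1e-7


@dataclass(frozen=True)
class PredictorConfig:
    """Bundle of per-method settings used by the cross-validation engine."""

    method: str = "RRBLUP"
    fixed_lambda: float | None = None  # RR-BLUP: skip REML when set
    lasso: LassoConfig = field(default_factory=LassoConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def __post_init__(self) -> None:
        if self.method not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.method!r}")
        if self.fixed_lambda is not None and self.fixed_lambda < 0:
            raise ValueError("lambda must be >= 0")


class GenomicResults:
    """A trained whole-genome regression.

    Marker-based methods store the effect vector ``beta``; GBLUP stores the
    training genetic values ``u`` and the projection vector ``alpha`` needed
    to predict new individuals through their G rows.  Prediction is
    reproducible from the stored fields alone.
    """

    def __init__(self, method, mu, beta=None, incidence=None, extra=None,
                 u=None, alpha=None, degenerate=False):
        self.method = method
        self.mu = float(mu)
        self.beta = beta
        self.incidence = incidence
        self.extra = extra or {}
        self.u = u
        self.alpha = alpha
        self.degenerate = degenerate

    # -- prediction --------------------------------------------------------

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """GEBV = mu + X_new @ beta for an already-centered design."""
        if self.beta is None:
            raise ValueError(f"{self.method} has no marker effects; use predict_g")
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.beta.size:
            raise ValueError(
                f"design has {X_new.shape[1]} columns, model expects {self.beta.size}"
            )
        return self.mu + X_new @ self.beta

    def predict_dosage(self, dosage: np.ndarray) -> np.ndarray:
        """GEBV from raw dosages, re-applying the training centering."""
        if self.incidence is None:
            raise ValueError("model was not fitted from an IncidenceMatrix")
        return self.predict(self.incidence.design_for(dosage))

    def predict_g(self, g_rows: np.ndarray) -> np.ndarray:
        """GBLUP prediction from rows of G linking new to training lines."""
        if self.alpha is None:
            raise ValueError(f"{self.method} does not predict through G rows")
        return self.mu + np.asarray(g_rows, dtype=float) @ self.alpha

    def fitted(self) -> np.ndarray:
        if self.u is not None:
            return self.mu + self.u
        return self.mu + self.extra["X_train"] @ self.beta if "X_train" in self.extra else None

    def summary(self) -> str:
        out = [f"{self.method}: intercept {self.mu:.4f}"]
        if self.beta is not None:
            nz = int(np.count_nonzero(self.beta))
            out.append(f"  markers: {self.beta.size} ({nz} nonzero effects)")
        for k in ("lambda", "sigma2_u", "sigma2_g", "sigma2_e", "sigma2_beta",
                  "lambda2", "cv_lambda", "n_kept"):
            if k in self.extra:
                v = self.extra[k]
                out.append(f"  {k} = {v:.6g}" if np.isscalar(v) else f"  {k} = {v}")
        if self.degenerate:
            out.append("  degenerate fit (constant response): beta = 0")
        return "\n".join(out)


# ---------------------------------------------------------------------------
# spectral REML shared by RR-BLUP and G-BLUP
# ---------------------------------------------------------------------------


def _spectral_reml(K: np.ndarray, y: np.ndarray,
                   bounds: tuple[float, float] = (-12.0, 12.0)):
    """REML for y = 1*mu + g, g ~ N(0, s2_u K), e ~ N(0, s2_e I).

    One eigendecomposition of K, then Brent optimization of the restricted
    profile likelihood over log(delta), delta = s2_e/s2_u.  Returns
    (delta, mu, s2_u, s2_e, U, d).
    """
    n = y.size
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yr = U.T @ y
    xr = U.T @ np.ones(n)

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (d + delta)
        xtwx = float(np.sum(w * xr * xr))
        mu = float(np.sum(w * xr * yr)) / xtwx
        r = yr - mu * xr
        quad = float(np.sum(w * r * r))
        s2u = quad / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2u) - np.sum(np.log(w))
                      + np.log(xtwx) + (n - 1))

    res = minimize_scalar(neg_reml, bounds=bounds, method="bounded",
                          options={"xatol": 1e-12})
    delta = float(np.exp(res.x))
    w = 1.0 / (d + delta)
    xtwx = float(np.sum(w * xr * xr))
    mu = float(np.sum(w * xr * yr)) / xtwx
    r = yr - mu * xr
    s2u = float(np.sum(w * r * r)) / (n - 1)
    return delta, mu, s2u, s2u * delta, U, d


class RRBLUP:
    """Ridge-regression BLUP: beta = (X'X + lambda I)^-1 X'(y - mu)."""

    method = "RRBLUP"

    def __init__(self, y: np.ndarray, X: np.ndarray, incidence=None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("rows of X must match y")
        if y.size < _MIN_TRAIN:
            raise ValueError(f"need at least {_MIN_TRAIN} training lines")
        self.y, self.X, self.incidence = y, X, incidence

    def fit(self, fixed_lambda: float | None = None) -> GenomicResults:
        y, X = self.y, self.X
        if np.ptp(y) == 0.0:
            return GenomicResults(self.method, mu=y[0],
                                  beta=np.zeros(X.shape[1]),
                                  incidence=self.incidence, degenerate=True,
                                  extra={"lambda": np.inf})
        if fixed_lambda is None:
            delta, mu, s2u, s2e, U, dvals = _spectral_reml(X @ X.T, y)
            w = 1.0 / (dvals + delta)
            beta = X.T @ (U @ (w * (U.T @ (y - mu))))
            extra = {"lambda": delta, "sigma2_u": s2u, "sigma2_e": s2e}
        else:
            mu = float(y.mean())
            p = X.shape[1]
            beta = np.linalg.solve(X.T @ X + fixed_lambda * np.eye(p),
                                   X.T @ (y - mu))
            extra = {"lambda": fixed_lambda}
        return GenomicResults(self.method, mu=mu, beta=beta,
                              incidence=self.incidence, extra=extra)


def vanraden_g(X: np.ndarray, p_freq: np.ndarray | None = None,
               loading: float = 1e-8) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix from a centered design:
    G = X X' / (2 sum p(1-p)), with a small diagonal loading for PSD."""
    X = np.asarray(X, dtype=float)
    if p_freq is None:
        # reconstruct p from the centering: columns of raw dosage have mean 2p
        denom = float(np.sum(X.var(axis=0))) / 2.0 * 2.0  # ~ 2 sum p(1-p) proxy
    else:
        denom = 2.0 * float(np.sum(p_freq * (1.0 - p_freq)))
    if denom <= 0:
        raise ValueError("zero denominator for G; all markers monomorphic?")
    G = X @ X.T / denom
    return G + loading * np.eye(G.shape[0])


class GBLUP:
    """Individual-level mixed model y = 1 mu + g + e, g ~ N(0, s2_g G)."""

    method = "GBLUP"

    def __init__(self, y: np.ndarray, G: np.ndarray, incidence=None,
                 psd_tol: float = 1e-6):
        y = np.asarray(y, dtype=float)
        G = np.asarray(G, dtype=float)
        if G.shape != (y.size, y.size):
            raise ValueError("G must be n x n matching y")
        if not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("G must be symmetric")
        w = np.linalg.eigvalsh(G)
        if w.min() < -psd_tol * max(w.max(), 1.0):
            raise ValueError(
                "G is not positive semi-definite; add diagonal loading "
                "(e.g. G + 1e-6 I)"
            )
        if y.size < _MIN_TRAIN:
            raise ValueError(f"need at least {_MIN_TRAIN} training lines")
        self.y, self.G, self.incidence = y, G, incidence

    @classmethod
    def from_markers(cls, y: np.ndarray, X: np.ndarray,
                     p_freq: np.ndarray | None = None, incidence=None) -> "GBLUP":
        return cls(y, vanraden_g(X, p_freq), incidence=incidence)

    def fit(self, fixed_variances: tuple[float, float] | None = None) -> GenomicResults:
        y, G = self.y, self.G
        if np.ptp(y) == 0.0:
            return GenomicResults(self.method, mu=y[0], u=np.zeros(y.size),
                                  alpha=np.zeros(y.size), degenerate=True)
        if fixed_variances is None:
            delta, mu, s2g, s2e, U, dvals = _spectral_reml(G, y)
        else:
            s2g, s2e = fixed_variances
            delta = s2e / s2g
            dvals, U = np.linalg.eigh(G)
            dvals = np.maximum(dvals, 0.0)
            w = 1.0 / (dvals + delta)
            xr, yr = U.T @ np.ones(y.size), U.T @ y
            mu = float(np.sum(w * xr * yr) / np.sum(w * xr * xr))
        w = 1.0 / (dvals + delta)
        alpha = U @ (w * (U.T @ (y - mu)))  # (G + delta I)^-1 (y - mu)
        u = G @ alpha
        return GenomicResults(self.method, mu=mu, u=u, alpha=alpha,
                              incidence=self.incidence,
                              extra={"sigma2_g": s2g, "sigma2_e": s2e,
                                     "delta": delta})


class LassoGS:
    """l1-penalized whole-genome regression with inner-CV penalty choice."""

    method = "LASSO"

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 config: LassoConfig | None = None, incidence=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        if self.X.shape[0] != self.y.size:
            raise ValueError("rows of X must match y")
        if self.y.size < _MIN_TRAIN:
            raise ValueError(f"need at least {_MIN_TRAIN} training lines")
        self.config = config or LassoConfig()
        self.incidence = incidence

    def _grid(self) -> np.ndarray:
        cfg = self.config
        if cfg.lambda_grid is not None:
            return np.asarray(sorted(cfg.lambda_grid, reverse=True), dtype=float)
        n = self.y.size
        lam_max = np.max(np.abs(self.X.T @ (self.y - self.y.mean()))) / n
        if lam_max <= 0:
            lam_max = 1.0
        return np.geomspace(lam_max, lam_max * 10.0 ** (-cfg.lambda_decades),
                            cfg.n_lambda)

    def _path(self, X, y, grid):
        """Warm-started solutions along a descending penalty grid."""
        cfg = self.config
        yc = y - y.mean()
        beta = np.zeros(X.shape[1])
        out = []
        for lam in grid:
            _samplers.lasso_cd(X, yc, lam, beta, cfg.max_sweeps, cfg.tol)
            out.append(beta.copy())
        return out

    def fit(self, lambda_: float | None = None) -> GenomicResults:
        cfg = self.config
        X, y = self.X, self.y
        if np.ptp(y) == 0.0:
            return GenomicResults(self.method, mu=y[0],
                                  beta=np.zeros(X.shape[1]),
                                  incidence=self.incidence, degenerate=True)
        if lambda_ is None:
            grid = self._grid()
            rng = np.random.default_rng(cfg.seed)
            folds = np.resize(np.arange(cfg.cv_folds), y.size)
            rng.shuffle(folds)
            mse = np.zeros(grid.size)
            for f in range(cfg.cv_folds):
                tr, va = folds != f, folds == f
                betas = self._path(np.ascontiguousarray(X[tr]), y[tr], grid)
                mu_f = y[tr].mean()
                for gi, b in enumerate(betas):
                    pred = mu_f + X[va] @ b
                    mse[gi] += float(np.mean((y[va] - pred) ** 2))
            lambda_ = float(grid[int(np.argmin(mse))])
            cv_info = {"cv_lambda": lambda_, "cv_mse": mse / cfg.cv_folds,
                       "lambda_grid": grid}
        else:
            cv_info = {"cv_lambda": lambda_}
        yc = y - y.mean()
        beta = np.zeros(X.shape[1])
        obj, _ = _samplers.lasso_cd(X, yc, lambda_, beta, cfg.max_sweeps, cfg.tol)
        cv_info["objective_path"] = obj
        return GenomicResults(self.method, mu=float(y.mean()), beta=beta,
                              incidence=self.incidence, extra=cv_info)


def _mcmc_hyper(y: np.ndarray, X: np.ndarray, cfg: McmcConfig):
    """BGLR-style prior scales from the target prior R^2."""
    vy = float(np.var(y)) or 1.0
    msx = float(np.sum(X.var(axis=0))) or 1.0
    S_e = vy * (1.0 - cfg.prior_r2) * (cfg.df_e + 2.0) / cfg.df_e
    S_b = vy * cfg.prior_r2 / msx * (cfg.df_b + 2.0) / cfg.df_b
    lam2_0 = 2.0 * msx * (1.0 - cfg.prior_r2) / cfg.prior_r2
    lam2_rate = (cfg.lambda2_shape - 1.0) / lam2_0 if cfg.lambda2_shape > 1 else 1.0 / lam2_0
    return vy, msx, S_e, S_b, lam2_0, lam2_rate


class BayesianRidge:
    """Gibbs-sampled ridge regression (marker-homogeneous shrinkage)."""

    method = "BRR"

    def __init__(self, y, X, config: McmcConfig | None = None, incidence=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.config = config or McmcConfig()
        self.incidence = incidence
        if self.y.size < _MIN_TRAIN:
            raise ValueError(f"need at least {_MIN_TRAIN} training lines")

    def fit(self, fixed_variances: tuple[float, float] | None = None) -> GenomicResults:
        cfg = self.config
        _, _, S_e, S_b, _, _ = _mcmc_hyper(self.y, self.X, cfg)
        if fixed_variances is not None:
            # freeze variances via near-degenerate hyper-priors (conjugate check)
            s2b, s2e = fixed_variances
            df_big = 1e8
            mu, bmean, bsq, s2b_m, s2e_m, kept = _samplers.brr_gibbs(
                self.X, self.y, cfg.n_iter, cfg.burn_in, cfg.thin,
                cfg.seed % (2**31), df_big, s2e, df_big, s2b)
        else:
            mu, bmean, bsq, s2b_m, s2e_m, kept = _samplers.brr_gibbs(
                self.X, self.y, cfg.n_iter, cfg.burn_in, cfg.thin,
                cfg.seed % (2**31), cfg.df_e, S_e, cfg.df_b, S_b)
        sd = np.sqrt(np.maximum(bsq - bmean**2, 0.0))
        return GenomicResults(self.method, mu=mu, beta=bmean,
                              incidence=self.incidence,
                              extra={"beta_sd": sd, "sigma2_beta": s2b_m,
                                     "sigma2_e": s2e_m, "n_kept": kept})


class BayesianLasso:
    """Gibbs-sampled Bayesian LASSO (marker-specific shrinkage)."""

    method = "BL"

    def __init__(self, y, X, config: McmcConfig | None = None, incidence=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.config = config or McmcConfig()
        self.incidence = incidence
        if self.y.size < _MIN_TRAIN:
            raise ValueError(f"need at least {_MIN_TRAIN} training lines")

    def fit(self, fixed_lambda2: float | None = None) -> GenomicResults:
        cfg = self.config
        _, _, S_e, _, _, lam2_rate = _mcmc_hyper(self.y, self.X, cfg)
        mu, bmean, bsq, lam2_m, s2e_m, kept = _samplers.bl_gibbs(
            self.X, self.y, cfg.n_iter, cfg.burn_in, cfg.thin,
            cfg.seed % (2**31), cfg.df_e, S_e,
            cfg.lambda2_shape, lam2_rate,
            -1.0 if fixed_lambda2 is None else float(fixed_lambda2))
        sd = np.sqrt(np.maximum(bsq - bmean**2, 0.0))
        return GenomicResults(self.method, mu=mu, beta=bmean,
                              incidence=self.incidence,
                              extra={"beta_sd": sd, "lambda2": lam2_m,
                                     "sigma2_e": s2e_m, "n_kept": kept})


# ---------------------------------------------------------------------------
# spec-surface wrappers and the CV-engine registry
# ---------------------------------------------------------------------------


def fit_rrblup(X, y, incidence=None, fixed_lambda=None) -> GenomicResults:
    return RRBLUP(y, X, incidence=incidence).fit(fixed_lambda=fixed_lambda)


def fit_gblup(X_or_G, y, from_markers=True, incidence=None) -> GenomicResults:
    if from_markers:
        return GBLUP.from_markers(y, X_or_G, incidence=incidence).fit()
    return GBLUP(y, X_or_G, incidence=incidence).fit()


def fit_lasso(X, y, config: LassoConfig | None = None, incidence=None) -> GenomicResults:
    return LassoGS(y, X, config=config, incidence=incidence).fit()


def fit_brr(X, y, config: McmcConfig | None = None, incidence=None) -> GenomicResults:
    return BayesianRidge(y, X, config=config, incidence=incidence).fit()


def fit_bl(X, y, config: McmcConfig | None = None, incidence=None) -> GenomicResults:
    return BayesianLasso(y, X, config=config, incidence=incidence).fit()


def predict_gebv(model: GenomicResults, X_new=None, dosage=None, g_rows=None) -> np.ndarray:
    """Common GEBV prediction entry point for all five methods."""
    if g_rows is not None:
        return model.predict_g(g_rows)
    if dosage is not None:
        return model.predict_dosage(dosage)
    if X_new is None:
        raise ValueError("pass X_new, dosage or g_rows")
    return model.predict(X_new)


METHOD_NAMES = ("RRBLUP", "GBLUP", "LASSO", "BRR", "BL")


def _cv_fit(method: str, y, X, seed: int, mcmc: McmcConfig | None = None,
            lasso: LassoConfig | None = None, incidence=None) -> GenomicResults:
    """Uniform (method, y, X, seed) -> results used by the CV engine."""
    if method == "RRBLUP":
        return RRBLUP(y, X, incidence=incidence).fit()
    if method == "GBLUP":
        return GBLUP.from_markers(y, X, incidence=incidence).fit()
    if method == "LASSO":
        cfg = lasso or LassoConfig()
        cfg = LassoConfig(**{**cfg.__dict__, "seed": seed})
        return LassoGS(y, X, config=cfg, incidence=incidence).fit()
    if method in ("BRR", "BL"):
        cfg = mcmc or McmcConfig()
        cfg = McmcConfig(**{**cfg.__dict__, "seed": seed})
        cls = BayesianRidge if method == "BRR" else BayesianLasso
        return cls(y, X, config=cfg, incidence=incidence).fit()
    raise ValueError(f"unknown method {method!r}")


METHODS = {m: m for m in METHOD_NAMES}
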