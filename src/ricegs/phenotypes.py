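"""Alpha-lattice mixed-model analysis: REML variance components and BLUPs.

The plot-level model is

    Y_ijk = mu + g_i + R_j + b_k(j) + e_ijk

with genotype g_i and block-within-replicate b_k(j) random, replicate R_j
fixed.  Variance components are estimated by EM-REML on Henderson's
mixed-model equations (unconditionally stable, non-negative by construction,
and fast at the ~700-plot scale of a lattice trial); genotype BLUPs are the
solutions of the MME at the converged variances.

Narrow-sense heritability is reported as h2 = s2_g / (s2_g + s2_e), i.e. the
genotypic variance among selfed families over genotypic-plus-residual
variance, assuming a strictly additive genetic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "Heritability",
    "LatticeModel",
    "LatticeResults",
    "fit_lattice_model",
    "narrow_sense_h2",
    "fit_all_traits",
]


@dataclass(frozen=True)
class VarianceComponents:
    """REML estimates for the lattice model (all >= 0 by construction)."""

    sigma2_g: float
    sigma2_b: float
    sigma2_e: float
    mu: float
    replicate_effects: dict
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class Heritability:
    """h2 = s2_g / (s2_g + s2_e); ``defined`` is False when both are zero."""

    h2: float
    defined: bool = True


def narrow_sense_h2(vc: VarianceComponents) -> Heritability:
    """Narrow-sense heritability from fitted variance components."""
    if vc.sigma2_g < 0 or vc.sigma2_e < 0:
        raise ValueError("variances must be non-negative")
    tot = vc.sigma2_g + vc.sigma2_e
    if tot == 0:
        return Heritability(h2=float("nan"), defined=False)
    return Heritability(h2=vc.sigma2_g / tot)


class LatticeModel:
    """Mixed model for one trait of a tidy plot-level trial table.

    Parameters
    ----------
    trial : DataFrame with columns line, trait, replicate, block, value
        (or already restricted to one trait if ``trait`` is None and a single
        trait is present).
    trait : trait name to analyse.
    include_blocks : drop the block term (e.g. for a randomized complete
        block analysis) when False.
    """

    def __init__(self, trial: pd.DataFrame, trait: str | None = None,
                 include_blocks: bool = True):
        if trait is None:
            traits = trial["trait"].unique()
            if len(traits) != 1:
                raise ValueError("trial holds several traits; pass trait=...")
            trait = traits[0]
        df = trial[trial["trait"] == trait].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no record for trait {trait!r}")
        if df["replicate"].nunique() < 2:
            raise ValueError("need at least two replicates")
        self.trait = trait
        self.data = df
        self.include_blocks = include_blocks

        self.lines = np.sort(df["line"].unique())
        self.reps = np.sort(df["replicate"].unique())
        y = df["value"].to_numpy(dtype=float)
        n = y.size

        # fixed: intercept + replicate dummies (first replicate as reference)
        X = np.ones((n, len(self.reps)))
        for j, r in enumerate(self.reps[1:], start=1):
            X[:, j] = (df["replicate"] == r).astype(float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular fixed-effect design")

        line_idx = pd.Categorical(df["line"], categories=self.lines).codes
        Zg = np.zeros((n, len(self.lines)))
        Zg[np.arange(n), line_idx] = 1.0
        if not np.all(Zg.sum(axis=0) > 0):
            raise ValueError("design not connected: line without plots")

        if include_blocks:
            rb = df["replicate"].astype(str) + ":" + df["block"].astype(str)
            self.blocks = np.sort(rb.unique())
            blk_idx = pd.Categorical(rb, categories=self.blocks).codes
            Zb = np.zeros((n, len(self.blocks)))
            Zb[np.arange(n), blk_idx] = 1.0
        else:
            self.blocks = np.array([])
            Zb = np.zeros((n, 0))

        self.y, self.X, self.Zg, self.Zb = y, X, Zg, Zb

    # -- REML machinery ----------------------------------------------------

    def reml_loglik(self, s2g: float, s2b: float, s2e: float) -> float:
        """Restricted log-likelihood at the given variances (direct V-based
        evaluation; used for diagnostics and the EM monotonicity check)."""
        y, X = self.y, self.X
        V = s2g * (self.Zg @ self.Zg.T) + s2e * np.eye(y.size)
        if self.Zb.shape[1]:
            V += s2b * (self.Zb @ self.Zb.T)
        L = np.linalg.cholesky(V)
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, Vi_X.T @ y)
        r = y - X @ beta
        quad = r @ np.linalg.solve(V, r)
        _, logdetXtViX = np.linalg.slogdet(XtViX)
        return -0.5 * (logdetV + logdetXtViX + quad)

    def fit(self, tol: float = 1e-8, max_iter: int = 500,
            track_loglik: bool = False) -> "LatticeResults":
        """EM-REML iterations on the MME until the relative change in every
        variance component falls below ``tol`` (or ``max_iter``)."""
        y, X, Zg, Zb = self.y, self.X, self.Zg, self.Zb
        n, p = X.shape[0], X.shape[1]
        qg, qb = Zg.shape[1], Zb.shape[1]
        W = np.hstack([X, Zg, Zb])
        WtW = W.T @ W
        Wty = W.T @ y
        yty = float(y @ y)

        vy = float(np.var(y)) or 1.0
        s2g, s2b, s2e = vy / 3, vy / 3, vy / 3
        if qb == 0:
            s2b = 0.0
        loglik_path: list[float] = []
        converged = False
        it = 0
        floor = 1e-10 * vy
        for it in range(1, max_iter + 1):
            C = WtW.copy()
            sl_g = slice(p, p + qg)
            sl_b = slice(p + qg, p + qg + qb)
            C[sl_g, sl_g] += np.eye(qg) * (s2e / max(s2g, floor))
            if qb:
                C[sl_b, sl_b] += np.eye(qb) * (s2e / max(s2b, floor))
            Cinv = np.linalg.inv(C)
            theta = Cinv @ Wty
            ug = theta[sl_g]
            ub = theta[sl_b]

            s2e_new = (yty - float(theta @ Wty)) / (n - p)
            s2g_new = (float(ug @ ug) + s2e_new * float(np.trace(Cinv[sl_g, sl_g]))) / qg
            if qb:
                s2b_new = (float(ub @ ub) + s2e_new * float(np.trace(Cinv[sl_b, sl_b]))) / qb
            else:
                s2b_new = 0.0

            if track_loglik:
                loglik_path.append(self.reml_loglik(s2g_new, s2b_new, s2e_new))

            rel = max(
                abs(s2g_new - s2g) / max(s2g, floor),
                abs(s2b_new - s2b) / max(s2b, floor) if qb else 0.0,
                abs(s2e_new - s2e) / max(s2e, floor),
            )
            s2g, s2b, s2e = s2g_new, s2b_new, s2e_new
            if rel < tol:
                converged = True
                break

        # final solve at the converged variances
        C = WtW.copy()
        C[p:p + qg, p:p + qg] += np.eye(qg) * (s2e / max(s2g, floor))
        if qb:
            C[p + qg:, p + qg:] += np.eye(qb) * (s2e / max(s2b, floor))
        Cinv = np.linalg.inv(C)
        theta = Cinv @ Wty
        beta, ug = theta[:p], theta[p:p + qg]
        pev = np.maximum(np.diag(Cinv)[p:p + qg] * s2e, 0.0)
        reliability = 1.0 - pev / s2g if s2g > 0 else np.zeros(qg)

        rep_eff = {int(r) if not isinstance(r, str) else r:
                   (0.0 if j == 0 else float(beta[j])) for j, r in enumerate(self.reps)}
        vc = VarianceComponents(
            sigma2_g=float(s2g), sigma2_b=float(s2b), sigma2_e=float(s2e),
            mu=float(beta[0]), replicate_effects=rep_eff,
            converged=converged, n_iter=it,
        )
        blups = pd.Series(ug, index=self.lines, name=self.trait)
        return LatticeResults(model=self, vc=vc, blups=blups,
                              reliability=pd.Series(reliability, index=self.lines),
                              loglik_path=loglik_path)


@dataclass
class LatticeResults:
    """Fitted lattice model: variance components, genotype BLUPs (deviations
    from the general mean), per-line reliabilities and diagnostics."""

    model: LatticeModel
    vc: VarianceComponents
    blups: pd.Series
    reliability: pd.Series
    loglik_path: list = field(default_factory=list)

    @property
    def heritability(self) -> Heritability:
        return narrow_sense_h2(self.vc)

    def summary(self) -> str:
        h2 = self.heritability
        lines = [
            f"Alpha-lattice REML — trait {self.model.trait}",
            f"  plots: {self.model.y.size}   lines: {len(self.model.lines)}   "
            f"blocks: {len(self.model.blocks)}",
            f"  sigma2_g = {self.vc.sigma2_g:.4f}",
            f"  sigma2_b = {self.vc.sigma2_b:.4f}",
            f"  sigma2_e = {self.vc.sigma2_e:.4f}",
            f"  h2 (s2g/(s2g+s2e)) = {h2.h2:.3f}" if h2.defined else "  h2 undefined",
            f"  mu = {self.vc.mu:.4f}   converged: {self.vc.converged} "
            f"({self.vc.n_iter} EM iterations)",
        ]
        return "\n".join(lines)


def fit_lattice_model(trial: pd.DataFrame, trait: str | None = None,
                      include_blocks: bool = True, **kwargs) -> LatticeResults:
    """Convenience wrapper: build and fit a :class:`LatticeModel`."""
    return LatticeModel(trial, trait=trait, include_blocks=include_blocks).fit(**kwargs)


def fit_all_traits(trial: pd.DataFrame, **kwargs) -> dict[str, LatticeResults]:
    """Fit every trait in the trial table; returns {trait: results}."""
    return {t: fit_lattice_model(trial, trait=t, **kwargs)
            for t in trial["trait"].unique()}
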