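"""Cross-validation factorial engine and GEBV-accuracy analysis.

A *scenario* is one cell of the evaluation factorial: trait x prediction
method x marker-selection thresholds (MAF, LD) x k-fold ratio x TP/VP
assignment strategy.  For every scenario the engine draws R replicate fold
partitions (R chosen so k*R >= 100 tests), fits the model on each training
fold, predicts the left-out fold and records the Pearson correlation r
between predicted GEBVs and the observed line BLUPs, plus its Fisher
z-transform z = 0.5 ln((1+r)/(1-r)).

The z values are then analysed with three fixed-effects ANOVA models
(scenario-as-a-whole; five main effects; main effects plus all first-order
interactions) and LSMeans with a compact letter display.

TP/VP assignment strategies:
  * ``random``      — near-equal random k folds;
  * ``stratified``  — random k folds stratified by subpopulation (each
                      subpopulation contributes (k-1)/k to the TP);
  * ``lso:<name>``  — leave-subpopulation-out: the named subpopulation is
                      the whole VP, the others the TP.
"""

from __future__ import annotations

import itertools
import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .markers import IncidenceMatrix, build_incidence_matrix, sample_random_sets
from .predictors import GBLUP, LassoConfig, McmcConfig, _cv_fit, vanraden_g

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "FoldAssignment",
    "enumerate_scenarios",
    "make_folds",
    "replicates_for",
    "run_cross_validation",
    "fisher_z",
    "fisher_z_inverse",
    "anova_accuracy",
    "AnovaResult",
    "lsmeans",
    "LsMeansTable",
]

FACTORS = ("trait", "method", "maf", "ld", "k")


@dataclass(frozen=True)
class Scenario:
    """One factorial cell.  ``maf``/``ld`` are thresholds (fractions); a
    random marker set instead carries ``random_size``/``random_rep``."""

    trait: str
    method: str
    maf: float | None = None
    ld: float | None = None
    k: int = 3
    strategy: str = "random"
    random_size: int | None = None
    random_rep: int | None = None

    @property
    def matrix_key(self):
        if self.random_size is not None:
            return ("random", self.random_size, self.random_rep)
        return ("threshold", self.maf, self.ld)

    @property
    def key(self) -> str:
        return "|".join(str(x) for x in (
            self.trait, self.method, self.maf, self.ld, self.k, self.strategy,
            self.random_size, self.random_rep))


def enumerate_scenarios(
    traits, methods, mafs=(None,), lds=(None,), ks=(3,), strategies=("random",),
    random_sizes=None, random_reps=1,
) -> list[Scenario]:
    """Cartesian product in canonical order (trait, method, maf, ld, k,
    strategy[, random set]); threshold grids and random-size grids are
    mutually exclusive."""
    out = []
    if random_sizes is not None:
        for t, m, s, size, rep in itertools.product(
                traits, methods, strategies, random_sizes, range(random_reps)):
            out.append(Scenario(t, m, k=ks[0] if len(ks) == 1 else 3,
                                strategy=s, random_size=size, random_rep=rep))
        return out
    for t, m, a, l, k, s in itertools.product(traits, methods, mafs, lds, ks, strategies):
        out.append(Scenario(t, m, maf=a, ld=l, k=k, strategy=s))
    return out


@dataclass(frozen=True)
class FoldAssignment:
    """Validation folds: list of line-index arrays; the TP of a fold is the
    complement of its VP.  Folds are disjoint; for k-fold strategies they
    are exhaustive and their sizes differ by at most one."""

    folds: tuple
    strategy: str
    seed: int
    replicate: int
    n_lines: int

    def __post_init__(self) -> None:
        allv = np.concatenate(self.folds)
        if np.unique(allv).size != allv.size:
            raise AssertionError("folds overlap")
        if not self.strategy.startswith("lso") and allv.size != self.n_lines:
            raise AssertionError("folds do not cover all lines")

    def splits(self):
        """Yield (train_idx, validation_idx) per fold."""
        universe = np.arange(self.n_lines)
        for vp in self.folds:
            yield np.setdiff1d(universe, vp), np.asarray(vp)


def _partition(n_items: int, k: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n_items)
    base = n_items // k
    rem = n_items - base * k
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    out, start = [], 0
    for s in sizes:
        out.append(order[start:start + s])
        start += s
    return out


def make_folds(line_ids, k: int, strategy: str = "random",
               subpop_labels=None, seed: int = 0, replicate: int = 0) -> FoldAssignment:
    """Partition lines into validation folds under the given strategy."""
    n = len(line_ids)
    if strategy.startswith("lso:"):
        if subpop_labels is None:
            raise ValueError("leave-subpop-out needs subpopulation labels")
        name = strategy.split(":", 1)[1]
        vp = np.flatnonzero(np.asarray(subpop_labels) == name)
        if vp.size == 0:
            raise ValueError(f"unknown subpopulation {name!r}")
        return FoldAssignment((vp,), strategy, seed, replicate, n)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} lines")
    rng = np.random.default_rng(seed)
    if strategy == "random":
        folds = _partition(n, k, rng)
    elif strategy == "stratified":
        if subpop_labels is None:
            raise ValueError("stratified assignment needs subpopulation labels")
        labels = np.asarray(subpop_labels)
        parts = [[] for _ in range(k)]
        for sp in pd.unique(labels):
            idx = np.flatnonzero(labels == sp)
            sub = _partition(idx.size, k, rng)
            # rotate which fold gets the larger share across subpops
            for f in range(k):
                parts[f].append(idx[sub[f]])
        folds = [np.concatenate(p) for p in parts]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return FoldAssignment(tuple(folds), strategy, seed, replicate, n)


def replicates_for(k: int, min_tests: int = 100) -> int:
    """Replicate partitions so that k * R >= min_tests (34/17/12 for k=3/6/9)."""
    return int(np.ceil(min_tests / k))


def fisher_z(r):
    """z = 0.5 ln((1+r)/(1-r)); |r| >= 1 is clipped with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlation at the boundary; clipping for Fisher z")
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return 0.5 * np.log((1.0 + r) / (1.0 - r))


def fisher_z_inverse(z):
    """Back-transform a Fisher z to a correlation (tanh)."""
    return np.tanh(np.asarray(z, dtype=float))


def _derive_seed(master: int, *parts) -> int:
    """Stable per-scenario seed below 2**31."""
    text = "|".join(str(p) for p in (master,) + parts)
    return zlib.crc32(text.encode()) % (2**31 - 1)


def _matrix_cache(population, scenarios, seed, standardize=False):
    cache: dict[tuple, IncidenceMatrix] = {}
    for sc in scenarios:
        kk = sc.matrix_key
        if kk in cache:
            continue
        if kk[0] == "threshold":
            cache[kk] = build_incidence_matrix(population, sc.maf, sc.ld,
                                               standardize=standardize)
        else:
            cache[kk] = sample_random_sets(
                population, [kk[1]], replicates=kk[2] + 1, seed=seed,
                standardize=standardize)[-1]
    return cache


def run_cross_validation(
    scenarios, population, blups: dict[str, pd.Series], seed: int = 0,
    min_tests: int = 100, mcmc: McmcConfig | None = None,
    lasso: LassoConfig | None = None, r_override: int | None = None,
    bayesian_independent_partitions: bool = False,
    record_tbv: bool = True,
) -> pd.DataFrame:
    """Run the factorial and return one tidy row per (scenario, replicate,
    fold) with the accuracy r and Fisher z.

    Marker selection is computed once per incidence-matrix spec on the full
    panel (the study's design).  Fold partitions are shared across the
    frequentist methods of the same scenario cell; Bayesian methods can draw
    independent partitions (off by default).  Simulated populations with
    stored true breeding values additionally get a diagnostic correlation
    with the TBV.
    """
    scenarios = list(scenarios)
    line_index = pd.Index(population.line_ids)
    cache = _matrix_cache(population, scenarios, seed)
    g_cache: dict[tuple, np.ndarray] = {}
    rows = []
    for sc in scenarios:
        y_all = blups[sc.trait].reindex(line_index)
        if y_all.isna().any():
            raise ValueError(f"missing BLUPs for trait {sc.trait}")
        y_all = y_all.to_numpy(dtype=float)
        tbv = population.true_breeding_values.get(sc.trait) if record_tbv else None
        inc = cache[sc.matrix_key]
        X = inc.X
        R = 1 if sc.strategy.startswith("lso") else (
            r_override if r_override is not None else replicates_for(sc.k, min_tests))
        for rep in range(R):
            part_parts = [sc.trait, sc.matrix_key, sc.k, sc.strategy, rep]
            if bayesian_independent_partitions and sc.method in ("BRR", "BL"):
                part_parts.append(sc.method)
            fold_seed = _derive_seed(seed, "folds", *part_parts)
            fa = make_folds(population.line_ids, sc.k, sc.strategy,
                            population.subpop_labels, seed=fold_seed, replicate=rep)
            for f, (tr, va) in enumerate(fa.splits()):
                fit_seed = _derive_seed(seed, "fit", sc.key, rep, f)
                try:
                    if sc.method == "GBLUP":
                        # one full-panel G per marker set keeps training and
                        # prediction rows on the same scale
                        if sc.matrix_key not in g_cache:
                            g_cache[sc.matrix_key] = vanraden_g(X)
                        G = g_cache[sc.matrix_key]
                        model = GBLUP(y_all[tr], G[np.ix_(tr, tr)]).fit()
                        gebv = model.predict_g(G[np.ix_(va, tr)])
                    else:
                        model = _cv_fit(sc.method, y_all[tr], X[tr], fit_seed,
                                        mcmc=mcmc, lasso=lasso)
                        gebv = model.predict(X[va])
                except Exception as exc:  # noqa: BLE001 - engine must continue
                    logger.warning("fit failed for %s rep %d fold %d: %s",
                                   sc.key, rep, f, exc)
                    rows.append(_row(sc, rep, f, np.nan, np.nan, np.nan))
                    continue
                r = _safe_corr(gebv, y_all[va])
                r_tbv = _safe_corr(gebv, tbv[va]) if tbv is not None else np.nan
                rows.append(_row(sc, rep, f, r, float(fisher_z(r)), r_tbv))
    return pd.DataFrame(rows)


def _safe_corr(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _row(sc: Scenario, rep, fold, r, z, r_tbv):
    return {
        "trait": sc.trait, "method": sc.method,
        "maf": sc.maf, "ld": sc.ld, "k": sc.k, "strategy": sc.strategy,
        "random_size": sc.random_size, "random_rep": sc.random_rep,
        "scenario": sc.key, "replicate": rep, "fold": fold,
        "r": r, "z": z, "r_tbv": r_tbv,
    }


# ---------------------------------------------------------------------------
# ANOVA of accuracy and LSMeans
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Fixed-effects ANOVA of Fisher-z accuracy.

    ``table`` holds per-term DF/SS/MS/F/p (Type III, sum-to-zero coding);
    fit statistics follow the conventions of variance-analysis reporting:
    R², CV% = 100 * rootMSE / mean(z), root MSE.
    """

    model_id: int
    table: pd.DataFrame
    r2: float
    cv_pct: float
    root_mse: float
    mse: float
    df_model: int
    df_resid: int
    ols_result: object = field(repr=False, default=None)
    factors: tuple = ()

    def summary(self) -> str:
        head = (f"ANOVA model {self.model_id}: R2 = {self.r2:.3f}, "
                f"CV% = {self.cv_pct:.2f}, root MSE = {self.root_mse:.4f}, "
                f"model DF = {self.df_model}")
        return head + "\n" + self.table.to_string(index=False)


def _active_factors(records: pd.DataFrame, factors) -> list[str]:
    return [f for f in factors if records[f].nunique() > 1]


def anova_accuracy(records: pd.DataFrame, model_id: int,
                   factors=FACTORS) -> AnovaResult:
    """Fit ANOVA model 1 (scenario as a single factor), 2 (main effects
    only) or 3 (main effects + all first-order interactions) to the Fisher-z
    accuracies.  Effects are fixed, coding is sum-to-zero, tests are Type
    III F against the model's own MSE."""
    if model_id not in (1, 2, 3):
        raise ValueError("model_id must be 1, 2 or 3")
    df = records.dropna(subset=["z"]).copy()
    if df["scenario"].nunique() < 2:
        raise ValueError("need records from at least two scenarios")
    active = _active_factors(df, factors)
    for f in active:
        df[f] = df[f].astype(str)

    if model_id == 1:
        formula = "z ~ C(scenario, Sum)"
    else:
        mains = [f"C({f}, Sum)" for f in active]
        formula = "z ~ " + " + ".join(mains)
        if model_id == 3:
            inter = [f"C({a}, Sum):C({b}, Sum)"
                     for a, b in itertools.combinations(active, 2)]
            formula += " + " + " + ".join(inter)

    ols = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(ols.model.exog) < ols.model.exog.shape[1]:
        aliased = [t for t in ols.params.index[ols.params.isna()]] or ["(unknown)"]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = sm.stats.anova_lm(ols, typ=3)

    aov = aov.drop(index=[i for i in ("Intercept",) if i in aov.index])
    tbl = pd.DataFrame({
        "source": [i.replace("C(", "").replace(", Sum)", "") for i in aov.index],
        "df": aov["df"].astype(int),
        "ss": aov["sum_sq"],
        "ms": aov["sum_sq"] / aov["df"],
        "F": aov["F"],
        "p": aov["PR(>F)"],
    }).reset_index(drop=True)
    tbl.loc[tbl["source"] == "Residual", ["F", "p"]] = np.nan

    mse = float(ols.mse_resid)
    zbar = float(df["z"].mean())
    return AnovaResult(
        model_id=model_id,
        table=tbl,
        r2=float(ols.rsquared),
        cv_pct=100.0 * np.sqrt(mse) / abs(zbar) if zbar != 0 else np.inf,
        root_mse=float(np.sqrt(mse)),
        mse=mse,
        df_model=int(ols.df_model),
        df_resid=int(ols.df_resid),
        ols_result=ols,
        factors=tuple(active if model_id != 1 else ["scenario"]),
    )


@dataclass
class LsMeansTable:
    """Adjusted (balanced-weight) means of z per factor level, back-
    transformed to r, with a compact letter display at alpha = 0.05
    (levels sharing a letter are not significantly different)."""

    factor: str
    table: pd.DataFrame  # level, lsmean_z, se, lsmean_r, letters

    def summary(self) -> str:
        return f"LSMeans for {self.factor}\n" + self.table.to_string(index=False)


def lsmeans(anova: AnovaResult, factor: str, alpha: float = 0.05) -> LsMeansTable:
    """LSMeans of a factor from a fitted accuracy ANOVA (models 2/3).

    Adjusted means average model predictions over a balanced grid of the
    other factors; pairwise comparisons are unadjusted t tests on the model
    MSE (the classical LSMeans default)."""
    if factor not in anova.factors:
        raise ValueError(f"factor {factor!r} not in the fitted model {anova.factors}")
    ols = anova.ols_result
    data = ols.model.data.frame
    levels = {f: sorted(data[f].unique()) for f in anova.factors}
    if not levels[factor]:
        raise ValueError("factor has no levels")

    grid = pd.DataFrame(
        list(itertools.product(*[levels[f] for f in anova.factors])),
        columns=list(anova.factors),
    )
    design = patsy.build_design_matrices(
        [ols.model.data.design_info], grid, return_type="dataframe")[0].to_numpy()

    L_rows, names = [], []
    for lev in levels[factor]:
        mask = (grid[factor] == lev).to_numpy()
        L_rows.append(design[mask].mean(axis=0))
        names.append(lev)
    L = np.vstack(L_rows)
    means = L @ ols.params.to_numpy()
    cov = ols.cov_params().to_numpy()
    ses = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))

    # pairwise unadjusted t tests -> significance matrix
    from scipy import stats as sps

    m = len(names)
    sig = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            c = L[i] - L[j]
            se = np.sqrt(c @ cov @ c)
            tval = (means[i] - means[j]) / se if se > 0 else np.inf
            p = 2 * sps.t.sf(abs(tval), anova.df_resid)
            sig[i, j] = sig[j, i] = p < alpha
    letters = _compact_letters(means, sig)

    tbl = pd.DataFrame({
        "level": names,
        "lsmean_z": means,
        "se": ses,
        "lsmean_r": fisher_z_inverse(means),
        "letters": letters,
    }).sort_values("lsmean_z", ascending=False).reset_index(drop=True)
    return LsMeansTable(factor=factor, table=tbl)


def _compact_letters(means: np.ndarray, sig: np.ndarray) -> list[str]:
    """Compact letter display: maximal runs of mutually non-significant
    levels (in decreasing-mean order) share one letter."""
    order = np.argsort(-means)
    m = len(order)
    windows = []
    for i in range(m):
        j = i
        while j + 1 < m and not any(sig[order[a], order[j + 1]] for a in range(i, j + 1)):
            j += 1
        windows.append((i, j))
    maximal = sorted({w for w in windows
                      if not any(o != w and o[0] <= w[0] and w[1] <= o[1]
                                 for o in windows)})
    letters = [""] * m
    for gi, (a, b) in enumerate(maximal):
        ch = chr(ord("a") + gi)
        for t in range(a, b + 1):
            letters[order[t]] += ch
    return letters
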