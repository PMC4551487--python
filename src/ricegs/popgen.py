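"""Population-genetic characterization of a line panel.

All statistics operate on an allele-dosage matrix (lines x loci, values in
{0, 1, 2}) as produced by the simulator or read from VCF/CSV:

* per-locus allele frequencies, MAF, observed and expected heterozygosity
  (the expected value uses He = 2p(1-p)/4, i.e. panmictic heterozygosity
  deflated by two generations of selfing);
* pairwise linkage disequilibrium r-squared within chromosomes, with a
  distance-binned decay profile;
* pairwise Weir-Cockerham F_ST between subpopulations;
* effective population size from the LD among physically unlinked loci
  (Waples-Do method with the Waples 2006 sample-size correction);
* a mismatch-distance kinship matrix s = 2(1 - d) in [0, 2].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleStats",
    "LDResult",
    "FstResult",
    "NeEstimate",
    "KinshipMatrix",
    "allele_stats",
    "pairwise_ld",
    "ld_decay_profile",
    "fst_pairwise",
    "weir_cockerham_components",
    "estimate_ne_ld",
    "kinship",
]


# ---------------------------------------------------------------------------
# allele statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleStats:
    """Per-locus alternate-allele frequency p, MAF, observed heterozygosity
    Ho and selfing-deflated expected heterozygosity He = 2p(1-p)/4."""

    p: np.ndarray
    maf: np.ndarray
    ho: np.ndarray
    he: np.ndarray

    def to_frame(self, locus_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"p": self.p, "maf": self.maf, "ho": self.ho, "he": self.he})
        if locus_ids is not None:
            df.insert(0, "locus", list(locus_ids))
        return df


def allele_stats(dosage: np.ndarray) -> AlleleStats:
    """Compute :class:`AlleleStats` from a lines x loci dosage matrix."""
    dosage = np.asarray(dosage)
    if dosage.size == 0:
        raise ValueError("empty dosage matrix")
    if not np.isin(dosage, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0, 1, 2}")
    p = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    ho = (dosage == 1).mean(axis=0)
    he = 2.0 * p * (1.0 - p) / 4.0
    return AlleleStats(p=p, maf=maf, ho=ho, he=he)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDResult:
    """Within-chromosome marker pairs with distances and composite r²
    (squared Pearson correlation of unphased dosages)."""

    locus_a: np.ndarray
    locus_b: np.ndarray
    chrom: np.ndarray
    distance_kb: np.ndarray
    r2: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.r2.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_a": self.locus_a,
                "locus_b": self.locus_b,
                "chrom": self.chrom,
                "distance_kb": self.distance_kb,
                "r2": self.r2,
            }
        )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; returns (Z, polymorphic mask)."""
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Z, ok


def pairwise_ld(
    dosage: np.ndarray,
    gmap,
    loci: np.ndarray | None = None,
    max_distance_kb: float | None = None,
) -> LDResult:
    """r² between all pairs of markers on the same chromosome.

    ``loci`` restricts the computation to a subset of locus indices;
    ``max_distance_kb`` drops pairs farther apart than the cutoff.
    Monomorphic loci cannot enter a correlation and are skipped (logged).
    """
    loci = np.arange(gmap.n_loci) if loci is None else np.asarray(loci)
    A, B, C, D, R = [], [], [], [], []
    n_skipped = 0
    for c in np.unique(gmap.chrom[loci]):
        idx = loci[gmap.chrom[loci] == c]
        Z, ok = _standardize(dosage[:, idx])
        n_skipped += int((~ok).sum())
        idx = idx[ok]
        if idx.size < 2:
            continue
        Z = Z[:, ok]
        corr = (Z.T @ Z) / Z.shape[0]
        iu, ju = np.triu_indices(idx.size, k=1)
        dist = np.abs(gmap.pos_kb[idx[ju]] - gmap.pos_kb[idx[iu]])
        keep = slice(None) if max_distance_kb is None else dist <= max_distance_kb
        A.append(idx[iu][keep])
        B.append(idx[ju][keep])
        C.append(np.full((idx[iu][keep]).size, c))
        D.append(dist[keep])
        R.append((corr[iu, ju] ** 2)[keep])
    if n_skipped:
        logger.info("pairwise_ld: skipped %d monomorphic loci", n_skipped)
    if not A:
        raise ValueError("need at least two polymorphic loci on one chromosome")
    return LDResult(
        np.concatenate(A), np.concatenate(B), np.concatenate(C),
        np.concatenate(D), np.concatenate(R),
    )


def ld_decay_profile(ld: LDResult, bin_edges: np.ndarray) -> pd.DataFrame:
    """Distance-binned mean r² pooled over chromosomes.

    Returns a table (bin_lo, bin_hi, n_pairs, mean_r2) plus the half-decay
    distance in the DataFrame ``attrs`` (lower edge of the first bin whose
    mean r² drops to half the 0-th bin's mean; NaN if never reached).
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    which = np.digitize(ld.distance_kb, bin_edges) - 1
    rows = []
    for b in range(bin_edges.size - 1):
        sel = which == b
        rows.append(
            (
                bin_edges[b],
                bin_edges[b + 1],
                int(sel.sum()),
                float(ld.r2[sel].mean()) if sel.any() else np.nan,
            )
        )
    out = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n_pairs", "mean_r2"])
    half = np.nan
    if np.isfinite(out.loc[0, "mean_r2"]):
        target = out.loc[0, "mean_r2"] / 2.0
        hit = out.index[(out["mean_r2"] <= target) & out["mean_r2"].notna()]
        if len(hit):
            half = float(out.loc[hit[0], "bin_lo"])
    out.attrs["half_decay_kb"] = half
    return out


# ---------------------------------------------------------------------------
# F_ST (Weir & Cockerham 1984)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FstResult:
    """Pairwise multilocus Weir-Cockerham theta between subpopulations, with
    the per-locus variance components (a, b, c) of each pair."""

    subpops: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    components: dict[tuple[str, str], np.ndarray]  # (a, b, c) stacked, shape (3, loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.subpops, columns=self.subpops)


def weir_cockerham_components(
    dosage_by_pop: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components for r samples.

    Returns (a, b, c): among-population, among-individual-within-population
    and within-individual components, vectorized over loci.
    """
    r = len(dosage_by_pop)
    n_i = np.array([d.shape[0] for d in dosage_by_pop], dtype=float)  # (r,)
    p_i = np.stack([d.mean(axis=0) / 2.0 for d in dosage_by_pop])  # (r, L)
    h_i = np.stack([(d == 1).mean(axis=0) for d in dosage_by_pop])  # (r, L)

    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def fst_pairwise(
    dosage: np.ndarray, subpop_labels: np.ndarray, truncate_negative: bool = False
) -> FstResult:
    """Pairwise F_ST: multilocus ratio-of-sums theta per subpopulation pair.

    Loci monomorphic across both members of a pair contribute zero to both
    numerator and denominator.  Negative multilocus estimates are reported
    as-is unless ``truncate_negative``.
    """
    labels = np.asarray(subpop_labels)
    pops = [str(x) for x in pd.unique(labels)]
    if len(pops) < 2:
        raise ValueError("need at least two subpopulations")
    groups = {p: dosage[labels == p] for p in pops}
    for p, d in groups.items():
        if d.shape[0] < 2:
            raise ValueError(f"subpopulation {p!r} has fewer than two lines")

    k = len(pops)
    mat = np.zeros((k, k))
    comps: dict[tuple[str, str], np.ndarray] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b, c = weir_cockerham_components([groups[pops[i]], groups[pops[j]]])
            denom = a + b + c
            theta = a[denom != 0].sum() / denom[denom != 0].sum()
            if truncate_negative:
                theta = max(theta, 0.0)
            mat[i, j] = mat[j, i] = theta
            comps[(pops[i], pops[j])] = np.stack([a, b, c])
    return FstResult(subpops=pops, matrix=mat, components=comps)


# ---------------------------------------------------------------------------
# effective population size (LD method)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeEstimate:
    """LD-method effective size with the corrected mean r²' it derives from."""

    ne: float  # np.inf when r2_prime <= 0
    r2_mean: float
    r2_prime: float
    n_pairs: int
    sample_size: int
    ci95: tuple[float, float]

    @property
    def infinite(self) -> bool:
        return not np.isfinite(self.ne)


_MIN_S = 30  # smallest sample size the Waples (2006) constants cover


def _invert_ne(r2p: float) -> float:
    """Random-mating inversion N̂e = (1/3 + sqrt(1/9 - 2.76 r²')) / (2 r²')."""
    if r2p <= 0:
        return np.inf
    disc = max(1.0 / 9.0 - 2.76 * r2p, 0.0)
    return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2p)


def estimate_ne_ld(
    dosage: np.ndarray,
    gmap,
    maf_floor: float = 0.05,
    max_loci: int | None = None,
    seed: int = 0,
) -> NeEstimate:
    """Effective population size from LD among unlinked loci (Waples-Do).

    Mean r² is taken over inter-chromosomal pairs only (physical linkage
    cannot contribute), after dropping loci with MAF < ``maf_floor``.  The
    sampling expectation E[r²] = 1/S + 3.19/S² (S >= 30) is subtracted and
    the drift expectation inverted for Ne under random mating.  The 95% CI is
    parametric (chi-squared on the number of pairs, which overstates their
    independence and is therefore optimistic).
    """
    S = dosage.shape[0]
    if S < _MIN_S:
        raise ValueError(f"sample size {S} < {_MIN_S}, the smallest supported by the bias correction")
    chroms = np.unique(gmap.chrom)
    if chroms.size < 2:
        raise ValueError("need loci on at least two chromosomes for unlinked pairs")

    stats = allele_stats(dosage)
    keep = np.flatnonzero(stats.maf >= maf_floor)
    if max_loci is not None and keep.size > max_loci:
        keep = np.sort(np.random.default_rng(seed).choice(keep, max_loci, replace=False))

    Z, ok = _standardize(dosage[:, keep])
    keep = keep[ok]
    Z = Z[:, ok]
    chrom_of = gmap.chrom[keep]

    # sum of r^2 over inter-chromosomal pairs, block-wise by chromosome pair
    total, n_pairs = 0.0, 0
    cols = {c: np.flatnonzero(chrom_of == c) for c in np.unique(chrom_of)}
    cs = sorted(cols)
    for ii, c1 in enumerate(cs):
        for c2 in cs[ii + 1:]:
            block = (Z[:, cols[c1]].T @ Z[:, cols[c2]]) / S
            total += float((block**2).sum())
            n_pairs += block.size
    if n_pairs == 0:
        raise ValueError("no inter-chromosomal pair available")

    r2_mean = total / n_pairs
    e_sample = 1.0 / S + 3.19 / S**2
    r2p = r2_mean - e_sample
    ne = _invert_ne(r2p)
    lo = _invert_ne(r2_mean * n_pairs / _sps.chi2.ppf(0.025, n_pairs) - e_sample)
    hi = _invert_ne(r2_mean * n_pairs / _sps.chi2.ppf(0.975, n_pairs) - e_sample)
    ci = (min(lo, hi), max(lo, hi))
    return NeEstimate(ne=ne, r2_mean=r2_mean, r2_prime=r2p, n_pairs=n_pairs,
                      sample_size=S, ci95=ci)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinshipMatrix:
    """Mismatch-distance kinship: d_ij = (# loci with differing dosage)/M,
    similarity s_ij = 2(1 - d_ij) in [0, 2] with s_ii = 2."""

    similarity: np.ndarray
    distance: np.ndarray

    def to_frame(self, line_ids=None) -> pd.DataFrame:
        ids = list(line_ids) if line_ids is not None else None
        return pd.DataFrame(self.similarity, index=ids, columns=ids)


def kinship(dosage: np.ndarray) -> KinshipMatrix:
    """Compute the mismatch kinship matrix (requires complete data)."""
    dosage = np.asarray(dosage)
    if dosage.ndim != 2 or dosage.shape[1] == 0:
        raise ValueError("need a non-empty lines x loci matrix")
    m = dosage.shape[1]
    matches = np.zeros((dosage.shape[0], dosage.shape[0]))
    for v in (0, 1, 2):
        ind = (dosage == v).astype(np.float32)
        matches += ind @ ind.T
    d = 1.0 - matches / m
    return KinshipMatrix(similarity=2.0 * (1.0 - d), distance=d)
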