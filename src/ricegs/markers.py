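"""Incidence-matrix construction: MAF filtering, LD pruning, random sets.

Marker subsets feed the whole-genome regressions as a column-centered design
matrix X (lines x selected loci).  Selection is two-stage: loci are first
retained by a minor-allele-frequency threshold, then greedily pruned per
chromosome so that every retained pair has r² at or below the LD threshold.
Random marker sets of fixed sizes provide the density-matched control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import AlleleStats, allele_stats, _standardize

__all__ = [
    "IncidenceMatrix",
    "filter_by_maf",
    "prune_by_ld",
    "build_incidence_matrix",
    "sample_random_sets",
]


@dataclass(frozen=True)
class IncidenceMatrix:
    """A selected marker subset and its centered design matrix.

    ``provenance`` records how the set was obtained: either
    (maf_threshold, ld_threshold) or (random size, replicate id, seed).
    Centering subtracts the column mean 2p̂; ``standardize`` additionally
    divides by the column standard deviation.
    """

    loci: np.ndarray
    X: np.ndarray
    center: np.ndarray
    scale: np.ndarray | None
    provenance: dict

    @property
    def n_markers(self) -> int:
        return self.loci.size

    def design_for(self, dosage: np.ndarray) -> np.ndarray:
        """Center (and scale) new dosage rows with the stored training
        centering vector — prediction must reuse the training frame."""
        X = dosage[:, self.loci].astype(float) - self.center
        if self.scale is not None:
            X = X / self.scale
        return X

    def manifest(self, gmap=None, stats: AlleleStats | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"locus_index": self.loci})
        if gmap is not None:
            df["locus"] = np.asarray(gmap.locus_ids())[self.loci]
            df["chrom"] = gmap.chrom[self.loci] + 1
            df["pos_kb"] = gmap.pos_kb[self.loci]
        if stats is not None:
            df["maf"] = stats.maf[self.loci]
        for k, v in self.provenance.items():
            df[k] = v
        return df


def filter_by_maf(stats: AlleleStats, threshold: float) -> np.ndarray:
    """Indices of loci with MAF >= threshold (inclusive), original order."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    if threshold == 0.0:
        return np.flatnonzero(stats.maf > 0.0)  # polymorphic loci
    return np.flatnonzero(stats.maf >= threshold)


def prune_by_ld(
    dosage: np.ndarray, gmap, candidates: np.ndarray, r2_max: float
) -> np.ndarray:
    """Greedy within-chromosome LD pruning in map order.

    A candidate is retained iff its r² with every already-retained marker on
    the same chromosome is <= ``r2_max`` (first-seen marker wins).
    ``r2_max`` = 1 retains everything.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must be in (0, 1]")
    candidates = np.asarray(candidates)
    if r2_max == 1.0:
        return candidates.copy()
    kept_all = []
    for c in np.unique(gmap.chrom[candidates]):
        idx = candidates[gmap.chrom[candidates] == c]
        idx = idx[np.argsort(gmap.pos_kb[idx], kind="stable")]
        Z, ok = _standardize(dosage[:, idx])
        corr2 = ((Z.T @ Z) / Z.shape[0]) ** 2
        kept: list[int] = []
        for j in range(idx.size):
            if not ok[j]:
                continue  # monomorphic: no LD defined, keep conservatively? drop
            if not kept or np.all(corr2[j, kept] <= r2_max):
                kept.append(j)
        kept_all.append(idx[kept])
    out = np.concatenate(kept_all) if kept_all else np.empty(0, dtype=int)
    order = np.argsort([np.flatnonzero(candidates == i)[0] for i in out])
    return out[order]


def build_incidence_matrix(
    population,
    maf_threshold: float,
    ld_threshold: float,
    standardize: bool = False,
) -> IncidenceMatrix:
    """MAF filter -> per-chromosome LD pruning -> column-centered design."""
    dosage = population.dosage
    stats = allele_stats(dosage)
    sel = filter_by_maf(stats, maf_threshold)
    sel = prune_by_ld(dosage, population.gmap, sel, ld_threshold)
    if sel.size == 0:
        raise ValueError(
            f"no marker passes MAF >= {maf_threshold} with r2 <= {ld_threshold}"
        )
    return _finalize(
        dosage, sel, standardize,
        {"maf_threshold": maf_threshold, "ld_threshold": ld_threshold},
    )


def sample_random_sets(
    population,
    sizes,
    replicates: int,
    seed: int,
    standardize: bool = False,
) -> list[IncidenceMatrix]:
    """For each size, ``replicates`` independent uniform draws of loci
    without replacement; per-draw seeds are derived deterministically from
    the master seed."""
    dosage = population.dosage
    sizes = list(sizes)
    if max(sizes) > population.n_loci:
        raise ValueError(f"requested {max(sizes)} markers but only {population.n_loci} loci")
    out = []
    for size in sizes:
        for rep in range(replicates):
            rng = np.random.default_rng(np.random.SeedSequence([seed, size, rep]))
            sel = np.sort(rng.choice(population.n_loci, size=size, replace=False))
            out.append(
                _finalize(dosage, sel, standardize,
                          {"random_size": size, "replicate": rep, "seed": seed})
            )
    return out


def _finalize(dosage, sel, standardize, provenance) -> IncidenceMatrix:
    X = dosage[:, sel].astype(float)
    center = X.mean(axis=0)
    X = X - center
    scale = None
    if standardize:
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = X / scale
    return IncidenceMatrix(loci=np.asarray(sel), X=X, center=center, scale=scale,
                           provenance=provenance)
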