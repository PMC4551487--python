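"""Readers and writers for the package's on-disk formats.

Genotypes travel as VCF v4.2 (GT only, synthetic REF/ALT, 1-based positions;
written/read through pysam) or as a dosage CSV (rows = lines, columns =
locus ids).  The map is a CSV (locus, chrom, pos_kb, pos_cm), the field
trial a tidy CSV (line, trait, replicate, block, value), and BLUP tables a
line x trait CSV.  Internally locus indexing is 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .popsim import GeneticMap, Population

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_csv",
    "read_dosage_csv",
    "write_map_csv",
    "read_map_csv",
    "export_population",
    "load_population",
]

_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(population: Population, path) -> Path:
    """Write genotypes as uncompressed VCF v4.2 (GT from dosage; phase
    within a line is not preserved, heterozygotes become 0/1)."""
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    gmap = population.gmap
    for c in np.unique(gmap.chrom):
        header.contigs.add(f"chr{c + 1:02d}")
    for line in population.line_ids:
        header.add_sample(line)
    dosage = population.dosage
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, locus in enumerate(gmap.locus_ids()):
            rec = vcf.new_record(
                contig=f"chr{gmap.chrom[j] + 1:02d}",
                start=int(round(gmap.pos_kb[j] * 1000)),  # 0-based start -> 1-based POS
                alleles=("A", "T"),
                id=locus,
            )
            for i, line in enumerate(population.line_ids):
                rec.samples[line]["GT"] = _GT[int(dosage[i, j])]
            vcf.write(rec)
    return path


def read_vcf(path) -> tuple[pd.DataFrame, GeneticMap]:
    """Read a GT-only VCF into (dosage DataFrame lines x loci, map).

    Genetic positions are not stored in VCF; pos_cm is returned as NaN and
    should come from the map CSV when needed.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        loci, chroms, pos, rows = [], [], [], []
        for rec in vcf:
            loci.append(rec.id or f"{rec.contig}_{rec.pos}")
            chroms.append(int(rec.contig.replace("chr", "")) - 1)
            pos.append(rec.pos / 1000.0)
            rows.append([sum(rec.samples[s]["GT"]) for s in samples])
    dosage = pd.DataFrame(np.asarray(rows, dtype=np.int8).T, index=samples, columns=loci)
    gmap = GeneticMap(np.asarray(chroms), np.asarray(pos, dtype=float),
                      np.full(len(pos), np.nan))
    return dosage, gmap


def write_dosage_csv(population: Population, path) -> Path:
    path = Path(path)
    pd.DataFrame(population.dosage, index=population.line_ids,
                 columns=population.gmap.locus_ids()).to_csv(path, index_label="line")
    return path


def read_dosage_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="line")


def write_map_csv(gmap: GeneticMap, path) -> Path:
    path = Path(path)
    gmap.to_frame().to_csv(path, index=False)
    return path


def read_map_csv(path) -> GeneticMap:
    df = pd.read_csv(path)
    return GeneticMap(df["chrom"].to_numpy() - 1, df["pos_kb"].to_numpy(dtype=float),
                      df["pos_cm"].to_numpy(dtype=float))


def export_population(population: Population, trial: pd.DataFrame | None, outdir) -> dict:
    """Write VCF + dosage CSV + map CSV (+ optional trial CSV and subpop
    labels); round-trips losslessly through the readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(population, outdir / "genotypes.vcf"),
        "dosage": write_dosage_csv(population, outdir / "dosage.csv"),
        "map": write_map_csv(population.gmap, outdir / "map.csv"),
        "subpops": outdir / "subpops.csv",
    }
    pd.DataFrame({"line": population.line_ids,
                  "subpop": population.subpop_labels}).to_csv(paths["subpops"], index=False)
    if trial is not None:
        paths["trial"] = outdir / "trial.csv"
        trial.to_csv(paths["trial"], index=False)
    return paths


def load_population(outdir) -> Population:
    """Rebuild a Population from an exported directory (dosage CSV + map;
    haplotypes are reconstituted with heterozygotes phased arbitrarily)."""
    outdir = Path(outdir)
    dosage = read_dosage_csv(outdir / "dosage.csv")
    gmap = read_map_csv(outdir / "map.csv")
    sub = pd.read_csv(outdir / "subpops.csv")
    d = dosage.to_numpy(dtype=np.int8)
    h0 = (d >= 1).astype(np.int8)
    h1 = (d == 2).astype(np.int8)
    haps = np.stack([h0, h1], axis=1)
    return Population(list(dosage.index), sub["subpop"].to_numpy(), haps, gmap,
                      generation="imported")
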