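"""Positional candidate-gene lookup and pairwise LD (r^2) for region plots.

Gene annotation is always a local BED or GFF3 file supplied by the user;
intervals are held in the 1-based inclusive convention internally (BED's
0-based half-open coordinates are converted on read).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataFormatError
from .genotypes import GenotypeMatrix


@dataclass
class GeneInterval:
    """A named gene interval, 1-based inclusive coordinates."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(
                f"gene {self.name!r}: start {self.start} > end {self.end}"
            )


@dataclass
class CandidateGene:
    """Nearest gene to a query SNP; distance 0 means the SNP lies within."""

    name: str | None
    distance_bp: int | None

    @property
    def within(self) -> bool:
        return self.distance_bp == 0

    @property
    def distance_label(self) -> str:
        if self.name is None:
            return "/"
        return "within" if self.within else str(self.distance_bp)


def read_bed_genes(path) -> list[GeneInterval]:
    """BED (3+ columns, 0-based half-open) -> 1-based inclusive intervals."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            strand = parts[5] if len(parts) > 5 else "."
            genes.append(GeneInterval(name, str(chrom), start + 1, end, strand))
    return genes


def read_gff3_genes(path, feature_types: tuple = ("gene",)) -> list[GeneInterval]:
    """Gene features from a GFF3 file (already 1-based inclusive)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataFormatError(f"{path}:{lineno}: GFF3 line has {len(parts)} columns")
            if parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID") or f"feature_{lineno}"
            genes.append(
                GeneInterval(name, str(parts[0]), int(parts[3]), int(parts[4]), parts[6])
            )
    return genes


def nearest_gene(chrom, pos_bp: int, genes: list[GeneInterval]) -> CandidateGene:
    """Nearest interval to a SNP position on its chromosome.

    Inside an interval -> distance 0; otherwise the interval minimising the
    distance to its closest edge; ties go to the smaller start. Returns an
    empty result (name None) when the chromosome has no genes.
    """
    here = [g for g in genes if g.chrom == str(chrom)]
    if not here:
        return CandidateGene(None, None)
    best: GeneInterval | None = None
    best_dist: int | None = None
    for g in sorted(here, key=lambda g: (g.start, g.end)):
        if g.start <= pos_bp <= g.end:
            dist = 0
        else:
            dist = min(abs(pos_bp - g.start), abs(pos_bp - g.end))
        if best_dist is None or dist < best_dist:
            best, best_dist = g, dist
    return CandidateGene(best.name, int(best_dist))


def annotate_windows(windows, genes: list[GeneInterval], snp_map: pd.DataFrame) -> pd.DataFrame:
    """Candidate-gene table for selected windows (uses each window's top SNP)."""
    pos_of = dict(zip(snp_map["snp"], snp_map["pos_bp"]))
    rows = []
    for w in windows:
        pos = pos_of.get(w.top_snp)
        cand = (
            nearest_gene(w.chrom, int(pos), genes)
            if pos is not None
            else CandidateGene(None, None)
        )
        rows.append(
            {
                "chrom": w.chrom,
                "window_start_bp": w.start_bp,
                "window_end_bp": w.end_bp,
                "gvar_percent": w.gvar_percent,
                "top_snp": w.top_snp,
                "candidate_gene": cand.name if cand.name else "/",
                "distance": cand.distance_label,
                "trait": w.trait,
            }
        )
    return pd.DataFrame(rows)


def ld_r2(genotypes: GenotypeMatrix, chrom=None, start_bp=None, end_bp=None) -> pd.DataFrame:
    """Pairwise r^2 (squared Pearson correlation of dosages) for a region.

    Unphased composite estimator over animals with both calls non-missing;
    monomorphic SNPs yield missing (NaN) r^2 for their pairs. Returns a
    symmetric DataFrame indexed by SNP id with a unit diagonal.
    """
    mask = np.ones(genotypes.n_snps, dtype=bool)
    if chrom is not None:
        mask &= genotypes.snp_map["chrom"].astype(str).to_numpy() == str(chrom)
    if start_bp is not None:
        mask &= genotypes.snp_map["pos_bp"].to_numpy() >= start_bp
    if end_bp is not None:
        mask &= genotypes.snp_map["pos_bp"].to_numpy() <= end_bp
    idx = np.nonzero(mask)[0]
    if idx.size < 2:
        raise ConfigurationError("LD region must contain at least 2 SNPs")
    if genotypes.n_animals < 2:
        raise ConfigurationError("LD needs at least 2 genotyped animals")
    sub = genotypes.subset(snp_idx=idx)
    df = pd.DataFrame(sub.dosages, columns=sub.snp_map["snp"])
    r = df.corr(min_periods=2)
    r2 = r**2
    np.fill_diagonal(r2.values, 1.0)
    return r2


def ld_long_format(r2: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangle long format (snp_a, snp_b, r2) for plotting exports."""
    snps = r2.index.to_list()
    rows = []
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            rows.append({"snp_a": snps[i], "snp_b": snps[j], "r2": r2.iat[i, j]})
    return pd.DataFrame(rows)
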