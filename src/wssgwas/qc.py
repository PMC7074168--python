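"""Phenotype derivation/cleaning and genotype quality control.

Phenotype side: average daily gain derivation and single-pass +-3 SD outlier
removal. Genotype side: the standard GWAS panel filters (individual call
rate, SNP call rate, minor allele frequency, Hardy-Weinberg exact test,
autosome/position checks) applied in PLINK-like order with a per-step report.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .genotypes import GenotypeMatrix


def derive_byadg(bw, yw, days):
    """Average daily gain from birth to yearling: (yw - bw) / days (kg/day).

    Accepts scalars or arrays; NaN inputs propagate to NaN outputs; days <= 0
    raises.
    """
    bw = np.asarray(bw, dtype=float)
    yw = np.asarray(yw, dtype=float)
    days = np.asarray(days, dtype=float)
    valid_days = days[~np.isnan(days)]
    if np.any(valid_days <= 0):
        raise ConfigurationError("days must be positive to derive daily gain")
    out = (yw - bw) / days
    return float(out) if out.ndim == 0 else out


def remove_outliers(values, ids=None, n_sd: float = 3.0):
    """Single-pass outlier screen: drop records with |x - mean| > n_sd * SD.

    Mean and SD (sample, n-1 denominator) are computed once on the non-missing
    input; there is no re-iteration after removal. Returns (kept values,
    removed ids); ids default to positional indices.
    """
    x = np.asarray(values, dtype=float)
    if ids is None:
        ids = np.arange(len(x))
    ids = np.asarray(ids)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ConfigurationError("outlier screen needs at least 2 non-missing values")
    mean = x[ok].mean()
    sd = x[ok].std(ddof=1)
    outlier = ok & (np.abs(x - mean) > n_sd * sd)
    keep = ok & ~outlier
    return x[keep], ids[outlier]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton et al. 2005).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the observed
    count. Returns the p-value (1.0 for monomorphic SNPs, which admit a single
    configuration).
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ConfigurationError("genotype counts must be nonnegative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ConfigurationError("total genotype count must be positive")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0
    # distribution over heterozygote counts conditional on allele counts:
    #   P(het) propto 2^het / (hom_rare! * hom_common! * het!)
    # evaluated in log space for stability at large counts
    from scipy.special import gammaln

    het_obs = n_Aa
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_common = 2 * n - n_rare
    hom_rare = (n_rare - hets) // 2
    hom_common = (n_common - hets) // 2
    logw = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
        - gammaln(hets + 1)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == het_obs)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-10)].sum()))


@dataclass
class QcReport:
    """Per-step removal counts and the thresholds used."""

    n_animals_in: int
    n_snps_in: int
    n_individuals_removed_call_rate: int = 0
    n_snps_removed_call_rate: int = 0
    n_snps_removed_maf: int = 0
    n_snps_removed_hwe: int = 0
    n_snps_removed_position: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_animals_out(self) -> int:
        return self.n_animals_in - self.n_individuals_removed_call_rate

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - (
            self.n_snps_removed_call_rate
            + self.n_snps_removed_maf
            + self.n_snps_removed_hwe
            + self.n_snps_removed_position
        )


def apply_genotype_qc(
    genotypes: GenotypeMatrix,
    ind_call_rate: float = 0.95,
    snp_call_rate: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    autosome_max: int | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Panel quality control in PLINK-like order.

    Steps: (1) drop individuals with call rate < ``ind_call_rate``; then on
    the remaining animals (2) drop SNPs with call rate < ``snp_call_rate``,
    (3) minor allele frequency < ``maf_min`` (strict), (4) Hardy-Weinberg
    exact p < ``hwe_p_min``, (5) non-autosomal (chrom > ``autosome_max`` or
    unmapped/nonpositive position). Raises if nothing survives.
    """
    for name, v in (("ind_call_rate", ind_call_rate), ("snp_call_rate", snp_call_rate),
                    ("maf_min", maf_min), ("hwe_p_min", hwe_p_min)):
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(f"{name} must be in [0,1], got {v}")
    report = QcReport(
        genotypes.n_animals,
        genotypes.n_snps,
        thresholds={
            "ind_call_rate": ind_call_rate,
            "snp_call_rate": snp_call_rate,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "autosome_max": autosome_max,
        },
    )
    X = genotypes.dosages
    called = ~np.isnan(X)
    ind_cr = called.mean(axis=1)
    keep_animals = np.nonzero(ind_cr >= ind_call_rate)[0]
    report.n_individuals_removed_call_rate = genotypes.n_animals - keep_animals.size
    g = genotypes.subset(animal_idx=keep_animals)
    if g.n_animals == 0:
        raise ConfigurationError("all individuals removed by the call-rate filter")

    X = g.dosages
    called = ~np.isnan(X)
    n_called = called.sum(axis=0)
    keep = np.ones(g.n_snps, dtype=bool)

    cr_fail = n_called / g.n_animals < snp_call_rate
    report.n_snps_removed_call_rate = int(cr_fail.sum())
    keep &= ~cr_fail

    with np.errstate(invalid="ignore"):
        p = np.where(n_called > 0, np.nansum(X, axis=0) / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    maf_fail = keep & (np.isnan(maf) | (maf < maf_min))
    report.n_snps_removed_maf = int(maf_fail.sum())
    keep &= ~maf_fail

    hwe_fail = np.zeros(g.n_snps, dtype=bool)
    for j in np.nonzero(keep)[0]:
        col = X[:, j]
        n_aa = int(np.sum(col == 0))
        n_het = int(np.sum(col == 1))
        n_AA = int(np.sum(col == 2))
        if hwe_exact_test(n_AA, n_het, n_aa) < hwe_p_min:
            hwe_fail[j] = True
    report.n_snps_removed_hwe = int(hwe_fail.sum())
    keep &= ~hwe_fail

    chrom = g.snp_map["chrom"].to_numpy()
    pos = g.snp_map["pos_bp"].to_numpy()
    numeric_chrom = np.array([_as_int_or(c, -1) for c in chrom])
    pos_fail = (numeric_chrom <= 0) | (pos <= 0)
    if autosome_max is not None:
        pos_fail |= numeric_chrom > autosome_max
    pos_fail &= keep
    report.n_snps_removed_position = int(pos_fail.sum())
    keep &= ~pos_fail

    if not keep.any():
        raise ConfigurationError("all SNPs removed by QC; check thresholds and input")
    return g.subset(snp_idx=np.nonzero(keep)[0]), report


def _as_int_or(value, default: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        return default
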