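"""Synthetic pedigree / genotype / phenotype generator.

Emulates the data structure the single-step analysis assumes: a multi
generation pedigree in which only a small fraction of animals is genotyped,
linked biallelic SNPs on several autosomes (gene-drop with Haldane, i.e.
no-interference, recombination), and phenotypes built as fixed effects +
additive genetic values (QTL + polygenic) + residual at a target
heritability.

Mating scheme: discrete non-overlapping generations, random male x female
pairing, equal sex ratio, no selection.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .genotypes import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree


@dataclass
class FixedEffectSpec:
    """Levels and effect sizes of the categorical fixed effects plus an age slope.

    Effects are in trait units; age slope in trait units per day. Age at
    recording is drawn N(age_mean_days, age_sd_days), matching yearling-type
    recording windows (e.g. 360 +- 30 d).
    """

    intercept: float = 100.0
    sex_effect: float = 8.0          # male - female contrast
    n_farms: int = 4
    farm_sd: float = 5.0             # SD of farm level effects
    n_years: int = 5
    year_sd: float = 3.0
    use_type_effect: float = 4.0     # meat - dual-purpose contrast
    age_slope: float = 0.5
    age_mean_days: float = 360.0
    age_sd_days: float = 30.0


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    Defaults give ~1000 animals over 3 generations with 10% genotyped and
    heritability in the range reported for beef-cattle growth traits.
    """

    n_founders: int = 80
    n_generations: int = 3
    offspring_per_mating: int = 8
    n_chromosomes: int = 5
    snps_per_chromosome: int = 200
    chromosome_length_cM: float = 100.0
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 10
    qtl_variance_fraction: float = 0.5
    heritability: float = 0.42
    fixed_effect_spec: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    genotyped_fraction: float = 0.1
    include_qtl_in_panel: bool = True
    phenotypic_variance: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_chromosomes", "snps_per_chromosome"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if self.n_generations > 0 and self.offspring_per_mating < 1:
            raise ConfigurationError("offspring_per_mating must be >= 1")
        if not (0.0 < self.heritability < 1.0):
            raise ConfigurationError(
                f"heritability must be strictly in (0,1), got {self.heritability}"
            )
        if not (0.0 < self.genotyped_fraction <= 1.0):
            raise ConfigurationError(
                f"genotyped_fraction must be in (0,1], got {self.genotyped_fraction}"
            )
        if not (0.0 <= self.qtl_variance_fraction <= 1.0):
            raise ConfigurationError(
                f"qtl_variance_fraction must be in [0,1], got {self.qtl_variance_fraction}"
            )
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"founder_maf_range must lie in (0, 0.5], got {self.founder_maf_range}"
            )
        if self.n_qtl < 0 or self.n_qtl > self.n_chromosomes * self.snps_per_chromosome:
            raise ConfigurationError("n_qtl out of range for the SNP panel")
        if self.chromosome_length_cM <= 0:
            raise ConfigurationError("chromosome_length_cM must be positive")


@dataclass
class SimTruth:
    """Ground truth recorded by the phenotype simulator."""

    true_breeding_values: np.ndarray
    qtl_positions: np.ndarray
    qtl_effects: np.ndarray
    realized_h2: float
    sigma_a2: float
    sigma_e2: float


def simulate_pedigree(config: SimConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Random-mating multi-generation pedigree.

    Returns the pedigree and a metadata frame (id, sex, generation). Sexes are
    assigned alternately within each cohort so the ratio stays balanced.
    """
    rng = np.random.default_rng(config.seed)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[int] = []  # 0 = male, 1 = female
    generation: list[int] = []

    def add(s: int, d: int, sx: int, gen: int) -> int:
        idx = len(ids)
        ids.append(f"A{idx + 1:06d}")
        sire.append(s)
        dam.append(d)
        sex.append(sx)
        generation.append(gen)
        return idx

    cohort = [add(UNKNOWN, UNKNOWN, i % 2, 0) for i in range(config.n_founders)]
    for gen in range(1, config.n_generations + 1):
        males = [i for i in cohort if sex[i] == 0]
        females = [i for i in cohort if sex[i] == 1]
        n_matings = min(len(males), len(females))
        if n_matings == 0:
            raise ConfigurationError(
                f"generation {gen}: cannot form matings (single-sex cohort)"
            )
        ms = rng.permutation(np.array(males))[:n_matings]
        fs = rng.permutation(np.array(females))[:n_matings]
        new_cohort = []
        for s, d in zip(ms, fs):
            for k in range(config.offspring_per_mating):
                new_cohort.append(add(int(s), int(d), k % 2, gen))
        cohort = new_cohort

    ped = Pedigree(np.array(ids, dtype=object), np.array(sire), np.array(dam))
    meta = pd.DataFrame({"id": ids, "sex": sex, "generation": generation})
    return ped, meta


def _snp_map(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced SNPs; 1 cM is laid out as 1 Mb of physical position."""
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        cm = np.linspace(0.0, config.chromosome_length_cM, config.snps_per_chromosome)
        for j, pos in enumerate(cm):
            rows.append(
                {
                    "snp": f"SNP{c:02d}_{j + 1:05d}",
                    "chrom": c,
                    "pos_bp": int(round(pos * 1e6)) + 1,
                    "cm": pos,
                    "a1": "A",
                    "a2": "B",
                }
            )
    return pd.DataFrame(rows)


def haldane_recombination_fraction(distance_cM: np.ndarray) -> np.ndarray:
    """Haldane map function: r = (1 - exp(-2 d_Morgan)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(distance_cM) / 100.0))


def _meiosis(haplo_pair: np.ndarray, r_adj: list[np.ndarray], chrom_slices, rng) -> np.ndarray:
    """One gamete from a (2, M) haplotype pair; Markov crossover per chromosome."""
    m = haplo_pair.shape[1]
    gamete = np.empty(m, dtype=np.int8)
    for sl, r in zip(chrom_slices, r_adj):
        k = sl.stop - sl.start
        switch = rng.random(k - 1) < r if k > 1 else np.empty(0, dtype=bool)
        origin = np.empty(k, dtype=np.int8)
        origin[0] = rng.integers(2)
        if k > 1:
            origin[1:] = origin[0] ^ (np.cumsum(switch.astype(np.int8)) % 2)
        gamete[sl] = haplo_pair[origin, np.arange(sl.start, sl.stop)]
    return gamete


def gene_drop_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Drop founder haplotypes through the pedigree with recombination.

    Founder haplotype alleles are Bernoulli draws at per-SNP frequencies
    sampled uniformly from ``founder_maf_range``; offspring gametes follow a
    no-interference (Haldane) crossover process along each chromosome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    snp_map = _snp_map(config)
    m = len(snp_map)
    n = len(pedigree)
    chrom_slices = []
    r_adj = []
    for c, grp in snp_map.groupby("chrom", sort=True):
        sl = slice(int(grp.index[0]), int(grp.index[-1]) + 1)
        chrom_slices.append(sl)
        d = np.diff(grp["cm"].to_numpy())
        r_adj.append(haldane_recombination_fraction(d))
    p = rng.uniform(*config.founder_maf_range, size=m)
    # counted allele is 'A' at frequency p (may end up minor or major; QC decides)
    haplos = np.zeros((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            haplos[i] = rng.random((2, m)) < p
        else:
            # spec guarantees both parents known for non-founders in this scheme
            haplos[i, 0] = _meiosis(haplos[s], r_adj, chrom_slices, rng)
            haplos[i, 1] = _meiosis(haplos[d], r_adj, chrom_slices, rng)
    dosages = haplos.sum(axis=1).astype(np.float64)
    return GenotypeMatrix(pedigree.ids.copy(), snp_map, dosages)


def _polygenic_values(pedigree: Pedigree, sigma2: float, rng) -> np.ndarray:
    """Breeding values by the pedigree recursion u_i = (u_s + u_d)/2 + Mendelian."""
    if sigma2 == 0.0:
        return np.zeros(len(pedigree))
    F = pedigree.inbreeding()
    u = np.zeros(len(pedigree))
    for i in range(len(pedigree)):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            u[i] = rng.normal(0.0, np.sqrt(sigma2))
        else:
            ps = u[s] if s != UNKNOWN else 0.0
            pd_ = u[d] if d != UNKNOWN else 0.0
            fs = F[s] if s != UNKNOWN else 0.0
            fd = F[d] if d != UNKNOWN else 0.0
            # Mendelian-sampling variance given the known parents:
            #   both known: sigma2 * (0.5 - (F_s + F_d)/4); one known: 0.75 * sigma2
            if s != UNKNOWN and d != UNKNOWN:
                mend_var = sigma2 * (0.5 - 0.25 * (fs + fd))
            else:
                mend_var = sigma2 * 0.75
            u[i] = 0.5 * (ps + pd_) + rng.normal(0.0, np.sqrt(max(mend_var, 0.0)))
    return u


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    meta: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotypes y = fixed effects + QTL value + polygenic value + residual.

    The additive variance sigma_a2 = h2 * sigma_p2 is split between QTLs
    (``qtl_variance_fraction``) and a pedigree polygenic term. QTL effects are
    drawn N(0,1) and rescaled so the base-generation (founder) variance of the
    QTL genetic value hits its target, which keeps REML (which estimates base
    population variance) unbiased.
    """
    cfg = config
    h2 = cfg.heritability
    sigma_p2 = cfg.phenotypic_variance
    sigma_a2 = h2 * sigma_p2
    sigma_e2 = (1.0 - h2) * sigma_p2
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = len(pedigree)
    if genotypes.n_animals != n:
        raise ConfigurationError(
            "phenotype simulation needs QTL genotypes for every pedigree animal "
            "(mask genotypes after simulating phenotypes)"
        )

    var_qtl = cfg.qtl_variance_fraction * sigma_a2 if cfg.n_qtl > 0 else 0.0
    var_poly = sigma_a2 - var_qtl
    founders = np.nonzero((pedigree.sire == UNKNOWN) & (pedigree.dam == UNKNOWN))[0]

    if cfg.n_qtl > 0 and var_qtl > 0:
        qtl_pos = np.sort(rng.choice(genotypes.n_snps, size=cfg.n_qtl, replace=False))
        effects = rng.standard_normal(cfg.n_qtl)
        Xq = genotypes.dosages[:, qtl_pos]
        g = Xq @ effects
        base_var = np.var(g[founders], ddof=1) if founders.size > 1 else np.var(g, ddof=1)
        if base_var <= 0:
            raise ConfigurationError("QTL genetic value has zero variance in founders")
        scale = np.sqrt(var_qtl / base_var)
        effects *= scale
        g *= scale
    else:
        qtl_pos = np.array([], dtype=int)
        effects = np.array([])
        g = np.zeros(n)

    u = _polygenic_values(pedigree, var_poly, rng)
    tbv = g + u
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)

    fe = cfg.fixed_effect_spec
    if covariates is not None:
        # reuse a previously drawn covariate table (fixed design across
        # phenotype replicates); effect values are still redrawn
        sex = np.where(covariates["sex"].to_numpy() == "M", 0, 1)
        year = covariates["year"].to_numpy()
        use_type = np.where(covariates["use_type"].to_numpy() == "meat", 1, 0)
        farm = np.array([int(str(f)[1:]) - 1 for f in covariates["farm"]])
        age = covariates["age_days"].to_numpy(dtype=float)
    else:
        if meta is None:
            sex = np.arange(n) % 2
            generation = np.zeros(n, dtype=int)
        else:
            sex = meta["sex"].to_numpy()
            generation = meta["generation"].to_numpy()
        farm = rng.integers(fe.n_farms, size=n)
        year = 2001 + generation * 2 + rng.integers(2, size=n)
        use_type = rng.integers(2, size=n)
        age = rng.normal(fe.age_mean_days, fe.age_sd_days, size=n)
    farm_eff = rng.normal(0.0, fe.farm_sd, size=int(farm.max()) + 1)
    year_levels = np.unique(year)
    year_eff = {y: v for y, v in zip(year_levels, rng.normal(0.0, fe.year_sd, size=len(year_levels)))}

    fixed = (
        fe.intercept
        + fe.sex_effect * (sex == 0)
        + farm_eff[farm]
        + np.array([year_eff[y] for y in year])
        + fe.use_type_effect * use_type
        + fe.age_slope * (age - fe.age_mean_days)
    )
    y = fixed + tbv + e

    var_a = float(np.var(tbv, ddof=1))
    var_e = float(np.var(e, ddof=1))
    truth = SimTruth(
        true_breeding_values=tbv,
        qtl_positions=qtl_pos,
        qtl_effects=effects,
        realized_h2=var_a / (var_a + var_e),
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
    )
    phen = pd.DataFrame(
        {
            "id": pedigree.ids,
            "trait": y,
            "sex": np.where(sex == 0, "M", "F"),
            "year": year,
            "use_type": np.where(use_type == 1, "meat", "dual"),
            "farm": [f"F{k + 1}" for k in farm],
            "age_days": age,
        }
    )
    return phen, truth


def mask_genotypes(
    genotypes: GenotypeMatrix, fraction: float, seed: int
) -> GenotypeMatrix:
    """Keep genotype records for a random subset of animals.

    The subset size is ``round(fraction * n)``; the returned matrix contains
    only the selected animals (others carry no genotype record), preserving
    pedigree order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError(f"genotyped fraction must be in (0,1], got {fraction}")
    if fraction == 1.0:
        return genotypes
    n = genotypes.n_animals
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=k, replace=False))
    return genotypes.subset(animal_idx=keep)


def simulate_dataset(config: SimConfig):
    """Full synthetic dataset: pedigree, masked genotypes, phenotypes, truth.

    Returns (pedigree, genotypes_all, genotypes_masked, phenotypes, truth, meta).
    The pedigree's genotyped flags are set from the masked subset.
    """
    ped, meta = simulate_pedigree(config)
    geno_all = gene_drop_genotypes(ped, config)
    phen, truth = simulate_phenotypes(ped, geno_all, config, meta)
    geno = mask_genotypes(geno_all, config.genotyped_fraction, config.seed + 7)
    if not config.include_qtl_in_panel and truth.qtl_positions.size:
        keep = np.setdiff1d(np.arange(geno.n_snps), truth.qtl_positions)
        geno = geno.subset(snp_idx=keep)
    gset = set(geno.animal_ids.tolist())
    ped.genotyped = np.array([a in gset for a in ped.ids])
    return ped, geno_all, geno, phen, truth, meta
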