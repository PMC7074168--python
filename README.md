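# wssgwas

Weighted single-step GWAS for populations where many animals are phenotyped
and pedigree-recorded but only a small fraction is genotyped — the typical
situation in national beef-cattle breeding programs, where thousands of
growth records (birth weight, yearling weight, daily gain, 18-month weight)
coexist with a few hundred SNP-chip genotypes.

## The model

All animals enter a single-trait animal model

```
y = W b + Z a + e,    a ~ N(0, H σa²),    e ~ N(0, I σe²)
```

where `b` holds the fixed effects (sex, birth year, use type, farm, and age
in days as a covariate for post-birth traits) and `a` the additive genetic
effects of every pedigree animal. `H` unifies pedigree and marker
information through its inverse

```
H⁻¹ = A⁻¹ + [ 0  0 ; 0  G⁻¹ − A₂₂⁻¹ ]
```

with `A` the pedigree numerator relationship matrix, `A₂₂` its block for the
genotyped animals, and `G = Z D Z′ / Σ 2pᵢ(1−pᵢ)` the (weighted) VanRaden
genomic relationship with per-SNP variance weights `D`. Variance components
come from REML (EM iterations on a one-time spectral decomposition of the
design, with an optional average-information step that also yields standard
errors).

The association statistic is obtained by back-solving SNP effects from the
genomic breeding values of the genotyped animals,

```
û = λ D Z′ G⁻¹ â_g,        λ = 1 / Σ 2pᵢ(1−pᵢ)
```

re-weighting each SNP by the variance it explains, `dᵢ = ûᵢ² · 2pᵢ(1−pᵢ)`,
normalizing `D` so its trace stays at the SNP count (total genetic variance
constant), rebuilding `G` and iterating (three iterations by default).
Evidence is reported as the percentage of additive genetic variance carried
by sliding windows of 20 consecutive SNPs:

```
gVar% = var(Σⱼ zⱼ ûⱼ) / σa² × 100
```

computed across genotyped animals, step 1, never crossing a chromosome.
Windows above 1% are selected, overlapping runs collapse to their local
maximum, and the top SNP of each window (largest `ûⱼ²·2pⱼ(1−pⱼ)`) is
annotated against a user-supplied BED/GFF3 gene set.

Because no real dataset ships with the package, a first-class synthetic-data
generator (`wssgwas.simulate`) produces multi-generation pedigrees, linked
genotypes by gene-drop with Haldane recombination, and phenotypes with
configurable heritability, QTL content and fixed-effect structure; every
pipeline stage is tested against it and against closed-form oracles.

## Worked example

```python
from wssgwas import SimConfig, simulate_dataset, SingleStepGBLUP, ModelSpec
from wssgwas.association import WeightedSingleStepGWAS
from wssgwas.qc import apply_genotype_qc
from wssgwas.relationship import (build_A_inverse, build_A22, build_G,
                                  blend_G, build_H_inverse, compute_allele_freqs)

cfg = SimConfig(n_founders=100, n_generations=2, offspring_per_mating=6,
                n_chromosomes=3, snps_per_chromosome=150, n_qtl=3,
                qtl_variance_fraction=0.5, heritability=0.42,
                genotyped_fraction=0.3, seed=42)
ped, _, geno, phen, truth, _ = simulate_dataset(cfg)
geno, report = apply_genotype_qc(geno)

A_inv = build_A_inverse(ped)
A22 = build_A22(ped)
G = blend_G(build_G(geno, compute_allele_freqs(geno)), A22, beta=0.95)
H_inv = build_H_inverse(A_inv, A22, G, ped.genotyped_index)

result = SingleStepGBLUP(phen, ped, H_inv, ModelSpec()).fit(method="ai")
print(result.summary())
windows = WeightedSingleStepGWAS(phen, ped, geno, ModelSpec(), vc=result.vc).fit()
print(windows.summary())
```

prints

```
Single-step GBLUP animal model
==========================================================
trait: trait   records: 1300   pedigree animals: 1300   genotyped: 390
mean 103.596  SD 18.768  min 40.196  max 178.017  CV% 18.12
----------------------------------------------------------
sigma_a2 47.474 (SE 7.03)
sigma_e2 59.4458 (SE 4.26)
sigma_p2 106.92
h2       0.4440 (SE 0.0501)
REML: method=ai iterations=8 converged=True
==========================================================
Weighted single-step GWAS
==========================================================
trait: trait   iterations: 3   window: 20 SNPs   threshold: >1.0%
h2 used: 0.444  (sigma_a2 47.47, sigma_e2 59.45)
selected windows: 4   gVar% range 3.67-20.34
----------------------------------------------------------
chr 1: 80,536,914-93,288,592  gVar 20.34%  top SNP01_00130
chr 3: 53,691,276-66,442,954  gVar 13.74%  top SNP03_00090
chr 2: 36,241,612-48,993,290  gVar 3.69%  top SNP02_00056
chr 3: 1,342,283-14,765,102  gVar 3.67%  top SNP03_00017
==========================================================
```

The simulation placed three QTLs carrying half the additive variance; REML
recovers the simulated heritability (0.444 estimated vs 0.42 simulated,
within one standard error) and the two strongest selected windows sit on the
two largest simulated QTLs (the top SNPs at chr1 SNP 130 and chr3 SNP 90 tag
the causal SNPs at panel indices 129 and 394).

A command-line interface mirrors the library:
`wssgwas simulate | qc | relmat | reml | run | annotate | ld`, each driven by
a YAML config with flag overrides (see `wssgwas --help`).

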