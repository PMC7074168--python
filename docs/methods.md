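# Methods

This note records the model, the numerical choices, and what the synthetic
data generator does and does not emulate.

## The single-step animal model

A single quantitative trait is modelled as `y = Wb + Za + e` with
`a ~ N(0, H σa²)`, `e ~ N(0, I σe²)`. The fixed-effect design `W` contains an
intercept, drop-first dummy coding for each categorical factor (sex, birth
year, use type, farm) and mean-centered covariates (age in days for traits
recorded after birth). Drop-first coding resolves the rank deficiency of
one-hot factors; the reference level of each factor is absorbed into the
intercept. `Z` is the 0/1 incidence of records onto pedigree animals; every
pedigree animal carries a breeding value whether or not it has a record.

`H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹]` is implemented exactly in this unscaled
form (no τ/ω scaling of the correction block). `A⁻¹` is assembled sparsely by
Henderson's rules with exact inbreeding coefficients obtained from a memoised
kinship recursion (equivalent to the Meuwissen–Luo recursion); `A` itself and
`A₂₂` come from the tabular method. `G` follows VanRaden with per-SNP weights:
dosages are centered by twice the allele frequency, missing calls are
mean-imputed (centered value zero, which leaves G unbiased in expectation),
and the denominator is `Σ 2pᵢ(1−pᵢ)`. Allele frequencies are computed from the
observed genotyped animals and tagged as such; supplied (base-population)
frequencies are accepted everywhere.

With observed frequencies the centered dosage columns each sum to zero, so
`G` always carries the all-ones vector in its null space and is singular by
construction. `G` is therefore blended as `βG + (1−β)A₂₂` with β = 0.95 by
default before inversion (β = 1 disables blending and is appropriate only
when `G` is full rank, e.g. with supplied frequencies). The back-solve
identity `Zû = â_g` is exact for unblended full-rank `G`; under blending the
relative deviation is recorded in the run object rather than asserted.

## REML

Variance components are estimated by EM-REML. Writing `S` for the projection
orthogonal to `W` and `M = Z′SZ + k H⁻¹` (k = σe²/σa²), the EM updates are
the textbook pair

```
σa² ← (â′H⁻¹â + σe² · tr(H⁻¹M⁻¹)) / q
σe² ← (y′Sy − â′Z′Sy) / (n − rank W)
```

Numerical engine: a one-time generalized eigendecomposition
`Φ′ H⁻¹ Φ = I`, `Φ′ Z′SZ Φ = diag(λ)` turns every quantity above into an
O(q) expression — `tr(H⁻¹M⁻¹) = Σ 1/(λᵢ+k)`, `â′H⁻¹â = Σ vᵢ²/(λᵢ+k)²` with
`v = Φ′Z′Sy` — and gives the REML deviance in closed form,

```
−2ℓ = (n−p−q)·log σe² + q·log σa² + Σ log(λᵢ+k) + (y′Sy − Σ vᵢ²/(λᵢ+k)) / σe².
```

The iterates are exactly the EM sequence; the decomposition is only a way of
evaluating them. Because EM's linear convergence can crawl when the
likelihood is nearly flat in h² (weakly identified designs, or a component
collapsing to the boundary σa² → 0), the EM fixed point is polished by a
derivative-free minimisation of the closed-form deviance (Nelder–Mead on log
variances; each evaluation is O(q)). Convergence is declared when the
relative parameter change (scaled by the total variance) falls below `tol`
(default 1e-8), or when the profiled deviance is stationary and the
scale-invariant score `|σᵢ² ∂ℓ/∂σᵢ²|/n < 1e-6`. Estimates at the boundary are
returned as very small positive variances.

`method="ai"` replaces the bulk of the EM iterations by Newton steps using
the average-information matrix `AIᵢⱼ = ½ y′P V̇ᵢ P V̇ⱼ P y` (three EM warm-up
steps, step-halving to stay positive). Standard errors of σa², σe² and — by
the delta method — h² come from the inverse AI matrix at the optimum; under
plain EM they are reported as not available. A model object caches the
decomposition, so repeated fits on re-drawn phenotypes over a fixed design
(`model.refit(y)`) cost O(q²) per fit instead of a fresh eigendecomposition;
this is what the parameter-recovery experiment uses.

GEBVs solve Henderson's mixed-model equations; the standalone
`assemble_mme`/`solve_mme` path uses a sparse direct factorisation and
verifies the relative residual to 1e-8 (raising a diagnostic error
otherwise). The spectral path and the sparse path agree to solver precision
and are cross-checked in the tests against a dense textbook implementation.

## Iterative SNP weighting and window variances

Iteration 1 uses D = I, so a one-iteration run is plain (unweighted)
single-step GWAS. Each iteration rebuilds G from the current weights, refits
GEBVs, back-solves `û = λDZ′G⁻¹â_g`, updates `dᵢ = ûᵢ²·2pᵢ(1−pᵢ)` and rescales
D so its trace stays at the SNP count M (keeping the total marker variance
constant; the starting trace is M since D(1)=I). Three iterations is the
default. Variance components are estimated once (under D = I) and held fixed
across iterations — re-estimating each round would fight the trace
normalisation, whose purpose is to keep the total genetic variance constant.
No weight flooring is applied at three iterations; a floor is exposed as an
option for longer runs, where small weights would otherwise become absorbing.

Window variances use sliding windows of 20 consecutive SNPs (step 1),
restricted within chromosomes; a chromosome shorter than the window is
skipped with a warning. The per-window statistic is the sample variance
(n−1 denominator) across genotyped animals of the window's genetic value,
divided by the REML σa², as a percentage. The n−1 choice is the unbiased
default for an empirical variance; it is visible in the configuration.
Selection keeps windows above 1% and collapses each chain of overlapping
selected windows to its local maximum, which yields one row per region as in
published window tables. The top SNP of a window is the argmax of the per-SNP
variance contribution `ûⱼ²·2pⱼ(1−pⱼ)` with ties broken by lower bp position;
an alternative reading of "top SNP" (the marker contributing most evenly to
the window) exists in the literature, but the argmax definition is
deterministic and matches the convention that the top SNP "explains the
largest proportion" of the window variance. Cross-trait reporting counts
regions with identical (chromosome, start, end) once; overlapping but
unequal regions from different traits stay separate.

## Synthetic data

The generator emulates the data structure the analysis assumes, not any
particular cattle population:

* **Pedigree** — discrete non-overlapping generations, random male×female
  pairing, alternating offspring sex (exactly balanced sex ratio), no
  selection, migration or mutation. Defaults (80 founders, 3 generations,
  8 offspring per mating) give ~10³ animals; the acceptance experiments use
  ~2100 with the youngest 2000 phenotyped, mirroring recording schemes in
  which ancestors lack records.
* **Genotypes** — founder haplotypes are Bernoulli draws at per-SNP
  frequencies uniform on (0.05, 0.5]; gametes drop through the pedigree with
  a Markov crossover process per chromosome whose switch probability between
  adjacent SNPs is the Haldane map function r = (1−e^(−2d))/2 — no
  interference, closed-form testable. SNPs are evenly spaced (1 cM laid out
  as 1 Mb); 5 chromosomes × 200 SNPs by default. Linkage-disequilibrium decay
  is therefore a free parameter of the map density, not calibrated to any
  real effective population size.
* **Phenotypes** — `y = fixed effects + QTL value + polygenic value +
  residual`. The additive variance σa² = h²σp² (σp² = 100 by default, h²
  defaulting to 0.42, within the 0.23–0.43 range typical of growth traits)
  is split between a configurable number of QTLs (chosen among panel SNPs,
  maskable from the analysed panel) and a pedigree polygenic term simulated
  by the Mendelian-sampling recursion with exact inbreeding adjustment. QTL
  effects are drawn N(0,1) and rescaled so the founder-generation variance of
  the QTL value hits its target — scaling to the base population is what
  makes REML (which estimates base-population variance) unbiased for the
  configured h². Fixed effects are categorical level shifts (sex contrast
  8, farm SD 5, year SD 3, use-type contrast 4 trait units) plus an age slope
  (0.5 units/day around 360 ± 30 d), magnitudes chosen so the fixed effects
  are material but do not dominate σp².

What passing tests on this generator do **not** show: realistic LD structure
or allele-frequency spectra, selection-induced trends (breeding values have
no generational trend here), genotyping error, or the scale of a 600k-SNP
panel. The pipeline's statistical properties (unbiased h² recovery, QTL
window enrichment under re-weighting, all algebraic identities) are what the
tests establish.

## Validation experiments and problem sizes

`wssgwas.experiments` contains the two built-in calibration experiments,
also used by `scripts/acceptance.py`:

* **Heritability recovery** — one pedigree of 2128 animals (304 founders,
  2 generations), 2000 phenotype records, 50 phenotype replicates per target
  h² ∈ {0.42, 0.23} with the full fixed-effect model; covariate assignments
  are frozen across replicates so the cached decomposition is shared. The
  mean estimate stays within |bias| < 0.03 of the target (observed ≈ 0.001).
* **QTL rank improvement** — 20 replicates of a 1050-animal, 1000-SNP,
  all-genotyped design with one QTL carrying 30% of the additive variance;
  the gVar% rank of the QTL-containing window after one re-weighting
  iteration is compared with the unweighted rank. The rank improves or holds
  at 1 in ≥ 90% of replicates.

These sizes were chosen to exercise the estimators at realistic desk scale;
the same code paths run unchanged on larger inputs.

## Quality control conventions

Filter order is individuals first (call rate < 95% removed), then SNPs —
call rate, then minor allele frequency (strict `< 0.05` removes; exactly
0.05 is kept), then the two-sided exact Hardy–Weinberg test
(Wigginton-style "no more probable" rule, evaluated in log space; p < 1e-6
removes), then non-autosomal or unmapped positions. SNP statistics are
recomputed after individual removal, and MAF uses non-missing calls only;
the QC report records removals per step and the thresholds used, so runs are
self-describing. QC is idempotent. Phenotype screening removes records more
than 3 sample SDs from the trait mean in a single pass (no re-iteration),
on raw values before model fitting. Average daily gain is (yearling −
birth weight)/days with positive-days and missingness guards.

## Degenerate inputs and tie-breaks

Monomorphic SNPs are rejected at the allele-frequency boundary (they violate
the MAF-filter invariant). An empty genotyped set makes H⁻¹ = A⁻¹ exactly;
an all-genotyped set with A = A₂₂ makes H⁻¹ = G⁻¹ exactly. Equidistant genes
in annotation resolve to the smaller start coordinate; equal top-SNP
contributions resolve to the lower bp position; equal window peaks keep the
first (leftmost) window. LD r² is the squared Pearson correlation of dosages
over pairwise-complete animals (unphased composite estimator); pairs
involving a monomorphic SNP are reported missing.

## Known limitations

Single trait, additive effects only: no maternal or permanent-environment
effects, no multi-trait models, no metafounders or unknown-parent groups,
no marker-effect (ssSNP-BLUP) reformulation. Dense q×q decompositions bound
the practical pedigree size at a few tens of thousands on a workstation.
The published window tables bundled in `wssgwas.datasets` are inputs for
summary arithmetic; their gene distances depend on an external annotation
release and are format examples, not reproducible targets.
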