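# Methods

`wssgblup` implements a weighted single-step GBLUP association pipeline for a
univariate animal model, of the kind used to map QTL for carcass and
meat-quality traits in beef cattle where only part of a pedigreed population
is genotyped. This note records the model, the algorithmic and numerical
choices, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Model

Phenotypes follow the linear animal model

    y = Xβ + Za + e,   a ~ N(0, σ²_a H),   e ~ N(0, σ²_e I)

where β holds the fixed effects — an intercept, contemporary-group (CG)
indicators with the reference level absorbed into the intercept, and centered
linear and quadratic slaughter-age covariates — and a is the additive genetic
effect of every pedigree animal. H combines pedigree and genomic
relationships through its inverse,

    H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A₂₂⁻¹],

with the correction confined to the genotyped block. A⁻¹ is assembled
directly by Henderson's rules with inbreeding coefficients from the
Meuwissen–Luo recursion; A₂₂ is the genotyped submatrix of the tabular A.
The genomic relationship matrix is G = Z_c D Z_c' / Σ_j 2p_j(1−p_j), where
Z_c is gene content centered at observed allele frequencies among genotyped
animals (base-population frequencies are unavailable in practice; this is a
documented choice) and D is the diagonal SNP-weight matrix, initially I. G is
then (i) rescaled by a single factor q so that mean(diag(G)) equals
mean(diag(A₂₂)), and (ii) blended, G* = (1−ε)G + εA₂₂ with ε = 0.05 by
default, to guarantee invertibility — G built from finitely many SNPs with
frequencies estimated in the same sample is always singular (the centered
content annihilates the ones vector).

## Variance components: Gibbs sampler

σ²_a and σ²_e are estimated by single-site Gibbs sampling: every location
effect is drawn from its univariate normal full conditional in a fixed sweep
order (fixed effects, then animals in pedigree order), then σ²_a from the
scaled inverse-chi-square full conditional with quadratic form a'H⁻¹a and
σ²_e from the residual sum of squares. Priors on both variances default to
flat (ν = −2, S² = 0), the convention of animal-breeding Gibbs software;
proper scaled inverse-chi-square priors are available. The flat default
matters at the boundary: a proper inverse-chi-square with scale S² has
density ∝ exp(−νS²/2σ²) and therefore essentially no mass below ≈ S²/3, so
it cannot concentrate on σ²_a ≈ 0 when the data say so. Fixed effects get an
implicit uniform prior.

The sweep is compiled with numba over a CSR representation in which the
W'W part and the sparse part of H⁻¹ share one pattern, so changing the
variance ratio λ = σ²_e/σ²_a between sweeps costs one vector operation. The
dense genotyped-block correction G*⁻¹ − A₂₂⁻¹ is stored separately as a
contiguous float32 array: its rounding error (relative ~1e-7) is orders of
magnitude below Monte-Carlo noise, and the contiguous rows vectorize, which
is what makes the default chain practical on one core. A float64 sparse path
handles arbitrary H⁻¹ (and pedigree-only models).

Default chain: 50,000 sweeps, 5,000 burn-in, thinning 10 — a desk-scale
setting chosen so a ~1,500-animal fit takes tens of seconds; production-scale
chains (10⁶ sweeps, 80,000 burn-in, thinning 100) are a configuration choice.
Posterior summaries report mean, median, SD and the highest-posterior-density
(HPD) interval computed as the shortest interval containing ⌈mass·n⌉ sorted
samples. Convergence diagnostics: Geweke's z comparing first/last segment
means with batch-means spectral variances (⌈√n⌉ batches), and
Heidelberger–Welch's Cramér–von-Mises stationarity test on the Brownian
bridge of cumulative sums with iterative 10% prefix discarding, plus the
halfwidth test. h² = σ²_a/(σ²_a+σ²_e) is computed per posterior sample and
then summarized.

## Weighted ssGWAS loop

With variance components frozen at their posterior means, the loop is:

1. build G from the current D, tune, blend, form H⁻¹;
2. GEBVs for all animals from Henderson's mixed-model equations (direct
   dense solve; residual verified < 1e-8);
3. back-solve SNP effects û = D Z_c' [Z_c D Z_c']⁻¹ â_g;
4. weights d_i = û_i² · 2p_i(1−p_i);
5. normalize d so Σ d_i·2p_i(1−p_i) keeps its D = I value (total genetic
   variance constant);
6. repeat (default 2 iterations).

Because Z_c'1 = 0, the ZDZ' system is solved on the orthogonal complement of
the ones vector: â_g is centered to its mean and the kernel direction filled
with a rank-one ones block before the Cholesky factorization (on that
subspace this equals the pseudo-inverse). The GEBV mean over the genotyped
group is a base-population constant carrying no SNP information, so the
reconstruction identity Z_c û = â_g − mean(â_g) holds to machine precision at
every iteration. The back-solve deliberately uses the *unblended* ZDZ'
operator (the tuning factor q cancels algebraically) so this identity is
exact; blending enters only through the GEBVs. If ZDZ' is rank-deficient
beyond centering, a minimum-norm solution is attempted and an error raised
unless it still reproduces the GEBVs.

Windows are non-overlapping blocks of 10 map-consecutive SNPs within a
chromosome (trailing remainders are kept and flagged as short). A window's
share of additive variance is Var(Σ_j Z_j û_j)/σ²_a × 100, the empirical
(ddof = 1) variance over genotyped animals, with σ²_a the posterior mean from
the initial fit. Windows at or above 1% are selected as candidate QTL regions
and can be annotated against a local GFF3 (closed-interval overlap, strand
ignored, optional flank).

## Synthetic data

The generator emulates a genotyped-bull study design: a multi-generation
random-mating pedigree; biallelic SNPs on several autosomes gene-dropped from
founder frequencies ~ Uniform(0.1, 0.9) (chosen so QC retention is high);
phenotypes composed of CG effects, linear+quadratic age covariates, a
polygenic breeding value simulated by the pedigree recursion
child = (sire+dam)/2 + Mendelian deviation, optional major QTL acting through
true gene content, and Gaussian residuals. The realized TBV spread is
rescaled so the additive fraction hits the target h² exactly in-sample.
Missing genotype calls are injected at 1% by default; contemporary groups are
assigned round-robin with optional imbalance.

Deliberately not emulated: linkage disequilibrium (SNPs segregate
independently; no recombination map), selection, assortative mating, maternal
effects, genotyping error. Passing tests therefore demonstrate correctness of
the machinery and recovery under linkage equilibrium, not performance under
realistic LD — with LD, window variances spread across neighboring windows.

The reference validation study uses 300 founders plus two generations of 600
(1,500 animals, all phenotyped), 3,000 SNPs on 10 chromosomes, h² = 0.30, and
8 contemporary groups. For heritability recovery, 800 of the 1,500 animals
are genotyped; for QTL-window recovery all phenotyped animals are genotyped,
mirroring the design this package emulates, where genotyped animals outnumber
phenotyped records and QTL localization draws entirely on the genotyped set.
Variance components for the weighting-loop experiments come from a shorter
chain (10,000/1,000/10), a package default for these experiments.

## Numerical choices and degenerate inputs

* Matrices: A⁻¹ sparse CSR; A₂₂, G dense float64; H⁻¹ sparse with the dense
  correction embedded (or carried separately for the sampler's fast path).
* Symmetry is enforced by averaging after every matrix product; blending
  fails fast with advice if the blended G is still numerically singular.
* QC filter order is fixed and logged: excluded chromosome/unknown position,
  SNP call rate, monomorphic, MAF, heterozygosity excess, then sample call
  rate; each SNP is attributed to the first filter it fails. "Excess
  heterozygosity" is observed minus Hardy–Weinberg expected heterozygosity
  above 0.15 (no universal convention exists; configurable). Missing calls
  are mean-imputed (2p̂) after QC.
* CG outlier removal is single-pass, using the population SD (ddof = 0) of
  the pre-drop group, with records at or beyond 3 SD removed; zero-variance
  groups remove nothing.
* All-equal covariates (e.g. constant slaughter age) are dropped from X with
  a flag; phenotyped animals missing from the pedigree raise with their ids.
* Every stochastic routine takes an explicit seed and is reproducible
  draw-for-draw; the sampler's fast and generic paths differ only in float32
  rounding of the genomic correction.

## Known limitations

* The iterative SNP weighting is self-reinforcing: û at iteration 2 scales
  roughly like d·û₁ ∝ û₁³ per SNP, so the largest windows grow between
  iterations even on null data (in our null calibration the maximum window
  percentage grows several-fold from iteration 1 to 2). This is the known
  overfitting behavior of iterated weighting schemes and the reason the
  default stops at 2 iterations; window percentages from iteration ≥ 2
  should be read as a ranking signal, not as unbiased variance estimates.
* With ~1,500 animals, h² = 0.3 and QTL at 4% of genetic variance against a
  mostly polygenic (non-genomic) background, window recovery is
  power-limited: single-marker association on the same data cannot reliably
  rank all such QTL either. Larger cohorts or larger QTL sharpen recovery.
* The posterior SD of h² under the reference design is ≈ 0.03–0.04, so any
  single study's posterior mean can sit several hundredths from the
  simulation truth; this is sampling variability of the design, not
  estimator bias.
* A₂₂ is built from the dense tabular A (O(n²) memory), appropriate for
  desk-scale pedigrees (≲ 10⁴ animals), not national evaluations.
* G is tuned on the mean diagonal only; no separate offdiagonal/diagonal
  compatibility adjustment, no metafounders, no APY.
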