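"""Synthetic pedigree / genotype / phenotype generator.

Emulates the design of a genotyped-bull study: a multi-generation pedigree of
which only a subset is genotyped, biallelic SNPs on several autosomes
transmitted by gene dropping, and phenotypes built from a contemporary-group
effect, linear+quadratic slaughter-age covariates, a pedigree-correlated
polygenic value, optional major QTL, and residual noise.

The polygenic value is simulated by the recursive rule
``child = (sire + dam)/2 + Mendelian-sampling deviation`` rather than from
SNPs, so planted QTL windows are the only true genomic signal and recovery
tests have an unambiguous truth. SNPs are in linkage equilibrium (no
recombination map, no selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ConfigurationError, GenotypeMatrix, PedigreeTable, PhenotypeTable


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    ``qtl_spec`` lists ``(snp_index, fraction_of_genetic_variance)`` pairs;
    the remaining genetic variance is polygenic. ``h2`` is the narrow-sense
    heritability the realized additive fraction targets. Founder allele
    frequencies are drawn per SNP from Uniform(maf_low, maf_high).
    """

    n_founders: int = 100
    n_generations: int = 2
    offspring_per_mating: int = 2
    matings_per_generation: int | None = None  # default: n_founders // 2
    n_chromosomes: int = 5
    snps_per_chromosome: int = 200
    chrom_length_bp: int = 100_000_000
    prop_genotyped: float = 0.5
    h2: float = 0.3
    qtl_spec: list[tuple[int, float]] = field(default_factory=list)
    n_contemporary_groups: int = 5
    cg_imbalance: float = 0.0   # 0 = round-robin; >0 skews group sizes
    age_range: tuple[float, float] = (550.0, 730.0)
    maf_low: float = 0.1
    maf_high: float = 0.9
    missing_rate: float = 0.01
    cg_effect_sd: float = 1.0
    age_beta: tuple[float, float] = (0.01, -1e-5)  # linear, quadratic
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "offspring_per_mating",
                     "n_chromosomes", "snps_per_chromosome", "chrom_length_bp",
                     "n_contemporary_groups"):
            v = getattr(self, name)
            if name == "n_generations":
                if v < 0:
                    raise ConfigurationError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigurationError(f"h2 must be in [0, 1], got {self.h2}")
        if not 0.0 <= self.prop_genotyped <= 1.0:
            raise ConfigurationError("prop_genotyped must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        total = sum(f for _, f in self.qtl_spec)
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"QTL variance fractions sum to {total:.3f} > 1"
            )
        if any(f < 0 for _, f in self.qtl_spec):
            raise ConfigurationError("QTL variance fractions must be >= 0")
        if not (self.age_range[0] > 0 and self.age_range[1] >= self.age_range[0]):
            raise ConfigurationError("age_range must be positive and ordered")

    @property
    def n_matings(self) -> int:
        return (self.n_founders // 2 if self.matings_per_generation is None
                else self.matings_per_generation)

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


def simulate_pedigree(cfg: SimConfig) -> PedigreeTable:
    """Random-mating pedigree: founders, then per generation ``n_matings``
    sire/dam pairs from the previous generation, each producing
    ``offspring_per_mating`` offspring. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    animal: list[str] = [f"F{i + 1}" for i in range(cfg.n_founders)]
    sire: list[str] = ["0"] * cfg.n_founders
    dam: list[str] = ["0"] * cfg.n_founders
    prev = list(animal)
    for g in range(1, cfg.n_generations + 1):
        if len(prev) < 2:
            raise ConfigurationError(
                f"generation {g - 1} has {len(prev)} animals; cannot mate"
            )
        cur: list[str] = []
        for m in range(cfg.n_matings):
            s, d = rng.choice(len(prev), size=2, replace=False)
            for k in range(cfg.offspring_per_mating):
                child = f"G{g}_{m + 1}_{k + 1}"
                animal.append(child)
                sire.append(prev[s])
                dam.append(prev[d])
                cur.append(child)
        prev = cur
    return PedigreeTable(
        animal=np.array(animal, dtype=object),
        sire=np.array(sire, dtype=object),
        dam=np.array(dam, dtype=object),
    )


def drop_genotypes(ped: PedigreeTable, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop biallelic SNPs through the pedigree.

    Founder haplotypes are sampled from Hardy-Weinberg at per-SNP founder
    frequencies drawn from Uniform(maf_low, maf_high); each non-founder
    receives one allele from each parent by Mendelian transmission (a missing
    parent's allele is drawn from the founder frequency). A ``prop_genotyped``
    subset of animals is marked genotyped and, among those, calls are set
    missing at ``missing_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n, m = ped.n_animals, cfg.n_snps
    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)

    # paternal/maternal allele per animal x SNP (uint8 0/1)
    pat = np.empty((n, m), dtype=np.uint8)
    mat = np.empty((n, m), dtype=np.uint8)
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s == -1:
            pat[i] = rng.random(m) < freqs
        else:
            which = rng.integers(0, 2, size=m)
            pat[i] = np.where(which == 0, pat[s], mat[s])
        if d == -1:
            mat[i] = rng.random(m) < freqs
        else:
            which = rng.integers(0, 2, size=m)
            mat[i] = np.where(which == 0, pat[d], mat[d])
    calls = (pat + mat).astype(np.float64)

    n_geno = int(round(cfg.prop_genotyped * n))
    genotyped = np.zeros(n, dtype=bool)
    if n_geno > 0:
        # prefer later generations, as in real designs where young animals
        # are genotyped; fill with random earlier animals if needed
        order = np.arange(n)[::-1]
        genotyped[order[:n_geno]] = True
    if cfg.missing_rate > 0 and n_geno > 0:
        mask = rng.random((n, m)) < cfg.missing_rate
        mask[~genotyped] = False
        calls[mask] = np.nan

    chroms = np.repeat(
        [f"{c + 1}" for c in range(cfg.n_chromosomes)], cfg.snps_per_chromosome
    )
    positions = np.empty(m, dtype=np.int64)
    for c in range(cfg.n_chromosomes):
        lo, hi = c * cfg.snps_per_chromosome, (c + 1) * cfg.snps_per_chromosome
        pos = np.sort(
            rng.choice(cfg.chrom_length_bp, size=cfg.snps_per_chromosome,
                       replace=False)
        ) + 1
        positions[lo:hi] = pos
    snp_map = pd.DataFrame(
        {"snp_id": [f"snp{j + 1}" for j in range(m)],
         "chrom": chroms, "pos_bp": positions}
    )
    return GenotypeMatrix(
        calls=calls, animal_ids=ped.animal.copy(), snp_map=snp_map,
        genotyped=genotyped,
    )


def _polygenic_values(ped: PedigreeTable, sigma2: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Breeding values by pedigree recursion (no inbreeding adjustment of the
    Mendelian-sampling variance; random mating keeps inbreeding negligible)."""
    n = ped.n_animals
    a = np.zeros(n)
    if sigma2 <= 0:
        return a
    sd = np.sqrt(sigma2)
    z = rng.standard_normal(n)
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        mean = 0.0
        ms_var = 1.0
        if s != -1:
            mean += 0.5 * a[s]
            ms_var -= 0.25
        if d != -1:
            mean += 0.5 * a[d]
            ms_var -= 0.25
        a[i] = mean + z[i] * sd * np.sqrt(ms_var)
    return a


def simulate_phenotypes(ped: PedigreeTable, geno: GenotypeMatrix,
                        cfg: SimConfig) -> PhenotypeTable:
    """Phenotype = CG effect + beta1*age + beta2*age^2 + TBV + residual.

    TBV = polygenic value + QTL contributions from true gene content. Variance
    components are scaled to unit phenotypic variance: sigma2_a = h2 split
    between QTL (per ``qtl_spec`` fractions, using the realized gene-content
    variance) and polygenics; sigma2_e = 1 - h2. The realized TBV spread is
    rescaled to hit sigma2_a = h2 exactly in-sample. Truth is recorded on the
    returned table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = ped.n_animals
    sigma2_a = cfg.h2
    sigma2_e = 1.0 - cfg.h2

    qtl_frac = sum(f for _, f in cfg.qtl_spec)
    tbv = _polygenic_values(ped, sigma2_a * (1.0 - qtl_frac), rng)
    for snp_idx, frac in cfg.qtl_spec:
        content = geno.calls[:, snp_idx]
        if np.isnan(content).any():
            # QTL effects act through the true (pre-missingness) gene content;
            # impute the few masked calls at the column mean for the truth.
            content = np.where(np.isnan(content),
                               np.nanmean(content), content)
        v = content.var()
        if v <= 0:
            raise ConfigurationError(
                f"QTL SNP {snp_idx} is monomorphic in this pedigree"
            )
        beta = np.sqrt(frac * sigma2_a / v)
        tbv = tbv + beta * (content - content.mean())

    if sigma2_a > 0 and n > 1:
        dev = tbv - tbv.mean()
        realized = dev.var()
        if realized > 0:
            tbv = dev * np.sqrt(sigma2_a / realized)

    cg_weights = np.ones(cfg.n_contemporary_groups)
    if cfg.cg_imbalance > 0:
        cg_weights += cfg.cg_imbalance * np.arange(cfg.n_contemporary_groups)
    cg_weights /= cg_weights.sum()
    cg_of = np.repeat(np.arange(cfg.n_contemporary_groups),
                      np.diff(np.round(np.cumsum(cg_weights) * n).astype(int),
                              prepend=0))
    cg_of = np.resize(cg_of, n)
    rng.shuffle(cg_of)
    cg_effects = rng.normal(0.0, cfg.cg_effect_sd, size=cfg.n_contemporary_groups)

    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    b1, b2 = cfg.age_beta
    residual = rng.normal(0.0, np.sqrt(sigma2_e), size=n) if sigma2_e > 0 else np.zeros(n)

    y = cg_effects[cg_of] + b1 * age + b2 * age**2 + tbv + residual
    data = pd.DataFrame(
        {"animal_id": ped.animal,
         "trait_value": y,
         "contemporary_group": np.array([f"CG{c + 1}" for c in cg_of], dtype=object),
         "slaughter_age": age}
    )
    return PhenotypeTable(
        data=data,
        trait="sim_trait",
        true_breeding_values=pd.Series(tbv, index=ped.animal),
        true_variances={"sigma2_a": sigma2_a, "sigma2_e": sigma2_e,
                        "h2": cfg.h2, "qtl_spec": list(cfg.qtl_spec)},
    )


def simulate_study(cfg: SimConfig):
    """Convenience wrapper: pedigree + genotypes + phenotypes in one call."""
    ped = simulate_pedigree(cfg)
    geno = drop_genotypes(ped, cfg)
    phen = simulate_phenotypes(ped, geno, cfg)
    return ped, geno, phen
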