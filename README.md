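# wssgblup

Weighted single-step GBLUP genome-wide association (ssGWAS) for quantitative
traits in pedigreed populations where only a subset of animals is genotyped —
the typical situation in beef-cattle studies of carcass and meat-quality
traits such as the intramuscular fatty-acid profile.

The package is aimed at quantitative geneticists who want a tested,
desk-scale, fully scriptable implementation of the whole chain:

1. **Relationship matrices** — A⁻¹ by Henderson's rules with Meuwissen–Luo
   inbreeding, the genotyped submatrix A₂₂, the genomic matrix
   G = ZDZ′/Σ2pⱼ(1−pⱼ) with SNP weights D, tuning of mean(diag G) to
   mean(diag A₂₂), blending for invertibility, and

       H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹].

2. **Variance components** — the animal model y = Xβ + Za + e,
   a ~ N(0, σ²ₐH), fitted by a numba-compiled single-site Gibbs sampler
   (flat or scaled-inverse-χ² priors), with posterior summaries
   (mean, median, SD, HPD interval), Geweke and Heidelberger–Welch
   convergence diagnostics, and a direct mixed-model-equation solver as the
   exact inner engine.

3. **Weighted ssGWAS** — back-solving SNP effects from GEBVs,
   û = DZ′[ZDZ′]⁻¹â_g, iterative reweighting dᵢ = ûᵢ²·2pᵢ(1−pᵢ) with
   variance-conserving normalization, and the percentage of additive genetic
   variance explained by non-overlapping windows of 10 adjacent SNPs,
   Var(Σⱼ Zⱼûⱼ)/σ²ₐ × 100.

4. **QC, I/O and annotation** — the standard genotype filters (excluded
   chromosomes, call rate, monomorphic, MAF, heterozygosity excess, sample
   call rate), contemporary-group filters, PLINK .ped/.map and TSV readers
   and writers, window-to-gene annotation against a local GFF3, and
   Manhattan-ready exports.

5. **Synthetic data** — a first-class generator (pedigree, gene-dropped
   genotypes, phenotypes with contemporary groups, age covariates, planted
   QTL and a pedigree-recursive polygenic background) so every stage is
   testable without external data.

## Worked example

```python
import numpy as np
from wssgblup import (SimConfig, simulate_study, filter_snps, impute_missing,
                      filter_contemporary_groups, build_design_matrices,
                      build_relationships, gibbs_fit, posterior_summary,
                      run_weighted_iterations, centered_content,
                      window_variances, select_regions)

cfg = SimConfig(n_founders=300, n_generations=2, offspring_per_mating=2,
                matings_per_generation=300, n_chromosomes=10,
                snps_per_chromosome=300, prop_genotyped=1.0, h2=0.30,
                n_contemporary_groups=8,
                qtl_spec=[(c * 300 + 155, 0.04) for c in range(5)], seed=2)
ped, geno, phen = simulate_study(cfg)

geno, _ = filter_snps(geno)
geno = impute_missing(geno)
phen, _ = filter_contemporary_groups(phen)
y, X, Z, design = build_design_matrices(phen, None, ped)

rel = build_relationships(ped, geno)
fit = gibbs_fit(y, X, Z, rel, chain=(10_000, 1_000, 10, 2))
s = posterior_summary(fit.samples_h2)
print(f"h2: mean {s.mean:.3f}  95% HPD [{s.hpd_low:.3f}, {s.hpd_high:.3f}]")

s2a = fit.samples_sigma2_a.mean()
s2e = fit.samples_sigma2_e.mean()
sols = run_weighted_iterations(ped, geno, y, X, Z, s2a, s2e, n_iter=2)
Zc, _ = centered_content(geno)
report = window_variances(sols[-1].u_hat, Zc, s2a, geno.observed().snp_map)
top = select_regions(report, threshold_pct=1.0)
print(top[["chrom", "start_bp", "end_bp", "pct_variance"]].head())
```

Output (seed 2):

```
h2: mean 0.202  95% HPD [0.128, 0.272]
  chrom  start_bp    end_bp  pct_variance
0     2  50652557  52563496      2.686979
1     1  45279178  48679256      1.249922
2     5  55240954  58634585      1.226557
3     4  50349307  52469730      1.088211
```

Four of the five planted mid-chromosome QTL windows (one per chromosome 1–5,
each at 4% of the genetic variance) dominate the selection at the 1%
threshold after two weighting iterations. The h² posterior sits below the
simulated 0.30: the polygenic background is simulated along the pedigree
while the model measures the genotyped animals' resemblance through G, which
attenuates the estimate — see `docs/methods.md` for this and for the power
limits of window recovery at this cohort size.
`annotate_io.annotate_regions` can then overlap the selected windows with
genes from a GFF3 file.

The same pipeline is available from the shell:

```bash
wssgblup simulate --config sim.yaml --out data/ --seed 1
wssgblup qc --geno data/genotypes --pheno data/phenotypes.tsv --out qc/
wssgblup fit --ped data/pedigree.csv --geno qc/genotypes.qc \
             --pheno qc/phenotypes.qc.tsv --seed 1 --out fit/
wssgblup gwas --ped data/pedigree.csv --geno qc/genotypes.qc \
              --pheno qc/phenotypes.qc.tsv --sigma2-a 0.3 --sigma2-e 0.7 \
              --out gwas/
wssgblup annotate --regions gwas/selected_regions.tsv --gff3 genes.gff3 \
                  --out annotated.tsv
```

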