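"""Canonical validation experiments on synthetic data.

These functions define the package's reference study conditions — a
desk-scale emulation of a genotyped-bull association study (1,500 phenotyped
animals of which 800 genotyped, 3,000 SNPs on 10 chromosomes) — and run the
pipeline end to end on them: heritability recovery by Gibbs sampling,
QTL-window recovery by the weighted GWAS loop, and the loop's null
calibration. Both the test suite and the reproduction script call these, so
the numbers they report always come from the same computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinship, mme, qc, ssgwas, synthdata

#: desk-scale default chain (length, burn_in, thin); seed appended per run
DESK_CHAIN = (50_000, 5_000, 10)
#: shorter chain used to estimate variance components before a weighting loop
LOOP_CHAIN = (10_000, 1_000, 10)


def study_config(seed: int, **overrides) -> synthdata.SimConfig:
    """The reference study: 300 founders + 2 generations of 600 = 1,500
    animals, all phenotyped, the last 800 genotyped, 3,000 SNPs, h² = 0.30."""
    params = dict(
        n_founders=300, n_generations=2, offspring_per_mating=2,
        matings_per_generation=300, n_chromosomes=10,
        snps_per_chromosome=300, chrom_length_bp=100_000_000,
        prop_genotyped=800 / 1500, h2=0.30,
        n_contemporary_groups=8, seed=seed,
    )
    params.update(overrides)
    return synthdata.SimConfig(**params)


def _prepare(cfg: synthdata.SimConfig):
    ped, geno, phen = synthdata.simulate_study(cfg)
    geno_qc, _ = qc.filter_snps(geno)
    geno_qc = qc.impute_missing(geno_qc)
    phen_qc, _ = qc.filter_contemporary_groups(phen)
    y, X, Z, design = mme.build_design_matrices(phen_qc, None, ped)
    return ped, geno_qc, phen, y, X, Z


@dataclass
class HeritabilityRun:
    seed: int
    true_h2: float
    post_mean_h2: float
    post_median_h2: float
    hpd_low: float
    hpd_high: float
    covered: bool
    geweke_z: float


def heritability_recovery(seed: int, chain=DESK_CHAIN) -> HeritabilityRun:
    """Fit the reference study with the Gibbs sampler; summarize h²."""
    cfg = study_config(seed)
    ped, geno_qc, phen, y, X, Z = _prepare(cfg)
    rel = kinship.build_relationships(ped, geno_qc)
    fit = mme.gibbs_fit(y, X, Z, rel, chain=(*chain, seed))
    s = mme.posterior_summary(fit.samples_h2)
    return HeritabilityRun(
        seed=seed, true_h2=cfg.h2, post_mean_h2=s.mean,
        post_median_h2=s.median, hpd_low=s.hpd_low, hpd_high=s.hpd_high,
        covered=bool(s.hpd_low <= cfg.h2 <= s.hpd_high),
        geweke_z=mme.geweke_diag(fit.samples_h2),
    )


def default_qtl_spec(cfg: synthdata.SimConfig, n_qtl: int = 5,
                     frac: float = 0.04) -> list[tuple[int, float]]:
    """One QTL per chromosome (first ``n_qtl``), mid-chromosome, each
    explaining ``frac`` of the genetic variance."""
    m = cfg.snps_per_chromosome
    return [(c * m + m // 2 + 5, frac) for c in range(n_qtl)]


@dataclass
class QtlRecoveryRun:
    seed: int
    qtl_windows: list[int]          # window ordinals holding a QTL
    qtl_pcts: list[float]           # their % variance at the last iteration
    qtl_ranks: list[int]            # 1-based rank among all windows
    n_selected: int
    all_above_threshold: bool
    all_in_top10: bool
    backsolve_residual: float
    weight_sum_error: float


def qtl_recovery(seed: int, n_qtl: int = 5, frac: float = 0.04,
                 n_iter: int = 2, threshold_pct: float = 1.0,
                 chain=LOOP_CHAIN) -> QtlRecoveryRun:
    """Plant QTL, run the weighted GWAS loop, and rank the QTL windows.

    All phenotyped animals are genotyped here, mirroring the design this
    package emulates (more genotyped animals than phenotyped records); QTL
    localization draws its information from the genotyped set.
    """
    cfg = study_config(seed)
    cfg = study_config(seed, prop_genotyped=1.0,
                       qtl_spec=default_qtl_spec(cfg, n_qtl, frac))
    ped, geno_qc, phen, y, X, Z = _prepare(cfg)
    rel = kinship.build_relationships(ped, geno_qc)
    fit = mme.gibbs_fit(y, X, Z, rel, chain=(*chain, seed))
    s2a = float(fit.samples_sigma2_a.mean())
    s2e = float(fit.samples_sigma2_e.mean())
    sols = ssgwas.run_weighted_iterations(ped, geno_qc, y, X, Z, s2a, s2e,
                                          n_iter=n_iter)
    final = sols[-1]
    Zc, p = ssgwas.centered_content(geno_qc)
    snp_map = geno_qc.observed().snp_map
    report = ssgwas.window_variances(final.u_hat, Zc, s2a, snp_map)

    qtl_ids = {f"snp{i + 1}" for i, _ in cfg.qtl_spec}
    qtl_windows = []
    for w, row in report.iterrows():
        lo = snp_map.index[snp_map.snp_id == row["first_snp"]][0]
        hi = snp_map.index[snp_map.snp_id == row["last_snp"]][0]
        if qtl_ids & set(snp_map.loc[lo:hi, "snp_id"]):
            qtl_windows.append(int(row["window"]))
    ranks_all = report["pct_variance"].rank(ascending=False, method="min")
    qtl_pcts = [float(report.loc[report.window == wdx, "pct_variance"].iloc[0])
                for wdx in qtl_windows]
    qtl_ranks = [int(ranks_all[report.window == wdx].iloc[0])
                 for wdx in qtl_windows]
    selected = ssgwas.select_regions(report, threshold_pct)
    het = 2.0 * final.p * (1.0 - final.p)
    wsum_err = abs(float(final.d @ het) - float(het.sum()))
    return QtlRecoveryRun(
        seed=seed, qtl_windows=qtl_windows, qtl_pcts=qtl_pcts,
        qtl_ranks=qtl_ranks, n_selected=len(selected),
        all_above_threshold=bool(len(qtl_windows) == n_qtl
                                 and min(qtl_pcts) >= threshold_pct),
        all_in_top10=bool(len(qtl_windows) == n_qtl
                          and max(qtl_ranks) <= 10),
        backsolve_residual=max(s.backsolve_residual for s in sols),
        weight_sum_error=wsum_err,
    )


def null_weighting(seed: int, n_iter: int = 2) -> tuple[float, float]:
    """Max window %-variance at iterations 1 and 2 with no planted QTL.

    Runs at a smaller scale (600 animals, 300 genotyped, 1,000 SNPs) with the
    true variance components, which isolates the weighting loop itself.
    """
    cfg = study_config(
        seed, n_founders=120, matings_per_generation=120,
        n_chromosomes=5, snps_per_chromosome=200, prop_genotyped=0.5,
    )
    ped, geno_qc, phen, y, X, Z = _prepare(cfg)
    s2a = phen.true_variances["sigma2_a"]
    s2e = phen.true_variances["sigma2_e"]
    sols = ssgwas.run_weighted_iterations(ped, geno_qc, y, X, Z, s2a, s2e,
                                          n_iter=n_iter)
    Zc, _ = ssgwas.centered_content(geno_qc)
    snp_map = geno_qc.observed().snp_map
    maxes = []
    for sol in (sols[0], sols[-1]):
        rep = ssgwas.window_variances(sol.u_hat, Zc, s2a, snp_map)
        maxes.append(float(rep["pct_variance"].max()))
    return maxes[0], maxes[1]


def pedigree_limit_check(seed: int = 0) -> dict:
    """With zero genotyped animals H⁻¹ must equal A⁻¹ and GEBVs must match a
    pedigree-only BLUP; returns the two max errors."""
    cfg = study_config(seed, n_founders=60, matings_per_generation=60,
                       n_chromosomes=2, snps_per_chromosome=50,
                       prop_genotyped=0.0, missing_rate=0.0)
    ped, geno, phen = synthdata.simulate_study(cfg)
    phen_qc, _ = qc.filter_contemporary_groups(phen)
    y, X, Z, _ = mme.build_design_matrices(phen_qc, None, ped)
    a_inv = kinship.build_A_inverse(ped)
    h_inv = kinship.build_H_inverse(
        a_inv, np.zeros((0, 0)), np.zeros((0, 0)), np.array([], dtype=int))
    diff = (h_inv - a_inv).tocoo()
    h_err = float(np.abs(diff.data).max()) if diff.nnz else 0.0
    s2a, s2e = 0.3, 0.7
    _, a_h = mme.mme_solve(y, X, Z, h_inv, s2a, s2e)
    # independent oracle: dense normal equations with the inverted tabular A
    A = kinship.tabular_A(ped)
    Ainv = np.linalg.inv(A)
    Xd, Zd = X, Z.toarray()
    lam = s2e / s2a
    p = Xd.shape[1]
    lhs = np.block([[Xd.T @ Xd, Xd.T @ Zd],
                    [Zd.T @ Xd, Zd.T @ Zd + lam * Ainv]])
    rhs = np.concatenate([Xd.T @ y, Zd.T @ y])
    a_oracle = np.linalg.solve(lhs, rhs)[p:]
    return {"h_vs_a_max_abs": h_err,
            "gebv_max_abs_diff": float(np.abs(a_h - a_oracle).max())}
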