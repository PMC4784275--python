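"""Weighted single-step GWAS: SNP effects from GEBVs, iterative reweighting,
and 10-SNP-window variance decomposition.

The loop (weights start at D = I):

1. build G = ZDZ'q from current weights, tune to A₂₂, blend, form H⁻¹;
2. compute GEBVs for the whole pedigree with the direct MME solver;
3. back-solve SNP effects  û = D Z' [Z D Z']⁻¹ â_g;
4. reweight  d_i = û_i² · 2p_i(1−p_i);
5. normalize so Σ d_i·2p_i(1−p_i) keeps its D = I value (total genetic
   variance constant);
6. repeat.

The back-solve inverts the *unblended* ZDZ' so the identity Z·û = â_g holds
to machine precision (the tuning factor q cancels algebraically in
D Z' q [Z D Z' q]⁻¹). H⁻¹ itself uses the tuned and blended G. Variance
components are estimated once and held fixed across iterations.

Windows are non-overlapping blocks of ``window_size`` map-consecutive SNPs
within a chromosome; a trailing remainder is kept as a short window and
flagged. A window's share of additive variance is the empirical variance,
across genotyped animals, of its genetic value a_i = Σ_j Z_j û_j, divided by
σ²_a, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from . import kinship, mme
from .types import GenotypeMatrix, PedigreeTable


@dataclass
class SnpSolution:
    """Per-SNP effects and the weights that produced them (one iteration)."""

    u_hat: np.ndarray        # effect per SNP, trait units per A1 allele
    d: np.ndarray            # weights used to compute u_hat
    p: np.ndarray            # allele frequencies
    iteration: int
    gebv_genotyped: np.ndarray
    backsolve_residual: float

    def __post_init__(self) -> None:
        if not (len(self.u_hat) == len(self.d) == len(self.p)):
            raise ValueError("u_hat, d and p must have equal length")
        if (self.d < 0).any():
            raise ValueError("weights must be nonnegative")


def backsolve_snp_effects(a_g_hat: np.ndarray, Z: np.ndarray,
                          D: np.ndarray | None = None) -> np.ndarray:
    """û = D Z' [Z D Z']⁻¹ â_g  (so Z·û reproduces â_g exactly).

    Z is the gene content of the genotyped animals (animals x SNPs), normally
    centered at the observed allele frequencies; D a nonnegative per-SNP
    weight vector (defaults to ones).

    When Z is column-centered, ZDZ' annihilates the ones vector by
    construction (Z'1 = 0), so the system is solved on the orthogonal
    complement of 1: â_g is centered to its mean and the kernel direction is
    filled with a rank-one ones-block before factorizing. On that subspace
    the augmented inverse coincides with the pseudo-inverse, hence
    Z·û = â_g − mean(â_g)·1 to machine precision — the GEBV mean over the
    genotyped group is a base-population constant that carries no SNP
    information. For a non-centered, full-rank Z the plain inverse is used
    and Z·û = â_g exactly.
    """
    n, m = Z.shape
    d = np.ones(m) if D is None else np.asarray(D, dtype=float)
    if (d < 0).any():
        raise ValueError("weights must be nonnegative")
    ZD = Z * d
    K = ZD @ Z.T
    centered = float(np.abs(Z.sum(axis=0)).max()) <= 1e-8 * max(1.0, n)
    rhs = np.asarray(a_g_hat, dtype=float)
    if centered:
        rhs = rhs - rhs.mean()
        K_solve = K + float(np.mean(np.diag(K))) * np.ones((n, n)) / n
    else:
        K_solve = K
    try:
        c, low = scipy.linalg.cho_factor(K_solve)
        alpha = scipy.linalg.cho_solve((c, low), rhs)
    except np.linalg.LinAlgError:
        # rank-deficient beyond centering: minimum-norm (pseudo-inverse)
        # solution, accepted only if it still reproduces the GEBVs
        alpha = np.linalg.pinv(K) @ rhs
        scale = float(np.abs(rhs).max()) or 1.0
        if np.abs(K @ alpha - rhs).max() > 1e-6 * scale:
            raise np.linalg.LinAlgError(
                "ZDZ' singular and GEBVs not reproducible from it; too few "
                "SNPs with nonzero weight — use a blended genomic operator "
                "or revisit the weights"
            ) from None
    return ZD.T @ alpha


def snp_weights(u_hat: np.ndarray, p: np.ndarray) -> np.ndarray:
    """d_i = û_i² · 2p_i(1−p_i)."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("allele frequencies must be strictly inside (0, 1)")
    return np.asarray(u_hat) ** 2 * 2.0 * p * (1.0 - p)


def normalize_weights(d: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Rescale d so Σ d_i·2p_i(1−p_i) equals its D = I value Σ 2p_i(1−p_i)."""
    d = np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    het = 2.0 * p * (1.0 - p)
    denom = float(d @ het)
    if denom <= 0.0:
        raise ValueError("all SNP weights are zero; cannot normalize")
    return d * (float(het.sum()) / denom)


def centered_content(geno: GenotypeMatrix,
                     allele_freqs: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Z = calls − 2p for the genotyped animals; returns (Z, p)."""
    obs = geno.observed()
    if np.isnan(obs.calls).any():
        raise ValueError("impute missing calls before the GWAS loop")
    p = obs.calls.mean(axis=0) / 2.0 if allele_freqs is None else allele_freqs
    return obs.calls - 2.0 * p, p


def run_weighted_iterations(ped: PedigreeTable, geno: GenotypeMatrix,
                            y: np.ndarray, X: np.ndarray,
                            Z_incidence, sigma2_a: float, sigma2_e: float,
                            n_iter: int = 2,
                            blend_epsilon: float = 0.05
                            ) -> list[SnpSolution]:
    """Run ``n_iter`` weighting rounds; returns the solution trajectory.

    Variance components are held fixed. Iteration 1 uses D = I, so its
    back-solve is the plain (unweighted) ssGBLUP solution. Deterministic.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    Zc, p = centered_content(geno)
    d = np.ones(geno.observed().n_snps)
    out: list[SnpSolution] = []
    for it in range(1, n_iter + 1):
        try:
            rel = kinship.build_relationships(
                ped, geno, weights_D=d, blend_epsilon=blend_epsilon,
                allele_freqs=p,
            )
            _, a_hat = mme.mme_solve(
                y, X, Z_incidence, rel.h_inv, sigma2_a, sigma2_e
            )
            a_g = a_hat[rel.genotyped_index]
            a_g = a_g - a_g.mean()  # SNP-attributable component (see backsolve)
            u_hat = backsolve_snp_effects(a_g, Zc, d)
        except Exception as exc:
            raise RuntimeError(
                f"weighting iteration {it} failed: {exc}"
            ) from exc
        resid = float(np.abs(Zc @ u_hat - a_g).max())
        out.append(SnpSolution(
            u_hat=u_hat, d=d.copy(), p=p, iteration=it,
            gebv_genotyped=a_g, backsolve_residual=resid,
        ))
        d = normalize_weights(snp_weights(u_hat, p), p)
    return out


def window_variances(u_hat: np.ndarray, Z: np.ndarray, sigma2_a: float,
                     snp_map: pd.DataFrame, window_size: int = 10
                     ) -> pd.DataFrame:
    """Percent of additive variance per non-overlapping SNP window.

    Returns one row per window: ordinal, chrom, first/last snp_id and bp,
    n_snps (``window_size``, or fewer in a flagged trailing remainder) and
    pct_variance = Var(Σ_j Z_j û_j) / σ²_a × 100 across genotyped animals.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    u_hat = np.asarray(u_hat, dtype=float)
    rows = []
    ordinal = 0
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for start in range(0, len(idx), window_size):
            block = idx[start:start + window_size]
            a_i = Z[:, block] @ u_hat[block]
            pct = float(a_i.var(ddof=1) / sigma2_a * 100.0)
            rows.append({
                "window": ordinal,
                "chrom": chrom,
                "first_snp": grp.loc[block[0], "snp_id"],
                "last_snp": grp.loc[block[-1], "snp_id"],
                "start_bp": int(grp.loc[block[0], "pos_bp"]),
                "end_bp": int(grp.loc[block[-1], "pos_bp"]),
                "n_snps": len(block),
                "short_window": len(block) < window_size,
                "pct_variance": pct,
            })
            ordinal += 1
    return pd.DataFrame(rows)


def select_regions(report: pd.DataFrame, threshold_pct: float = 1.0
                   ) -> pd.DataFrame:
    """Windows with pct_variance ≥ threshold, sorted by pct descending
    (ties by chromosome then position)."""
    sel = report[report["pct_variance"] >= threshold_pct]
    return sel.sort_values(
        ["pct_variance", "chrom", "start_bp"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
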