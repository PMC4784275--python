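"""Pedigree and genomic relationship matrices for single-step GBLUP.

Builds A⁻¹ by Henderson's rules with inbreeding coefficients from the
Meuwissen-Luo recursion, the genotyped-animal submatrix A₂₂ by the tabular
method, the genomic relationship matrix G = ZDZ' / Σ2p(1-p) from gene content
centered at observed allele frequencies, a multiplicative tuning factor q that
matches mean(diag(G)) to mean(diag(A₂₂)), a blending step
G* = (1-ε)G + εA₂₂ for invertibility, and finally

    H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ - A₂₂⁻¹]

with the correction added into the genotyped block. A⁻¹ is stored sparse;
G, A₂₂ and the correction are dense (desk-scale cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .types import GenotypeMatrix, PedigreeTable


def inbreeding_coefficients(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficient per animal (Meuwissen & Luo recursion).

    Works on the L'DL decomposition of A: F_i = diag(A)_i - 1, with each
    diagonal accumulated by walking the ancestor list of animal i.
    """
    import heapq

    n = ped.n_animals
    f = np.zeros(n)           # inbreeding
    d = np.zeros(n)           # within-family (Mendelian sampling) variance
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, dd = sire[i], dam[i]
        d[i] = 0.5 - 0.25 * ((f[s] if s != -1 else -1.0)
                             + (f[dd] if dd != -1 else -1.0))
        if s == -1 and dd == -1:
            f[i] = 0.0
            continue
        # a_ii = Σ_j L_ij² d_j over ancestors j, visited in decreasing index
        # order so every child contribution lands before a parent is popped
        coeff = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            c = coeff[j]
            aii += c * c * d[j]
            for par in (sire[j], dam[j]):
                if par != -1:
                    if par not in coeff:
                        coeff[par] = 0.0
                        heapq.heappush(heap, -par)
                    coeff[par] += 0.5 * c
        f[i] = aii - 1.0
    return f


def tabular_A(ped: PedigreeTable) -> np.ndarray:
    """Full numerator relationship matrix by the tabular method (dense).

    O(n²) memory — intended as the oracle for A⁻¹/A₂₂ and for desk-scale
    pedigrees, which is all this package targets.
    """
    n = ped.n_animals
    A = np.zeros((n, n))
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s != -1 and d != -1) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        rel = np.zeros(i)
        if s != -1:
            rel += 0.5 * A[s, :i]
        if d != -1:
            rel += 0.5 * A[d, :i]
        A[i, :i] = rel
        A[:i, i] = rel
    return A


def build_A_inverse(ped: PedigreeTable) -> sp.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    For each animal the Mendelian-sampling precision
    m_i = 1 / (0.5 - 0.25(F_s + F_d)) (missing parents contribute F = -1)
    is scattered over the (animal, sire, dam) triplet.
    """
    n = ped.n_animals
    f = inbreeding_coefficients(ped)
    sire, dam = ped.sire_idx, ped.dam_idx
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = sire[i], dam[i]
        fs = f[s] if s != -1 else -1.0
        fd = f[d] if d != -1 else -1.0
        m = 1.0 / (0.5 - 0.25 * (fs + fd))
        entries = [(i, 1.0)]
        if s != -1:
            entries.append((s, -0.5))
        if d != -1:
            entries.append((d, -0.5))
        for (j, cj) in entries:
            for (k, ck) in entries:
                rows.append(j)
                cols.append(k)
                vals.append(m * cj * ck)
    return sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )


def build_A22(ped: PedigreeTable, genotyped_ids) -> np.ndarray:
    """Numerator relationships among the genotyped animals.

    Equals the genotyped rows/columns of the tabular A; computed by running
    the tabular recursion and slicing (the pedigrees here are desk-scale).
    """
    idx = ped.index_of(genotyped_ids)
    A = tabular_A(ped)
    return A[np.ix_(idx, idx)]


class MonomorphicSnpError(ValueError):
    """G cannot be built from monomorphic columns; run QC first."""


def build_raw_G(geno: GenotypeMatrix, weights_D: np.ndarray | None = None,
                allele_freqs: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """G = Z diag(D) Z' / Σ_j 2p_j(1-p_j), Z = calls - 2p.

    Uses the genotyped animals only; missing calls must already be imputed.
    Returns (G_raw, allele_freqs). Pass ``allele_freqs`` to reuse frequencies
    across weighting iterations (the base scale factor must not drift).
    """
    obs = geno.observed()
    calls = obs.calls
    if np.isnan(calls).any():
        raise ValueError("missing calls present; impute after QC first")
    p = calls.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise MonomorphicSnpError(
            "monomorphic SNP encountered (p in {0,1}); apply QC before G"
        )
    m = calls.shape[1]
    d = np.ones(m) if weights_D is None else np.asarray(weights_D, dtype=float)
    if d.shape != (m,) or (d < 0).any():
        raise ValueError("weights_D must be a nonnegative vector, one per SNP")
    Z = calls - 2.0 * p
    scale = float(np.sum(2.0 * p * (1.0 - p)))
    G = (Z * d) @ Z.T / scale
    return 0.5 * (G + G.T), p


def tune_G(g_raw: np.ndarray, a22: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale G so its mean diagonal equals that of A₂₂; returns (G_tuned, q)."""
    if g_raw.shape != a22.shape:
        raise ValueError("G and A22 dimensions differ")
    md = float(np.mean(np.diag(g_raw)))
    if md == 0.0:
        raise ValueError("mean diagonal of raw G is zero; cannot tune")
    q = float(np.mean(np.diag(a22))) / md
    return g_raw * q, q


def blend_G(g_tuned: np.ndarray, a22: np.ndarray, epsilon: float = 0.05
            ) -> np.ndarray:
    """G* = (1-ε)·G_tuned + ε·A₂₂, for numerical invertibility of G."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    g = (1.0 - epsilon) * g_tuned + epsilon * a22
    # fail early with advice rather than downstream in the solver
    eigmin = float(np.linalg.eigvalsh(g)[0])
    if eigmin <= 1e-10 * max(1.0, float(np.mean(np.diag(g)))):
        raise np.linalg.LinAlgError(
            f"blended G numerically singular (min eigenvalue {eigmin:.3e}); "
            "increase the blending epsilon"
        )
    return g


def build_H_inverse(a_inv: sp.spmatrix, a22: np.ndarray, g_final: np.ndarray,
                    genotyped_index: np.ndarray) -> sp.csr_matrix:
    """H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ - A₂₂⁻¹], correction in the genotyped block.

    ``genotyped_index`` gives the positions of the genotyped animals within
    the full pedigree ordering. Returned sparse (the genotyped block is dense
    inside the sparse container).
    """
    n = a_inv.shape[0]
    k = len(genotyped_index)
    if a22.shape != (k, k) or g_final.shape != (k, k):
        raise ValueError("A22/G dimensions do not match the genotyped index")
    if k == 0:
        return sp.csr_matrix(a_inv.copy())
    corr = np.linalg.inv(g_final) - np.linalg.inv(a22)
    corr = 0.5 * (corr + corr.T)
    ix = np.asarray(genotyped_index, dtype=np.int64)
    block = sp.coo_matrix(
        (corr.ravel(), (np.repeat(ix, k), np.tile(ix, k))), shape=(n, n)
    )
    return (sp.csr_matrix(a_inv) + block.tocsr()).tocsr()


@dataclass
class RelationshipSet:
    """All matrices one ssGBLUP evaluation needs, with their bookkeeping."""

    a_inv: sp.csr_matrix
    a22: np.ndarray
    g_raw: np.ndarray
    g_tuned: np.ndarray
    g_final: np.ndarray
    h_inv: sp.csr_matrix
    allele_freqs: np.ndarray
    tuning_factor: float
    blend_epsilon: float
    genotyped_index: np.ndarray
    genotyped_ids: np.ndarray


def build_relationships(ped: PedigreeTable, geno: GenotypeMatrix,
                        weights_D: np.ndarray | None = None,
                        blend_epsilon: float = 0.05,
                        allele_freqs: np.ndarray | None = None
                        ) -> RelationshipSet:
    """One-call pipeline: A⁻¹, A₂₂, raw/tuned/blended G, H⁻¹."""
    obs = geno.observed()
    a_inv = build_A_inverse(ped)
    a22 = build_A22(ped, obs.animal_ids)
    g_raw, p = build_raw_G(geno, weights_D=weights_D, allele_freqs=allele_freqs)
    g_tuned, q = tune_G(g_raw, a22)
    g_final = blend_G(g_tuned, a22, blend_epsilon)
    gen_index = ped.index_of(obs.animal_ids)
    h_inv = build_H_inverse(a_inv, a22, g_final, gen_index)
    return RelationshipSet(
        a_inv=a_inv, a22=a22, g_raw=g_raw, g_tuned=g_tuned, g_final=g_final,
        h_inv=h_inv, allele_freqs=p, tuning_factor=q,
        blend_epsilon=blend_epsilon, genotyped_index=gen_index,
        genotyped_ids=obs.animal_ids,
    )
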