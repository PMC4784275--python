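"""Univariate animal model y = Xβ + Za + e.

Two fitting routes share the same design matrices:

* :func:`mme_solve` — Henderson's mixed-model equations with H⁻¹, solved
  directly. Used as the inner engine of the SNP-weighting loop and as an
  exact oracle for the sampler.
* :func:`gibbs_fit` — single-site Gibbs sampler. Location effects are drawn
  from their normal full conditionals; σ²_a and σ²_e from scaled
  inverse-chi-square full conditionals (flat prior on β, scaled inverse
  chi-square priors on the variances — the univariate case of an inverted
  Wishart). The sweep is compiled with numba over a shared CSR pattern so the
  variance-ratio rescaling of the coefficient matrix is a vector operation.

Fixed effects are an intercept, contemporary-group indicators (reference
level absorbed into the intercept), and centered linear + quadratic
slaughter-age covariates. Posterior summaries report mean, median, SD and the
shortest (highest-posterior-density) interval; Geweke and Heidelberger-Welch
diagnostics check chain convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from .types import PedigreeTable, PhenotypeTable


@dataclass
class ModelSpec:
    """Fixed-effect layout of the animal model."""

    trait: str = "trait"
    contemporary_group: str = "contemporary_group"
    age: str = "slaughter_age"
    quadratic_age: bool = True


@dataclass
class DesignInfo:
    """Column bookkeeping for X (used to label solutions)."""

    columns: list[str]
    dropped_columns: list[str]
    cg_levels: list[str]


def build_design_matrices(phen: PhenotypeTable, spec: ModelSpec | None,
                          ped: PedigreeTable
                          ) -> tuple[np.ndarray, np.ndarray, sp.csr_matrix, DesignInfo]:
    """Assemble y, X and the record->animal incidence matrix Z.

    X columns: intercept, CG indicators for all but the first level, centered
    age, centered age². Age columns that are identically zero after centering
    (all ages equal) are flagged and dropped. Errors if any phenotyped animal
    is missing from the pedigree.
    """
    spec = spec or ModelSpec()
    df = phen.data
    known = set(ped.animal)
    missing = [a for a in df["animal_id"] if a not in known]
    if missing:
        raise ValueError(
            f"{len(missing)} phenotyped animals absent from pedigree: "
            f"{missing[:10]}"
        )
    y = df["trait_value"].to_numpy(dtype=float)
    n = len(df)

    cg = df[spec.contemporary_group].astype(str)
    levels = sorted(cg.unique())
    cols = [np.ones(n)]
    names = ["intercept"]
    for lev in levels[1:]:
        cols.append((cg == lev).to_numpy(dtype=float))
        names.append(f"cg[{lev}]")
    age = df[spec.age].to_numpy(dtype=float)
    age_c = age - age.mean()
    candidates = [(f"{spec.age}_c", age_c)]
    if spec.quadratic_age:
        age2 = age**2
        candidates.append((f"{spec.age}2_c", age2 - age2.mean()))
    dropped = []
    for name, col in candidates:
        if np.allclose(col, 0.0):
            dropped.append(name)
        else:
            cols.append(col)
            names.append(name)
    X = np.column_stack(cols)

    rec_animal = ped.index_of(df["animal_id"])
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), rec_animal)), shape=(n, ped.n_animals)
    )
    return y, X, Z, DesignInfo(columns=names, dropped_columns=dropped,
                               cg_levels=levels)


def mme_solve(y: np.ndarray, X: np.ndarray, Z: sp.spmatrix,
              h_inv: sp.spmatrix, sigma2_a: float, sigma2_e: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Solve Henderson's MME: [X'X X'Z; Z'X Z'Z + λH⁻¹][β;â] = [X'y; Z'y].

    λ = σ²_e/σ²_a. Dense symmetric solve; verifies the linear-system residual
    to 1e-8 and raises on a singular left-hand side.
    """
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    lam = sigma2_e / sigma2_a
    Zd = Z.toarray() if sp.issparse(Z) else np.asarray(Z)
    p, q = X.shape[1], Zd.shape[1]
    lhs = np.empty((p + q, p + q))
    lhs[:p, :p] = X.T @ X
    lhs[:p, p:] = X.T @ Zd
    lhs[p:, :p] = lhs[:p, p:].T
    lhs[p:, p:] = Zd.T @ Zd + lam * h_inv.toarray()
    rhs = np.concatenate([X.T @ y, Zd.T @ y])
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "mixed-model equations singular; check X rank and H"
        ) from exc
    resid = float(np.abs(lhs @ sol - rhs).max())
    scale = max(1.0, float(np.abs(rhs).max()))
    if resid > 1e-8 * scale:
        raise np.linalg.LinAlgError(
            f"MME solve residual {resid:.2e} exceeds tolerance"
        )
    return sol[:p], sol[p:]


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass
class VariancePriors:
    """Scaled inverse-chi-square priors σ² ~ ν·S² / χ²_ν.

    The default ν = −2, S² = 0 is the flat (improper) prior on each variance
    — the conventional default of animal-breeding Gibbs samplers — under
    which the full conditional is q/χ²_{q-2} with q the quadratic form, and
    the posterior tracks the likelihood even at the σ²_a → 0 boundary (a
    proper inverse-chi-square scale S² > 0 puts vanishing mass below ≈ S²/3
    and cannot concentrate there). Proper priors are available by setting
    ν > 0 and S² > 0.
    """

    nu_a: float = -2.0
    s2_a: float = 0.0
    nu_e: float = -2.0
    s2_e: float = 0.0


@dataclass
class FitResult:
    """Thinned post-burn-in variance chains plus point solutions."""

    samples_sigma2_a: np.ndarray
    samples_sigma2_e: np.ndarray
    beta_hat: np.ndarray
    a_hat: np.ndarray
    chain_length: int
    burn_in: int
    thin: int
    seed: int
    design: DesignInfo | None = None
    animal_ids: np.ndarray | None = None

    @property
    def samples_h2(self) -> np.ndarray:
        tot = self.samples_sigma2_a + self.samples_sigma2_e
        return self.samples_sigma2_a / tot

    def gebv(self, ids=None) -> np.ndarray:
        """GEBVs, optionally for a subset of animals (e.g. the genotyped)."""
        if ids is None:
            return self.a_hat
        if self.animal_ids is None:
            raise ValueError("fit carries no animal ids")
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        return self.a_hat[[pos[a] for a in ids]]


@njit(cache=True)
def _gibbs_core(indptr, indices, wtw, hdat, diag_pos,
                B, block_start,
                w_indptr, w_indices, w_data, y, rhs,
                n_total, n_animals, n_records,
                n_iter, burn_in, thin,
                nu_a, nuS_a, nu_e, nuS_e,
                s2a, s2e, seed):
    """Single-site Gibbs sweep.

    The sparse CSR (indptr/indices) carries W'W (``wtw``) and the sparse part
    of the padded H⁻¹ (``hdat``) on one shared pattern. ``B`` is an optional
    dense genotyped-block correction (G⁻¹ − A₂₂⁻¹) in float32, occupying
    equations block_start .. block_start+k-1; k = 0 disables it. float32 is
    ample for the correction: its rounding is orders of magnitude below the
    Monte-Carlo noise, and the contiguous rows vectorize.
    """
    np.random.seed(seed)
    k_blk = B.shape[0]
    theta = np.zeros(n_total)
    theta32 = np.zeros(k_blk, dtype=np.float32)
    n_keep = (n_iter - burn_in) // thin
    out_s2a = np.empty(n_keep)
    out_s2e = np.empty(n_keep)
    theta_mean = np.zeros(n_total)
    kept = 0
    ok = True
    for it in range(n_iter):
        lam = s2e / s2a
        # single-site sweep over all location effects
        for j in range(n_total):
            acc = 0.0
            for k in range(indptr[j], indptr[j + 1]):
                acc += (wtw[k] + lam * hdat[k]) * theta[indices[k]]
            kd = diag_pos[j]
            cjj = wtw[kd] + lam * hdat[kd]
            jj = j - block_start
            if 0 <= jj < k_blk:
                accs = np.float32(0.0)
                row = B[jj]
                for t in range(k_blk):
                    accs += row[t] * theta32[t]
                acc += lam * np.float64(accs)
                cjj += lam * np.float64(row[jj])
            mean = (rhs[j] - acc + cjj * theta[j]) / cjj
            theta[j] = mean + np.random.standard_normal() * np.sqrt(s2e / cjj)
            if 0 <= jj < k_blk:
                theta32[jj] = np.float32(theta[j])
        # additive variance from a' H⁻¹ a (fixed-effect block of hdat is 0)
        qf = 0.0
        for j in range(n_total):
            tj = theta[j]
            row_acc = 0.0
            for k in range(indptr[j], indptr[j + 1]):
                row_acc += hdat[k] * theta[indices[k]]
            qf += tj * row_acc
        if k_blk > 0:
            v = np.dot(B, theta32)
            qd = np.float32(0.0)
            for t in range(k_blk):
                qd += v[t] * theta32[t]
            qf += np.float64(qd)
        if qf < -1e-8:
            ok = False
            break
        s2a = (qf + nuS_a) / np.random.chisquare(n_animals + nu_a)
        # residual variance
        ess = 0.0
        for r in range(n_records):
            pred = 0.0
            for k in range(w_indptr[r], w_indptr[r + 1]):
                pred += w_data[k] * theta[w_indices[k]]
            d = y[r] - pred
            ess += d * d
        s2e = (ess + nuS_e) / np.random.chisquare(n_records + nu_e)
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            out_s2a[kept] = s2a
            out_s2e[kept] = s2e
            theta_mean += theta
            kept += 1
    if kept > 0:
        theta_mean /= kept
    return out_s2a, out_s2e, theta_mean, ok


def _pattern(M: sp.spmatrix) -> sp.csr_matrix:
    M = M.tocsr()
    return sp.csr_matrix(
        (np.ones(M.nnz), M.indices.copy(), M.indptr.copy()), shape=M.shape
    )


def _aligned_data(M: sp.csr_matrix, U: sp.csr_matrix) -> np.ndarray:
    """Data of M scattered onto the (sorted) union pattern U."""
    M = M.tocsr()
    M.sort_indices()
    ncol = np.int64(U.shape[1])
    key_u = (np.repeat(np.arange(U.shape[0], dtype=np.int64),
                       np.diff(U.indptr)) * ncol + U.indices)
    key_m = (np.repeat(np.arange(M.shape[0], dtype=np.int64),
                       np.diff(M.indptr)) * ncol + M.indices)
    pos = np.searchsorted(key_u, key_m)
    if not np.array_equal(key_u[pos], key_m):  # pragma: no cover
        raise AssertionError("CSR pattern alignment failed")
    out = np.zeros(U.nnz)
    out[pos] = M.data
    return out


def gibbs_fit(y: np.ndarray, X: np.ndarray, Z: sp.spmatrix,
              h_inv,
              chain: tuple[int, int, int, int] = (50_000, 5_000, 10, 0),
              priors: VariancePriors | None = None,
              design: DesignInfo | None = None,
              animal_ids: np.ndarray | None = None) -> FitResult:
    """Gibbs sampling of the animal model; deterministic given the seed.

    ``chain`` is (length, burn_in, thin, seed). The sampler sweeps fixed
    effects then animals in pedigree order; variances are updated once per
    sweep. Starting values split var(y) by the prior ratio.

    ``h_inv`` may be a sparse H⁻¹ (or A⁻¹ for pedigree-only models), or a
    :class:`~wssgblup.kinship.RelationshipSet`; the latter keeps the
    genotyped-block correction G⁻¹ − A₂₂⁻¹ as a dense array inside the sweep,
    which is substantially faster when the genotyped animals are contiguous
    in the pedigree ordering.
    """
    length, burn_in, thin, seed = chain
    if burn_in >= length:
        raise ValueError(f"burn-in {burn_in} must be < chain length {length}")
    if thin <= 0:
        raise ValueError("thin must be positive")
    y = np.asarray(y, dtype=float)
    vy = float(np.var(y)) or 1.0
    if priors is None:
        priors = VariancePriors()  # flat on both variances

    Xs = sp.csr_matrix(X)
    W = sp.hstack([Xs, Z]).tocsr()
    n_records, n_total = W.shape
    p = X.shape[1]

    # split H⁻¹ into a sparse part and an optional dense genotyped block
    B = np.zeros((0, 0), dtype=np.float32)
    block_start = -1
    h_sparse = h_inv
    if hasattr(h_inv, "a_inv") and hasattr(h_inv, "genotyped_index"):
        rel = h_inv
        gi = np.asarray(rel.genotyped_index)
        contiguous = (len(gi) > 0 and np.array_equal(
            gi, np.arange(gi[0], gi[0] + len(gi))))
        if contiguous:
            corr = (np.linalg.inv(rel.g_final) - np.linalg.inv(rel.a22))
            corr = 0.5 * (corr + corr.T)
            B = corr.astype(np.float32)
            block_start = p + int(gi[0])
            h_sparse = rel.a_inv
        else:
            h_sparse = rel.h_inv

    WtW = (W.T @ W).tocsr()
    Hpad = sp.bmat(
        [[sp.csr_matrix((p, p)), None], [None, h_sparse]], format="csr"
    )
    union = (_pattern(WtW) + _pattern(Hpad)).tocsr()
    union.sort_indices()
    wtw_data = _aligned_data(WtW, union)
    h_data = _aligned_data(Hpad, union)
    indptr, indices = union.indptr, union.indices

    diag_pos = np.empty(n_total, dtype=np.int64)
    for j in range(n_total):
        row = indices[indptr[j]:indptr[j + 1]]
        loc = np.searchsorted(row, j)
        if loc >= len(row) or row[loc] != j:
            raise np.linalg.LinAlgError(
                f"zero diagonal at equation {j}; X is rank deficient or an "
                "animal has no pedigree/genomic information"
            )
        diag_pos[j] = indptr[j] + loc

    rhs = np.asarray(W.T @ y).ravel()
    # chain start: an even variance split unless the prior pins a scale
    start_a = priors.s2_a if priors.s2_a > 0 else 0.5 * vy
    start_e = priors.s2_e if priors.s2_e > 0 else 0.5 * vy
    out_a, out_e, theta_mean, ok = _gibbs_core(
        indptr, indices, wtw_data, h_data, diag_pos,
        np.ascontiguousarray(B), int(block_start),
        W.indptr, W.indices, W.data, y, rhs,
        n_total, n_total - p, n_records,
        int(length), int(burn_in), int(thin),
        float(priors.nu_a), float(max(priors.nu_a, 0.0) * priors.s2_a),
        float(priors.nu_e), float(max(priors.nu_e, 0.0) * priors.s2_e),
        float(start_a), float(start_e), int(seed) & 0x7FFFFFFF,
    )
    if not ok:
        raise np.linalg.LinAlgError(
            "negative quadratic form a'H⁻¹a: H⁻¹ not positive definite"
        )
    return FitResult(
        samples_sigma2_a=out_a, samples_sigma2_e=out_e,
        beta_hat=theta_mean[:p], a_hat=theta_mean[p:],
        chain_length=length, burn_in=burn_in, thin=thin, seed=seed,
        design=design, animal_ids=animal_ids,
    )


# ---------------------------------------------------------------------------
# Posterior summaries and convergence diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    mean: float
    median: float
    sd: float
    hpd_low: float
    hpd_high: float
    mass: float = 0.95


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ⌈mass·n⌉ sorted samples."""
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def posterior_summary(samples: np.ndarray, mass: float = 0.95) -> PosteriorSummary:
    """Mean, median, SD and HPD interval of one monitored scalar."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 samples to summarize")
    lo, hi = hpd_interval(x, mass)
    return PosteriorSummary(
        mean=float(x.mean()), median=float(np.median(x)),
        sd=float(x.std(ddof=1)), hpd_low=lo, hpd_high=hi, mass=mass,
    )


def _batch_means_var_of_mean(x: np.ndarray) -> float:
    """Variance of the sample mean via batch means, ⌈√n⌉ batches.

    Estimates the spectral density at frequency zero divided by n, so it is
    valid for autocorrelated MCMC output.
    """
    n = len(x)
    nb = int(np.ceil(np.sqrt(n)))
    bs = n // nb
    if bs < 1:
        raise ValueError("segment too short for batch means")
    means = x[: nb * bs].reshape(nb, bs).mean(axis=1)
    if nb < 2:
        raise ValueError("need at least two batches")
    return float(means.var(ddof=1) / nb)


def geweke_diag(chain: np.ndarray, first: float = 0.1, last: float = 0.5
                ) -> float:
    """Geweke z-score comparing the first and last chain segments.

    z = (mean_first − mean_last) / sqrt(s²_first + s²_last) with
    batch-means estimates of each segment mean's variance.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic")
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise ValueError("segment fractions must be in (0,1) with sum <= 1")
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    va = _batch_means_var_of_mean(a)
    vb = _batch_means_var_of_mean(b)
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero-variance segments with unequal means")
    return float((a.mean() - b.mean()) / denom)


# asymptotic Cramér-von Mises critical values (one-sample, mean case)
_CVM_CRITICAL = {0.10: 0.3473, 0.05: 0.4614, 0.025: 0.5806, 0.01: 0.7435}


@dataclass
class HeidelbergerWelchResult:
    stationarity_pass: bool
    kept_fraction: float
    halfwidth_pass: bool
    cvm_statistic: float = float("nan")
    halfwidth: float = float("nan")


def heidelberger_welch_diag(chain: np.ndarray, alpha: float = 0.05,
                            halfwidth_tol: float = 0.1
                            ) -> HeidelbergerWelchResult:
    """Heidelberger–Welch stationarity and halfwidth tests.

    Applies the Cramér–von Mises test to the Brownian bridge of cumulative
    sums, discarding successive 10% prefixes (up to 50%) until it passes.
    The halfwidth test compares the 95% CI halfwidth of the mean (batch-means
    spectral variance) against ``halfwidth_tol``·|mean|.
    """
    x = np.asarray(chain, dtype=float)
    n0 = len(x)
    if n0 < 100:
        raise ValueError("chain too short for the Heidelberger-Welch test")
    crit = _CVM_CRITICAL.get(alpha)
    if crit is None:
        crit = _CVM_CRITICAL[min(_CVM_CRITICAL, key=lambda a: abs(a - alpha))]
    if np.ptp(x) == 0.0:  # constant chain: trivially stationary
        return HeidelbergerWelchResult(True, 1.0, True, 0.0, 0.0)

    stat = float("nan")
    for drop in range(0, 6):  # 0%,10%,...,50% discarded
        start = int(0.1 * drop * n0)
        seg = x[start:]
        n = len(seg)
        s0 = _batch_means_var_of_mean(seg) * n  # spectral density at 0
        if s0 <= 0:
            break
        csum = np.cumsum(seg - seg.mean())
        bridge = csum / np.sqrt(n * s0)
        stat = float(np.mean(bridge**2))
        if stat < crit:
            kept = n / n0
            hw = 1.96 * np.sqrt(_batch_means_var_of_mean(seg))
            hw_pass = bool(hw <= halfwidth_tol * abs(seg.mean())) if seg.mean() != 0 \
                else bool(hw == 0.0)
            return HeidelbergerWelchResult(True, kept, hw_pass, stat, hw)
    return HeidelbergerWelchResult(False, 0.0, False, stat, float("nan"))
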