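import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from wssgblup import (PedigreeTable, PhenotypeTable, SimConfig, VariancePriors,
                      build_A_inverse, build_design_matrices,
                      build_relationships, geweke_diag, gibbs_fit,
                      heidelberger_welch_diag, hpd_interval, mme_solve,
                      posterior_summary, qc, simulate_study)
from wssgblup import mme


def _phen(n=6, groups=("g1", "g1", "g1", "g2", "g2", "g2"), ages=None):
    rng = np.random.default_rng(0)
    ages = ages if ages is not None else rng.uniform(550, 700, n)
    df = pd.DataFrame({
        "animal_id": [f"a{i}" for i in range(n)],
        "trait_value": rng.normal(size=n),
        "contemporary_group": list(groups),
        "slaughter_age": ages,
    })
    return PhenotypeTable(data=df)


def _flat_pedigree(n=6):
    return PedigreeTable(
        animal=np.array([f"a{i}" for i in range(n)], dtype=object),
        sire=np.array(["0"] * n, dtype=object),
        dam=np.array(["0"] * n, dtype=object),
    )


class TestDesignMatrices:
    def test_two_cgs_give_one_cg_column_and_two_age_columns(self):
        phen = _phen()
        y, X, Z, info = build_design_matrices(phen, None, _flat_pedigree())
        cg_cols = [c for c in info.columns if c.startswith("cg[")]
        age_cols = [c for c in info.columns if "age" in c]
        assert len(cg_cols) == 1 and len(age_cols) == 2
        assert X.shape == (6, 4)  # + intercept
        assert Z.shape == (6, 6)

    def test_constant_age_columns_are_dropped(self):
        phen = _phen(ages=np.full(6, 600.0))
        _, X, _, info = build_design_matrices(phen, None, _flat_pedigree())
        assert len(info.dropped_columns) == 2
        assert not any("age" in c for c in info.columns)

    def test_record_permutation_is_consistent(self):
        phen = _phen()
        y1, X1, Z1, _ = build_design_matrices(phen, None, _flat_pedigree())
        perm = [3, 1, 5, 0, 2, 4]
        phen2 = PhenotypeTable(data=phen.data.iloc[perm].reset_index(drop=True))
        y2, X2, Z2, _ = build_design_matrices(phen2, None, _flat_pedigree())
        assert np.allclose(y2, y1[perm])
        assert np.allclose(X2, X1[perm])
        assert np.allclose(Z2.toarray(), Z1.toarray()[perm])

    def test_unknown_animal_raises_with_ids(self):
        phen = _phen()
        ped = _flat_pedigree(3)  # a3..a5 missing
        with pytest.raises(ValueError, match="a3"):
            build_design_matrices(phen, None, ped)


class TestMmeSolve:
    def _system(self, n=8, seed=2):
        rng = np.random.default_rng(seed)
        ped = _flat_pedigree(n)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = sp.eye(n, format="csr")
        return y, X, Z, build_A_inverse(ped)

    def test_huge_lambda_shrinks_gebvs_to_ols(self):
        y, X, Z, a_inv = self._system()
        beta, a = mme_solve(y, X, Z, a_inv, sigma2_a=1e-12, sigma2_e=1.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(a).max() < 1e-6
        assert np.allclose(beta, ols, atol=1e-6)

    def test_matches_bruteforce_dense_solve(self):
        y, X, Z, a_inv = self._system(n=4)
        s2a, s2e = 0.4, 0.6
        beta, a = mme_solve(y, X, Z, a_inv, s2a, s2e)
        lam = s2e / s2a
        Zd = Z.toarray()
        lhs = np.block([[X.T @ X, X.T @ Zd],
                        [Zd.T @ X, Zd.T @ Zd + lam * a_inv.toarray()]])
        rhs = np.concatenate([X.T @ y, Zd.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        assert np.allclose(np.concatenate([beta, a]), sol, atol=1e-10)

    def test_constant_shift_moves_intercept_not_gebvs(self):
        y, X, Z, a_inv = self._system()
        _, a1 = mme_solve(y, X, Z, a_inv, 0.3, 0.7)
        beta2, a2 = mme_solve(y + 5.0, X, Z, a_inv, 0.3, 0.7)
        assert np.allclose(a2, a1, atol=1e-8)

    def test_nonpositive_variances_rejected(self):
        y, X, Z, a_inv = self._system()
        with pytest.raises(ValueError):
            mme_solve(y, X, Z, a_inv, 0.0, 1.0)


@pytest.fixture(scope="module")
def small_fit_system():
    cfg = SimConfig(n_founders=120, n_generations=2, offspring_per_mating=2,
                    matings_per_generation=80, n_chromosomes=2,
                    snps_per_chromosome=100, prop_genotyped=0.5, h2=0.4,
                    seed=21)
    ped, geno, phen = simulate_study(cfg)
    geno = qc.impute_missing(qc.filter_snps(geno)[0])
    phen, _ = qc.filter_contemporary_groups(phen)
    y, X, Z, _ = build_design_matrices(phen, None, ped)
    rel = build_relationships(ped, geno)
    return y, X, Z, rel


class TestGibbs:
    def test_fixed_seed_reproduces_chain(self, small_fit_system):
        y, X, Z, rel = small_fit_system
        f1 = gibbs_fit(y, X, Z, rel, chain=(2000, 200, 5, 13))
        f2 = gibbs_fit(y, X, Z, rel, chain=(2000, 200, 5, 13))
        assert np.array_equal(f1.samples_sigma2_a, f2.samples_sigma2_a)
        assert np.array_equal(f1.a_hat, f2.a_hat)

    def test_location_means_converge_to_mme_solution(self, small_fit_system):
        """With variances pinned by an overwhelming prior, posterior means of
        (beta, a) agree with the direct solver within Monte-Carlo error."""
        y, X, Z, rel = small_fit_system
        s2a, s2e = 0.4, 0.6
        priors = VariancePriors(nu_a=1e9, s2_a=s2a, nu_e=1e9, s2_e=s2e)
        fit = gibbs_fit(y, X, Z, rel, chain=(6000, 1000, 1, 3), priors=priors)
        assert np.allclose(fit.samples_sigma2_a, s2a, rtol=1e-3)
        beta, a = mme_solve(y, X, Z, rel.h_inv, s2a, s2e)
        # MC error of the mean of ~5000 correlated draws
        assert np.abs(fit.beta_hat - beta).max() < 0.15
        assert np.corrcoef(fit.a_hat, a)[0, 1] > 0.98

    def test_h2_samples_invariant_to_y_rescaling(self, small_fit_system):
        # scale by a power of two so floating-point scaling is exact and the
        # two chains follow identical trajectories draw for draw
        y, X, Z, rel = small_fit_system
        pri = VariancePriors(nu_a=4, s2_a=0.5, nu_e=4, s2_e=0.5)
        pri_scaled = VariancePriors(nu_a=4, s2_a=0.5 * 4, nu_e=4, s2_e=0.5 * 4)
        f1 = gibbs_fit(y, X, Z, rel, chain=(1500, 200, 5, 7), priors=pri)
        f2 = gibbs_fit(2.0 * y, X, Z, rel, chain=(1500, 200, 5, 7),
                       priors=pri_scaled)
        assert np.allclose(f2.samples_sigma2_a, 4.0 * f1.samples_sigma2_a,
                           rtol=1e-12)
        assert np.allclose(f2.samples_h2, f1.samples_h2, rtol=1e-12)
        assert ((f1.samples_h2 > 0) & (f1.samples_h2 < 1)).all()

    def test_zero_heritability_concentrates_at_boundary(self):
        # large full-sib families identify h2 = 0 sharply (no sib resemblance)
        cfg = SimConfig(n_founders=60, n_generations=1,
                        offspring_per_mating=20, matings_per_generation=30,
                        n_chromosomes=1, snps_per_chromosome=50,
                        prop_genotyped=0.0, h2=0.0, seed=17)
        ped, geno, phen = simulate_study(cfg)
        phen, _ = qc.filter_contemporary_groups(phen)
        y, X, Z, _ = build_design_matrices(phen, None, ped)
        a_inv = build_A_inverse(ped)
        fit = gibbs_fit(y, X, Z, a_inv, chain=(20_000, 2_000, 10, 5))
        s = posterior_summary(fit.samples_h2)
        assert s.hpd_low < 0.02
        assert s.median < 0.1

    def test_burn_in_validation(self, small_fit_system):
        y, X, Z, rel = small_fit_system
        with pytest.raises(ValueError):
            gibbs_fit(y, X, Z, rel, chain=(100, 100, 1, 0))


class TestPosteriorSummary:
    def test_constant_chain_is_a_point_mass(self):
        s = posterior_summary(np.full(500, 3.2))
        assert (s.mean, s.median, s.sd) == (3.2, 3.2, 0.0)
        assert (s.hpd_low, s.hpd_high) == (3.2, 3.2)

    def test_hpd_on_standard_normal_draws(self):
        x = np.random.default_rng(1).standard_normal(100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert abs(lo - (-1.96)) < 0.05 and abs(hi - 1.96) < 0.05

    def test_hpd_is_shorter_than_equal_tail_for_skewed_chains(self):
        x = np.random.default_rng(2).exponential(size=50_000)
        lo, hi = hpd_interval(x, 0.95)
        eq = np.quantile(x, [0.025, 0.975])
        assert lo < 0.05                      # pinned near the mode at 0
        assert (hi - lo) < (eq[1] - eq[0])

    def test_mass_validation(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(200.0), 1.5)
        with pytest.raises(ValueError):
            posterior_summary(np.arange(50.0))  # too few samples


class TestDiagnostics:
    def test_geweke_flags_a_linear_trend(self):
        z = geweke_diag(np.arange(5000, dtype=float))
        assert abs(z) > 10

    def test_geweke_zero_for_mirrored_chain(self):
        rng = np.random.default_rng(3)
        half = rng.standard_normal(2500)
        chain = np.concatenate([half, half[::-1]])
        assert geweke_diag(chain, first=0.5, last=0.5) == 0.0

    def test_geweke_null_calibration_sample(self):
        rng = np.random.default_rng(4)
        hits = sum(abs(geweke_diag(rng.standard_normal(5000))) > 1.96
                   for _ in range(200))
        assert 0.01 <= hits / 200 <= 0.11

    def test_heidelberger_passes_stationary_chain(self):
        rng = np.random.default_rng(5)
        res = heidelberger_welch_diag(rng.standard_normal(5000))
        assert res.stationarity_pass and res.kept_fraction == 1.0

    def test_heidelberger_detects_level_shift(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(4000)
        x[2000:] += 6.0
        res = heidelberger_welch_diag(x)
        assert (not res.stationarity_pass) or res.kept_fraction <= 0.5

    def test_heidelberger_constant_chain_trivially_passes(self):
        res = heidelberger_welch_diag(np.full(1000, 2.0))
        assert res.stationarity_pass and res.halfwidth_pass
        assert res.halfwidth == 0.0
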