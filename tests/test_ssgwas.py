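import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wssgblup import (backsolve_snp_effects, centered_content,
                      normalize_weights, run_weighted_iterations,
                      select_regions, snp_weights, window_variances)


def _snp_map(m, chrom="1"):
    return pd.DataFrame({"snp_id": [f"s{j}" for j in range(m)],
                         "chrom": [chrom] * m,
                         "pos_bp": np.arange(1, m + 1) * 1000})


class TestBacksolve:
    def test_zero_gebvs_give_zero_effects(self):
        rng = np.random.default_rng(0)
        Z = rng.integers(0, 3, size=(8, 20)).astype(float)
        Z = Z - Z.mean(axis=0)
        u = backsolve_snp_effects(np.zeros(8), Z)
        assert np.allclose(u, 0.0)

    def test_reproduces_gebvs_exactly_on_full_rank_instances(self):
        rng = np.random.default_rng(1)
        Z = rng.integers(0, 3, size=(15, 60)).astype(float)
        Z = Z - Z.mean(axis=0)
        a = rng.normal(size=15)
        a = a - a.mean()
        u = backsolve_snp_effects(a, Z)
        assert np.abs(Z @ u - a).max() < 1e-8

    def test_orthogonal_columns_match_least_squares(self):
        # Z with orthogonal columns, D = I: the minimum-norm reconstruction
        # coincides with the pseudo-inverse regression of a on Z
        Z = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0],
                      [0, -1, 0], [0, 0, 2], [0, 0, -2]])
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        u = backsolve_snp_effects(a, Z)
        u_ls = np.linalg.lstsq(Z, a, rcond=None)[0]
        assert np.allclose(u, u_ls, atol=1e-10)

    def test_weighted_form_respects_weights(self):
        rng = np.random.default_rng(2)
        Z = rng.integers(0, 3, size=(10, 40)).astype(float)
        Z = Z - Z.mean(axis=0)
        a = rng.normal(size=10); a -= a.mean()
        d = rng.uniform(0.1, 2.0, size=40)
        u = backsolve_snp_effects(a, Z, d)
        assert np.abs(Z @ u - a).max() < 1e-8
        # hand evaluation of D Z'[Z D Z']^+ a on the centered complement
        K = (Z * d) @ Z.T
        u_hand = d * (Z.T @ np.linalg.pinv(K) @ a)
        assert np.allclose(u, u_hand, atol=1e-8)


class TestWeights:
    @pytest.mark.parametrize("u,p,expected", [
        (0.0, 0.5, 0.0),
        (1.0, 0.5, 0.5),
        (0.2, 0.3, 0.0168),
    ])
    def test_snp_weight_formula(self, u, p, expected):
        assert snp_weights(np.array([u]), np.array([p]))[0] == pytest.approx(expected)

    def test_rejects_boundary_frequencies(self):
        with pytest.raises(ValueError):
            snp_weights(np.array([1.0]), np.array([0.0]))

    def test_normalization_fixed_point_and_scale_invariance(self):
        p = np.array([0.2, 0.5, 0.4])
        ones = np.ones(3)
        assert np.allclose(normalize_weights(ones, p), ones)
        assert np.allclose(normalize_weights(7.3 * ones, p), ones)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_normalization_conserves_weighted_heterozygosity(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 50)
        d = rng.exponential(size=m)
        p = rng.uniform(0.05, 0.95, size=m)
        het = 2 * p * (1 - p)
        d_norm = normalize_weights(d, p)
        assert d_norm @ het == pytest.approx(het.sum(), abs=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights(np.zeros(4), np.full(4, 0.5))


class TestWindowVariances:
    def test_zero_effects_give_zero_everywhere(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(12, 30))
        rep = window_variances(np.zeros(30), Z, 1.0, _snp_map(30))
        assert (rep["pct_variance"] == 0).all()
        assert rep["n_snps"].tolist() == [10, 10, 10]

    def test_hand_computed_single_window(self):
        rng = np.random.default_rng(4)
        Z = rng.integers(0, 3, size=(5, 10)).astype(float)
        Z = Z - Z.mean(axis=0)
        u = rng.normal(size=10)
        s2a = 0.25
        rep = window_variances(u, Z, s2a, _snp_map(10))
        a_i = Z @ u
        expected = a_i.var(ddof=1) / s2a * 100
        assert rep["pct_variance"].iloc[0] == pytest.approx(expected)
        assert len(rep) == 1 and rep["n_snps"].iloc[0] == 10

    def test_concentrated_effects_light_up_one_window(self):
        rng = np.random.default_rng(5)
        n, m = 400, 50
        Z = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        Z = Z - Z.mean(axis=0)
        u = np.zeros(m)
        u[10:20] = rng.normal(size=10)          # all effect in window 2
        a = Z @ u
        s2a = a.var(ddof=1)
        rep = window_variances(u, Z, s2a, _snp_map(m))
        assert rep["pct_variance"].iloc[1] == pytest.approx(100.0)
        others = rep["pct_variance"].drop(index=1)
        assert (others < 1e-20).all()

    def test_trailing_remainder_window_is_flagged(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(8, 23))
        rep = window_variances(rng.normal(size=23), Z, 1.0, _snp_map(23))
        assert rep["n_snps"].tolist() == [10, 10, 3]
        assert rep["short_window"].tolist() == [False, False, True]

    def test_windows_tile_chromosomes_without_overlap(self):
        m = 35
        snp_map = _snp_map(m)
        snp_map.loc[20:, "chrom"] = "2"
        snp_map["pos_bp"] = list(range(1, 21)) + list(range(1, 16))
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(6, m))
        rep = window_variances(rng.normal(size=m), Z, 1.0, snp_map)
        assert rep["chrom"].tolist() == ["1", "1", "2", "2"]
        assert rep["n_snps"].tolist() == [10, 10, 10, 5]

    def test_snp_permutation_leaves_window_contents_invariant(self):
        rng = np.random.default_rng(8)
        m = 30
        Z = rng.normal(size=(10, m))
        u = rng.normal(size=m)
        snp_map = _snp_map(m)
        rep1 = window_variances(u, Z, 1.0, snp_map)
        perm = rng.permutation(m)
        # permute storage order, then restore map order via the map itself
        snp_map2 = snp_map.iloc[perm].reset_index(drop=True)
        order = snp_map2["pos_bp"].argsort().to_numpy()
        rep2 = window_variances(u[perm][order], Z[:, perm][:, order], 1.0,
                                snp_map2.iloc[order].reset_index(drop=True))
        assert np.allclose(rep1["pct_variance"], rep2["pct_variance"])

    def test_bad_inputs_rejected(self):
        Z = np.zeros((4, 10))
        with pytest.raises(ValueError):
            window_variances(np.zeros(10), Z, 1.0, _snp_map(10), window_size=0)
        with pytest.raises(ValueError):
            window_variances(np.zeros(10), Z, 0.0, _snp_map(10))


class TestSelectRegions:
    def _report(self, pcts):
        return pd.DataFrame({
            "window": range(len(pcts)),
            "chrom": ["1"] * len(pcts),
            "start_bp": np.arange(len(pcts)) * 10_000 + 1,
            "end_bp": np.arange(len(pcts)) * 10_000 + 9_000,
            "n_snps": 10,
            "pct_variance": pcts,
        })

    def test_magnitude_fixture_selects_and_orders(self):
        sel = select_regions(self._report([0.9, 6.64, 1.29]))
        assert sel["pct_variance"].tolist() == [6.64, 1.29]

    def test_all_below_threshold_selects_nothing(self):
        assert len(select_regions(self._report([0.2, 0.5]))) == 0

    def test_zero_threshold_returns_everything(self):
        assert len(select_regions(self._report([0.2, 0.5]), 0.0)) == 2


class TestWeightedIterations:
    def test_single_iteration_is_the_unweighted_backsolve(self, fitted_study):
        fs = fitted_study
        sols = run_weighted_iterations(fs["ped"], fs["geno"], fs["y"],
                                       fs["X"], fs["Z"], 0.4, 0.6, n_iter=1)
        assert len(sols) == 1
        sol = sols[0]
        assert np.allclose(sol.d, 1.0)
        Zc, _ = centered_content(fs["geno"])
        u_direct = backsolve_snp_effects(sol.gebv_genotyped, Zc)
        assert np.allclose(sol.u_hat, u_direct, atol=1e-10)

    def test_backsolve_identity_and_weight_conservation_each_iteration(
            self, fitted_study):
        fs = fitted_study
        sols = run_weighted_iterations(fs["ped"], fs["geno"], fs["y"],
                                       fs["X"], fs["Z"], 0.4, 0.6, n_iter=3)
        het0 = None
        for sol in sols:
            assert sol.backsolve_residual < 1e-8
            het = 2 * sol.p * (1 - sol.p)
            if het0 is None:
                het0 = float(het.sum())
            assert float(sol.d @ het) == pytest.approx(het0, abs=1e-10)

    def test_planted_qtl_weight_strictly_increases(self, fitted_study):
        fs = fitted_study
        sols = run_weighted_iterations(fs["ped"], fs["geno"], fs["y"],
                                       fs["X"], fs["Z"], 0.4, 0.6, n_iter=2)
        # the study plants one QTL at 20% of genetic variance at raw index 50
        qtl_id = "snp51"
        snp_map = fs["geno"].observed().snp_map
        j = snp_map.index[snp_map.snp_id == qtl_id][0]
        assert sols[1].d[j] > sols[0].d[j]

    def test_iteration_counter_and_determinism(self, fitted_study):
        fs = fitted_study
        s1 = run_weighted_iterations(fs["ped"], fs["geno"], fs["y"], fs["X"],
                                     fs["Z"], 0.4, 0.6, n_iter=2)
        s2 = run_weighted_iterations(fs["ped"], fs["geno"], fs["y"], fs["X"],
                                     fs["Z"], 0.4, 0.6, n_iter=2)
        assert [s.iteration for s in s1] == [1, 2]
        for a, b in zip(s1, s2):
            assert np.array_equal(a.u_hat, b.u_hat)

    def test_invalid_iteration_count(self, fitted_study):
        fs = fitted_study
        with pytest.raises(ValueError):
            run_weighted_iterations(fs["ped"], fs["geno"], fs["y"], fs["X"],
                                    fs["Z"], 0.4, 0.6, n_iter=0)
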