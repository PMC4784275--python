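import numpy as np
import pandas as pd
import pytest

from wssgblup import (PedigreeTable, GenotypeMatrix, SimConfig, mme, qc,
                      simulate_study)


@pytest.fixture
def trio():
    """Sire, dam, one non-inbred offspring."""
    return PedigreeTable(
        animal=np.array(["s", "d", "o"], dtype=object),
        sire=np.array(["0", "0", "s"], dtype=object),
        dam=np.array(["0", "0", "d"], dtype=object),
    )


def random_pedigree(seed: int, n_founders=40, generations=3, matings=27):
    cfg = SimConfig(n_founders=n_founders, n_generations=generations,
                    offspring_per_mating=2, matings_per_generation=matings,
                    n_chromosomes=1, snps_per_chromosome=10, seed=seed)
    from wssgblup import simulate_pedigree
    return simulate_pedigree(cfg)


@pytest.fixture
def small_geno():
    """4 animals x 4 SNPs, complete calls, polymorphic."""
    calls = np.array([
        [0, 1, 2, 1],
        [1, 1, 0, 2],
        [2, 0, 1, 1],
        [1, 2, 1, 0],
    ], dtype=float)
    snp_map = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(1, 5)],
        "chrom": ["1"] * 4,
        "pos_bp": [100, 200, 300, 400],
    })
    return GenotypeMatrix(calls=calls,
                          animal_ids=np.array(list("abcd"), dtype=object),
                          snp_map=snp_map)


@pytest.fixture(scope="session")
def fitted_study():
    """One moderate simulated study, QC'd, with design matrices — shared by
    the solver/GWAS tests (session-scoped: ~1 s to build)."""
    cfg = SimConfig(n_founders=80, n_generations=2, offspring_per_mating=2,
                    matings_per_generation=60, n_chromosomes=2,
                    snps_per_chromosome=100, prop_genotyped=0.5,
                    h2=0.4, qtl_spec=[(50, 0.2)], seed=42)
    ped, geno, phen = simulate_study(cfg)
    geno_qc, _ = qc.filter_snps(geno)
    geno_qc = qc.impute_missing(geno_qc)
    phen_qc, _ = qc.filter_contemporary_groups(phen)
    y, X, Z, design = mme.build_design_matrices(phen_qc, None, ped)
    return {"cfg": cfg, "ped": ped, "geno": geno_qc, "phen": phen,
            "y": y, "X": X, "Z": Z, "design": design}
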