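"""Genotype and phenotype quality control.

SNP filters run in a fixed, logged order — (1) unknown position / excluded
chromosome, (2) SNP call rate, (3) monomorphic, (4) MAF, (5) heterozygosity
excess — followed by (6) sample call rate. Each SNP is attributed to the
first filter it fails. "Excess heterozygosity" is defined here as observed
minus Hardy-Weinberg expected heterozygosity (2p(1-p)) above an absolute
limit; the threshold is configurable because the convention varies between
genotyping platforms.

Contemporary-group (CG) filtering drops whole groups with too few records and
then, in a single pass, records deviating more than ``cg_sd_limit`` standard
deviations from their group mean (SD computed on the pre-drop group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, PhenotypeTable

DEFAULT_EXCLUDED_CHROMS = frozenset({"X", "Y", "MT", "0"})


@dataclass
class QcThresholds:
    min_maf: float = 0.05
    min_snp_call_rate: float = 0.90
    min_sample_call_rate: float = 0.90
    het_excess_limit: float = 0.15
    excluded_chromosomes: frozenset = DEFAULT_EXCLUDED_CHROMS
    min_cg_size: int = 3
    cg_sd_limit: float = 3.0

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_snp_call_rate", "min_sample_call_rate",
                     "het_excess_limit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_cg_size <= 0:
            raise ValueError("min_cg_size must be positive")
        if self.cg_sd_limit <= 0:
            raise ValueError("cg_sd_limit must be positive")
        self.excluded_chromosomes = frozenset(
            str(c) for c in self.excluded_chromosomes
        )


@dataclass
class QcReport:
    """Per-filter removal counts; removed + surviving = input per axis."""

    n_snps_in: int = 0
    n_samples_in: int = 0
    n_records_in: int = 0
    removed_position: int = 0
    removed_snp_call_rate: int = 0
    removed_monomorphic: int = 0
    removed_maf: int = 0
    removed_het_excess: int = 0
    removed_sample_call_rate: int = 0
    removed_small_cg: int = 0
    removed_cg_outlier: int = 0
    n_snps_out: int = 0
    n_samples_out: int = 0
    n_records_out: int = 0
    snp_filter_of: pd.Series | None = field(default=None, repr=False)

    def snp_counts(self) -> tuple[int, int, int, int, int]:
        return (self.removed_position, self.removed_snp_call_rate,
                self.removed_monomorphic, self.removed_maf,
                self.removed_het_excess)

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.__dict__.items()
                if k != "snp_filter_of" and v is not None]
        return pd.DataFrame(rows, columns=["filter", "count"])


class NoSurvivingSnpsError(RuntimeError):
    """No SNPs survive QC."""


def filter_snps(geno: GenotypeMatrix, thr: QcThresholds | None = None
                ) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the SNP filters, then the sample call-rate filter.

    Statistics (call rate, allele frequency, heterozygosity) are computed on
    the genotyped animals only. Surviving SNPs keep their input order; the
    report records, per removed SNP, the first filter it failed.
    """
    thr = thr or QcThresholds()
    obs = geno.observed()
    calls = obs.calls
    n_samples, n_snps = calls.shape
    report = QcReport(n_snps_in=n_snps, n_samples_in=n_samples)

    observed_mask = ~np.isnan(calls)
    n_obs = observed_mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0) / np.maximum(2 * n_obs, 1)
        het_obs = np.nansum(calls == 1.0, axis=0) / np.maximum(n_obs, 1)
    maf = np.minimum(p, 1.0 - p)
    het_exp = 2.0 * p * (1.0 - p)

    chrom = geno.snp_map["chrom"].astype(str).to_numpy()
    pos = geno.snp_map["pos_bp"].to_numpy()
    fails = [
        ("position", np.isin(chrom, list(thr.excluded_chromosomes)) | (pos <= 0)),
        ("snp_call_rate", n_obs < thr.min_snp_call_rate * n_samples),
        ("monomorphic", (n_obs > 0) & ((p == 0.0) | (p == 1.0))),
        ("maf", maf < thr.min_maf),
        ("het_excess", het_obs - het_exp > thr.het_excess_limit),
    ]
    filter_of = np.full(n_snps, "", dtype=object)
    removed = np.zeros(n_snps, dtype=bool)
    for name, mask in fails:
        newly = mask & ~removed
        filter_of[newly] = name
        setattr(report, f"removed_{name}", int(newly.sum()))
        removed |= mask

    keep_snps = ~removed
    if not keep_snps.any():
        raise NoSurvivingSnpsError("no SNPs survive QC")

    kept_calls = geno.calls[:, keep_snps]
    # sample call rate, evaluated on surviving SNPs, genotyped animals only
    if geno.genotyped is None:
        sample_rate = (~np.isnan(kept_calls)).mean(axis=1)
        sample_keep = sample_rate >= thr.min_sample_call_rate
    else:
        sample_keep = np.ones(geno.n_animals, dtype=bool)
        g = geno.genotyped
        rate = (~np.isnan(kept_calls[g])).mean(axis=1)
        sample_keep[np.where(g)[0][rate < thr.min_sample_call_rate]] = False
    report.removed_sample_call_rate = int((~sample_keep).sum())

    new_genotyped = None if geno.genotyped is None else geno.genotyped[sample_keep]
    out = GenotypeMatrix(
        calls=kept_calls[sample_keep],
        animal_ids=geno.animal_ids[sample_keep],
        snp_map=geno.snp_map.loc[keep_snps].reset_index(drop=True),
        genotyped=new_genotyped,
    )
    report.n_snps_out = out.n_snps
    report.n_samples_out = (out.n_animals if new_genotyped is None
                            else int(new_genotyped.sum()))
    report.snp_filter_of = pd.Series(
        filter_of[removed], index=geno.snp_map.loc[removed, "snp_id"]
    )
    return out, report


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Mean-impute missing calls as 2p (the column mean among observed calls).

    Run after QC; imputed values are fractional and only meaningful for
    relationship-matrix construction.
    """
    calls = geno.calls.copy()
    col_mean = np.nanmean(np.where(np.isnan(calls), np.nan, calls), axis=0)
    idx = np.where(np.isnan(calls))
    calls[idx] = col_mean[idx[1]]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.calls = calls
    out.animal_ids = geno.animal_ids
    out.snp_map = geno.snp_map
    out.genotyped = geno.genotyped
    return out


def filter_contemporary_groups(phen: PhenotypeTable,
                               thr: QcThresholds | None = None
                               ) -> tuple[PhenotypeTable, QcReport]:
    """Drop CGs smaller than ``min_cg_size``, then single-pass 3-SD outliers.

    The outlier SD is computed on the pre-drop group; a zero-variance group
    removes no outliers.
    """
    thr = thr or QcThresholds()
    df = phen.data
    report = QcReport(n_records_in=len(df))

    sizes = df.groupby("contemporary_group")["trait_value"].transform("size")
    small = sizes < thr.min_cg_size
    report.removed_small_cg = int(small.sum())
    df = df[~small]

    grp = df.groupby("contemporary_group")["trait_value"]
    mean = grp.transform("mean")
    # population SD; a record AT the limit counts as deviating
    sd = grp.transform("std", ddof=0).fillna(0.0)
    outlier = (sd > 0) & (
        (df["trait_value"] - mean).abs() >= thr.cg_sd_limit * sd - 1e-12
    )
    report.removed_cg_outlier = int(outlier.sum())
    df = df[~outlier].reset_index(drop=True)

    report.n_records_out = len(df)
    out = PhenotypeTable(
        data=df, trait=phen.trait,
        true_breeding_values=phen.true_breeding_values,
        true_variances=phen.true_variances,
    )
    return out, report
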