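"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Animal identifiers are strings; ``"0"`` (or empty) marks an unknown parent.
* Genotype calls are counts of the A1 allele in {0, 1, 2}; missing calls are
  ``numpy.nan`` (the matrix is float64).
* Map positions are 1-based bp and strictly increasing within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass
class PedigreeTable:
    """Ordered animal/sire/dam records defining the numerator relationship A.

    Records must be topologically sorted: every named parent appears as an
    earlier record. Integer parent indices (``-1`` = unknown) are derived once
    at construction and reused by all relationship-matrix code.
    """

    animal: np.ndarray   # str ids, unique
    sire: np.ndarray     # str ids or "0"
    dam: np.ndarray      # str ids or "0"
    sire_idx: np.ndarray = field(init=False)
    dam_idx: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        self.dam = np.asarray(self.dam, dtype=object)
        n = len(self.animal)
        if len(self.sire) != n or len(self.dam) != n:
            raise ValueError("animal/sire/dam columns must have equal length")
        pos = {a: i for i, a in enumerate(self.animal)}
        if len(pos) != n:
            raise ValueError("duplicate animal ids in pedigree")
        sire_idx = np.full(n, -1, dtype=np.int64)
        dam_idx = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            for parent, out in ((self.sire[i], sire_idx), (self.dam[i], dam_idx)):
                if parent in (UNKNOWN_PARENT, "", None):
                    continue
                j = pos.get(parent)
                if j is None:
                    raise ValueError(
                        f"parent {parent!r} of animal {self.animal[i]!r} "
                        "is not a pedigree record"
                    )
                if j >= i:
                    raise ValueError(
                        f"pedigree not topologically ordered: parent {parent!r} "
                        f"appears at or after its offspring {self.animal[i]!r}"
                    )
                out[i] = j
            if sire_idx[i] != -1 and sire_idx[i] == dam_idx[i]:
                raise ValueError(
                    f"animal {self.animal[i]!r} has identical sire and dam"
                )
        self.sire_idx = sire_idx
        self.dam_idx = dam_idx

    def __len__(self) -> int:
        return len(self.animal)

    @property
    def n_animals(self) -> int:
        return len(self.animal)

    def index_of(self, ids) -> np.ndarray:
        """Positions of the given animal ids in pedigree order."""
        pos = {a: i for i, a in enumerate(self.animal)}
        try:
            return np.array([pos[a] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal id {exc.args[0]!r} not in pedigree") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal, "sire": self.sire, "dam": self.dam}
        )


@dataclass
class GenotypeMatrix:
    """Allele counts per animal x SNP plus the SNP map.

    ``calls[i, j]`` counts the A1 allele of SNP j in animal i (0/1/2, nan for
    missing). ``genotyped`` marks the animals whose genotypes are observed;
    rows for non-genotyped animals hold the simulated truth (used only by the
    phenotype simulator) and are excluded from G by :meth:`observed`.
    """

    calls: np.ndarray
    animal_ids: np.ndarray
    snp_map: pd.DataFrame  # columns: snp_id, chrom, pos_bp
    genotyped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.float64)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (animals x SNPs)")
        if self.calls.shape[0] != len(self.animal_ids):
            raise ValueError("row count of calls != number of animal ids")
        if self.calls.shape[1] != len(self.snp_map):
            raise ValueError("column count of calls != SNP map length")
        required = {"snp_id", "chrom", "pos_bp"}
        if not required.issubset(self.snp_map.columns):
            raise ValueError(f"snp_map must have columns {sorted(required)}")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["pos_bp"].is_monotonic_increasing or grp["pos_bp"].duplicated().any():
                raise ValueError(
                    f"positions on chromosome {chrom} not strictly increasing"
                )
        # raw calls are 0/1/2; mean-imputed calls may be fractional in [0, 2]
        valid = np.isnan(self.calls) | ((self.calls >= 0.0) & (self.calls <= 2.0))
        if not valid.all():
            raise ValueError("calls must lie in [0, 2] or be missing (nan)")
        if self.genotyped is not None:
            self.genotyped = np.asarray(self.genotyped, dtype=bool)
            if self.genotyped.shape != (self.calls.shape[0],):
                raise ValueError("genotyped mask length != number of animals")

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def observed(self) -> "GenotypeMatrix":
        """Submatrix of the animals marked genotyped (all, if no mask)."""
        if self.genotyped is None:
            return self
        return GenotypeMatrix(
            calls=self.calls[self.genotyped],
            animal_ids=self.animal_ids[self.genotyped],
            snp_map=self.snp_map.reset_index(drop=True),
            genotyped=None,
        )

    def allele_freqs(self) -> np.ndarray:
        """Observed A1 allele frequency per SNP (missing calls ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0


@dataclass
class PhenotypeTable:
    """Trait records plus, for simulated data, a truth side-channel.

    ``data`` columns: animal_id, trait_value, contemporary_group,
    slaughter_age (days). ``true_breeding_values`` maps animal_id -> TBV and
    ``true_variances`` holds the simulation's variance components; both are
    None for real data.
    """

    data: pd.DataFrame
    trait: str = "trait"
    true_breeding_values: pd.Series | None = None
    true_variances: dict | None = None

    def __post_init__(self) -> None:
        required = {"animal_id", "trait_value", "contemporary_group", "slaughter_age"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        if self.data["animal_id"].duplicated().any():
            raise ValueError("an animal has more than one record for this trait")
        if (self.data["slaughter_age"] <= 0).any():
            raise ValueError("slaughter ages must be positive")

    def __len__(self) -> int:
        return len(self.data)
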