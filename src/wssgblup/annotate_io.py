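"""Readers, writers, and region-to-gene annotation.

Formats: pedigree CSV (animal,sire,dam; "0" = unknown parent), PLINK-style
.ped/.map and a simple allele-count TSV dialect for genotypes, phenotype TSV
(with an optional truth sidecar for simulated data), GFF3 gene annotation,
and the window/Manhattan TSV outputs. All coordinates are 1-based inclusive
(GFF3 / map convention). Readers reject malformed rows with line numbers
rather than coercing silently; every writer round-trips with its reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, PedigreeTable, PhenotypeTable

# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def write_pedigree_csv(ped: PedigreeTable, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str).fillna("0")
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"pedigree CSV missing column {col!r}")
    return PedigreeTable(
        animal=df["animal"].to_numpy(dtype=object),
        sire=df["sire"].to_numpy(dtype=object),
        dam=df["dam"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_count_tsv(geno: GenotypeMatrix, prefix) -> None:
    """Allele-count dialect: <prefix>.counts.tsv (animal_id, genotyped flag,
    then one integer column per SNP, NA = missing) + <prefix>.map.tsv."""
    prefix = Path(prefix)
    calls = geno.calls
    df = pd.DataFrame(
        {"animal_id": geno.animal_ids,
         "genotyped": (np.ones(geno.n_animals, dtype=int)
                       if geno.genotyped is None
                       else geno.genotyped.astype(int))}
    )
    body = pd.DataFrame(calls, columns=geno.snp_map["snp_id"])
    pd.concat([df, body], axis=1).to_csv(
        prefix.with_suffix(".counts.tsv"), sep="\t", index=False,
        na_rep="NA", float_format="%.10g",
    )
    geno.snp_map.to_csv(prefix.with_suffix(".map.tsv"), sep="\t", index=False)


def read_count_tsv(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t",
                     na_values=["NA"])
    snp_map = pd.read_csv(prefix.with_suffix(".map.tsv"), sep="\t",
                          dtype={"chrom": str})
    calls = df.drop(columns=["animal_id", "genotyped"]).to_numpy(dtype=float)
    if calls.shape[1] != len(snp_map):
        raise ValueError(
            f"count file has {calls.shape[1]} SNP columns but map lists "
            f"{len(snp_map)}"
        )
    return GenotypeMatrix(
        calls=calls,
        animal_ids=df["animal_id"].astype(str).to_numpy(dtype=object),
        snp_map=snp_map,
        genotyped=df["genotyped"].to_numpy(dtype=bool),
    )


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """PLINK-style .ped/.map. A1 = 'A', A2 = 'B'; missing = '0 0'.

    Only the genotyped animals are written (a .ped file holds observed
    calls, not simulation truth).
    """
    prefix = Path(prefix)
    obs = geno.observed()
    code = {0.0: ("B", "B"), 1.0: ("A", "B"), 2.0: ("A", "A")}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, aid in enumerate(obs.animal_ids):
            fields = ["FAM", str(aid), "0", "0", "0", "-9"]
            for c in obs.calls[i]:
                a1, a2 = ("0", "0") if np.isnan(c) else code[c]
                fields.append(a1)
                fields.append(a2)
            fh.write(" ".join(fields) + "\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in geno.snp_map.iterrows():
            fh.write(f"{row.chrom} {row.snp_id} 0 {row.pos_bp}\n")


def read_plink(prefix) -> GenotypeMatrix:
    """Read .ped/.map; calls count the A1 ('A') allele; '0 0' = missing."""
    prefix = Path(prefix)
    snp_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{prefix}.map line {ln}: expected 4 fields")
            snp_rows.append((parts[1], parts[0], int(parts[3])))
    snp_map = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos_bp"])
    m = len(snp_map)
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * m} fields "
                    f"for {m} map SNPs, got {len(parts)}"
                )
            ids.append(parts[1])
            alleles = parts[6:]
            row = np.empty(m)
            for j in range(m):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    row[j] = np.nan
                else:
                    row[j] = (a1 == "A") + (a2 == "A")
            rows.append(row)
    return GenotypeMatrix(
        calls=np.vstack(rows) if rows else np.empty((0, m)),
        animal_ids=np.array(ids, dtype=object),
        snp_map=snp_map, genotyped=None,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes_tsv(phen: PhenotypeTable, path, truth_path=None) -> None:
    phen.data.to_csv(path, sep="\t", index=False)
    if truth_path is not None and phen.true_breeding_values is not None:
        tdf = pd.DataFrame(
            {"animal_id": phen.true_breeding_values.index,
             "true_bv": phen.true_breeding_values.to_numpy()}
        )
        for k, v in (phen.true_variances or {}).items():
            if np.isscalar(v):
                tdf[k] = v
        tdf.to_csv(truth_path, sep="\t", index=False)


def read_phenotypes_tsv(path, trait: str = "trait") -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str,
                                            "contemporary_group": str})
    return PhenotypeTable(data=df, trait=trait)


# ---------------------------------------------------------------------------
# GFF3 genes and region annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    gene_id: str
    name: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start_bp} > end {self.end_bp}"
            )


def read_gff3_genes(path, feature_types=("gene",)) -> list[GeneRecord]:
    """Minimal GFF3 reader returning gene-type features.

    Only seqid/type/start/end/strand and the ID/Name attributes are used;
    malformed lines raise with their line number.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}: line {ln}: expected 9 tab-separated GFF3 "
                    f"columns, got {len(parts)}"
                )
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in feature_types:
                continue
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ValueError(
                    f"{path}: line {ln}: non-integer coordinates"
                ) from None
            adict = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    adict[k.strip()] = v.strip()
            gid = adict.get("ID", f"line{ln}")
            genes.append(GeneRecord(
                gene_id=gid, name=adict.get("Name", gid),
                chromosome=seqid, start_bp=s, end_bp=e, strand=strand,
            ))
    return genes


NO_GENE = "none"


def annotate_regions(regions: pd.DataFrame, genes, flank_bp: int = 0
                     ) -> pd.DataFrame:
    """Attach overlapping genes to each selected window.

    ``genes`` is a GFF3 path or a list of :class:`GeneRecord`. Overlap is on
    closed intervals after widening each gene by ``flank_bp`` on both sides;
    strand is ignored. Regions with no overlapping gene get the explicit
    marker ``"none"``. One output row per (region, gene) pair.
    """
    if not isinstance(genes, (list, tuple)):
        genes = read_gff3_genes(genes)
    rows = []
    for _, reg in regions.iterrows():
        hits = [
            g for g in genes
            if str(g.chromosome) == str(reg["chrom"])
            and g.start_bp - flank_bp <= reg["end_bp"]
            and g.end_bp + flank_bp >= reg["start_bp"]
        ]
        if not hits:
            rows.append({**reg.to_dict(), "gene_id": NO_GENE,
                         "gene_name": NO_GENE, "gene_start_bp": pd.NA,
                         "gene_end_bp": pd.NA})
        for g in hits:
            rows.append({**reg.to_dict(), "gene_id": g.gene_id,
                         "gene_name": g.name, "gene_start_bp": g.start_bp,
                         "gene_end_bp": g.end_bp})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Manhattan export
# ---------------------------------------------------------------------------

def export_manhattan(report: pd.DataFrame, path, plot_path=None) -> pd.DataFrame:
    """Write a Manhattan-ready TSV (cumulative genome coordinate per window).

    Chromosomes are laid out in their order of appearance; each one's offset
    is the running sum of the previous chromosomes' spans. Optionally renders
    a PNG with the percent of additive variance per window.
    """
    df = report.copy()
    offset = 0
    cum = np.empty(len(df), dtype=np.int64)
    for chrom in df["chrom"].drop_duplicates():
        mask = (df["chrom"] == chrom).to_numpy()
        pos = df.loc[mask, "start_bp"].to_numpy()
        cum[mask] = pos + offset
        offset += int(df.loc[mask, "end_bp"].max())
    df["cum_bp"] = cum
    out = df[["cum_bp", "chrom", "start_bp", "end_bp", "n_snps",
              "pct_variance"]]
    out.to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(10, 3))
        for k, (chrom, grp) in enumerate(df.groupby("chrom", sort=False)):
            ax.scatter(grp["cum_bp"], grp["pct_variance"], s=8,
                       color=f"C{k % 2}")
        ax.set_xlabel("genome position")
        ax.set_ylabel("% additive genetic variance")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return out
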