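"""Readers and writers for genotypes, phenotypes, interval tables and kernels.

Supported formats are deliberately plain text: the PLINK 1.x ``.ped``/``.map``
dialect for genotypes, headered TSV for everything else, and a square-matrix
TSV (header row of individual ids) for relationship matrices so they can be
exchanged with external REML tools.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    GeneRecord,
    GeneSet,
    GenotypeMatrix,
    PhenotypeTable,
    QTLRecord,
    ValidationError,
)

__all__ = [
    "read_plink_text",
    "write_plink_text",
    "read_gene_table",
    "read_qtl_table",
    "read_gene_sets",
    "read_tables",
    "read_phenotypes",
    "align_samples",
    "write_kinship_tsv",
    "read_kinship_tsv",
    "read_plink_genome",
]


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1.x text fileset into a dosage matrix.

    Dosages count the minor allele as estimated from the file itself; a
    frequency tie at 0.5 is broken lexicographically by allele symbol so the
    coding is reproducible.  The PLINK missing genotype ``0 0`` maps to the
    missing sentinel.  SNP order follows the ``.map`` file.  Monomorphic SNPs
    are kept but reported with a warning.
    """
    snp_map = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    m = len(snp_map)
    individual_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValidationError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * m} for {m} SNPs"
                )
            individual_ids.append(fields[1])
            allele_rows.append(fields[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(individual_ids), m, 2)

    calls = np.full((len(individual_ids), m), MISSING, dtype=np.int16)
    counted: list[str] = []
    for j in range(m):
        a = alleles[:, j, :]
        observed = a[a != "0"]
        symbols, counts = np.unique(observed, return_counts=True)
        if len(symbols) > 2:
            raise ValidationError(
                f"SNP {snp_map.snp_id[j]!r} has {len(symbols)} alleles; "
                "only biallelic SNPs are supported"
            )
        if len(symbols) == 0:  # entirely missing column
            counted.append("0")
            continue
        # minor allele = lower count; ties broken by allele symbol
        order = np.lexsort((symbols, counts))
        minor = symbols[order[0]]
        counted.append(str(minor))
        nonmissing = np.all(a != "0", axis=1)
        dose = (a == minor).sum(axis=1)
        calls[nonmissing, j] = dose[nonmissing]
        if len(symbols) == 1:
            warnings.warn(
                f"SNP {snp_map.snp_id[j]!r} is monomorphic", stacklevel=2
            )

    positions = snp_map.set_index("snp_id")[["chrom", "pos"]]
    return GenotypeMatrix(
        individual_ids=individual_ids,
        snp_ids=list(snp_map.snp_id),
        calls=calls,
        snp_positions=positions,
        counted_alleles=counted,
    )


def write_plink_text(
    G: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dosage matrix as a PLINK text fileset with generic A/B alleles.

    Per column the counted allele's symbol is chosen so that the reader's
    minor-allele rule recovers the dosages: "B" when the counted allele is
    the rarer one, "A" at an exact frequency tie (the reader's tie-break
    picks the lexicographically smaller symbol).  A column whose counted
    allele is the *major* allele cannot survive the round trip — the reader
    will count the complementary allele — so it triggers a warning; recode
    with :meth:`GenotypeMatrix.minor_allele_coded` first.
    """
    with open(map_path, "w") as fh:
        for j, snp in enumerate(G.snp_ids):
            if G.snp_positions is not None:
                chrom = str(G.snp_positions.iloc[j]["chrom"])
                pos = int(G.snp_positions.iloc[j]["pos"])
            else:
                chrom, pos = "1", j + 1
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\n")
    freq = G.allele_frequencies()
    if np.any(freq > 0.5):
        warnings.warn(
            f"{int((freq > 0.5).sum())} column(s) count the major allele; "
            "reading the file back will recode them to the minor allele",
            stacklevel=2,
        )
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(G.individual_ids):
            fields = [ind, ind, "0", "0", "0", "-9"]
            for j in range(G.n_snps):
                counted, other = ("A", "B") if freq[j] == 0.5 else ("B", "A")
                pair_for = {
                    0: (other, other),
                    1: (other, counted),
                    2: (counted, counted),
                    MISSING: ("0", "0"),
                }
                fields.extend(pair_for[int(G.calls[i, j])])
            fh.write(" ".join(fields) + "\n")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a gene annotation TSV with columns gene_id, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    _require(df, ["gene_id", "chrom", "start", "end"], path)
    if df.gene_id.duplicated().any():
        dup = df.gene_id[df.gene_id.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    return [
        GeneRecord(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def read_qtl_table(path: str | Path, default_chrom: str = "1") -> list[QTLRecord]:
    """Read a QTL table TSV (QTL_ID, QTL_symbol, Trait_name, QTL_start, QTL_end).

    An optional ``chrom`` column overrides ``default_chrom``; QTL catalogue
    extracts restricted to one chromosome commonly omit it.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require(df, ["QTL_ID", "QTL_symbol", "Trait_name", "QTL_start", "QTL_end"], path)
    if df.QTL_ID.duplicated().any():
        dup = df.QTL_ID[df.QTL_ID.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate QTL_ID {dup!r}")
    records = []
    for r in df.itertuples():
        chrom = str(getattr(r, "chrom", default_chrom) or default_chrom)
        records.append(
            QTLRecord(
                qtl_id=str(r.QTL_ID),
                qtl_symbol=str(r.QTL_symbol),
                trait_name=str(r.Trait_name),
                start=int(r.QTL_start),
                end=int(r.QTL_end),
                chrom=chrom,
            )
        )
    return records


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read a gene-set membership TSV with columns set, gene_id [, snp_id]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        warnings.warn(f"{path}: empty gene-set file", stacklevel=2)
        return {}
    _require(df, ["set", "gene_id"], path)
    sets: dict[str, GeneSet] = {}
    for name, grp in df.groupby("set", sort=True):
        snps = (
            [s for s in grp["snp_id"].dropna().unique()] if "snp_id" in grp else []
        )
        sets[str(name)] = GeneSet(
            name=str(name),
            gene_ids=[str(g) for g in grp.gene_id.dropna().unique()],
            snp_ids=[str(s) for s in snps],
        )
    return sets


def read_tables(
    genes_path: str | Path, qtl_path: str | Path, geneset_path: str | Path
) -> tuple[list[GeneRecord], list[QTLRecord], dict[str, GeneSet]]:
    """Read the three annotation tables used by the co-localization pipeline."""
    return (
        read_gene_table(genes_path),
        read_qtl_table(qtl_path),
        read_gene_sets(geneset_path),
    )


def read_phenotypes(
    path: str | Path,
    traits: list[str] | None = None,
    covariates: list[str] | None = None,
    id_column: str = "id",
) -> PhenotypeTable:
    """Read a phenotype TSV keyed by an id column.

    When ``traits`` is not given, every numeric non-covariate column is
    treated as a trait.  Missing trait values stay as NaN and are flagged by
    the model layer, never silently dropped here.
    """
    df = pd.read_csv(path, sep="\t", dtype={id_column: str})
    _require(df, [id_column], path)
    df = df.set_index(id_column)
    covariates = list(covariates or [])
    if traits is None:
        traits = [
            c
            for c in df.columns
            if c not in covariates and pd.api.types.is_numeric_dtype(df[c])
        ]
    return PhenotypeTable(data=df, trait_names=list(traits), covariate_names=covariates)


def align_samples(
    G: GenotypeMatrix, P: PhenotypeTable
) -> tuple[GenotypeMatrix, PhenotypeTable, int]:
    """Intersect and co-order a genotype matrix and phenotype table by id.

    Returns the aligned pair plus the number of identifiers dropped from
    either side.  The common order is the genotype matrix's order restricted
    to the intersection, so the result is independent of the phenotype row
    order.
    """
    geno_ids = G.individual_ids
    pheno_ids = set(P.individual_ids)
    common = [i for i in geno_ids if i in pheno_ids]
    if not common:
        raise ValidationError("no overlapping individual ids between genotypes and phenotypes")
    dropped = (len(geno_ids) - len(common)) + (len(pheno_ids) - len(common))
    G2 = G.subset_individuals(common)
    P2 = PhenotypeTable(
        data=P.data.loc[common],
        trait_names=list(P.trait_names),
        covariate_names=list(P.covariate_names),
    )
    return G2, P2, dropped


def write_kinship_tsv(matrix: np.ndarray, individual_ids: list[str], path: str | Path) -> None:
    """Write a square relationship matrix as TSV with an id header row."""
    pd.DataFrame(matrix, index=individual_ids, columns=individual_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_kinship_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ValidationError(f"{path}: row and column ids differ")
    return df.to_numpy(dtype=float), ids


def read_plink_genome(path: str | Path) -> pd.DataFrame:
    """Read pairwise IBD-sharing estimates from a PLINK ``.genome`` file.

    Returns a DataFrame with columns IID1, IID2, Z0, Z1, Z2 (probabilities of
    sharing 0/1/2 alleles identical by descent) so externally computed
    estimates can feed the kernel builders.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"IID1": str, "IID2": str})
    _require(df, ["IID1", "IID2", "Z0", "Z1", "Z2"], path)
    return df[["IID1", "IID2", "Z0", "Z1", "Z2"]]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
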