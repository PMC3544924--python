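"""Core domain containers for gene-set association analysis.

The package works on four kinds of tabular data: SNP genotypes coded as
counted-allele dosages, phenotype/covariate tables, genomic interval
records (genes and QTL confidence intervals), and gene-set membership.
All genomic coordinates are 1-based inclusive base pairs; chromosome
labels are strings (sex chromosomes such as "X" are valid labels and are
never coerced to numbers).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved dosage code for a missing genotype call.  Kept as an explicit
#: integer sentinel (not NaN) so that dosage matrices stay integer typed and
#: missingness is handled deliberately, pairwise, by downstream consumers.
MISSING = -9


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-dosage matrix.

    Parameters
    ----------
    individual_ids : list of str
        Unique sample identifiers, one per row of ``calls``.
    snp_ids : list of str
        Unique SNP identifiers, one per column of ``calls``.
    calls : ndarray of int
        Dosage of the counted allele, coded 0/1/2, with :data:`MISSING`
        marking no-calls.
    snp_positions : DataFrame, optional
        Per-SNP ``chrom`` (str) and ``pos`` (1-based int), indexed by SNP id.
    counted_alleles : list of str, optional
        The allele whose copies are counted, per SNP (minor allele when the
        matrix was read from a PLINK text fileset).
    """

    individual_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    snp_positions: pd.DataFrame | None = None
    counted_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D matrix")
        n, m = self.calls.shape
        if n != len(self.individual_ids):
            raise ValidationError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if m != len(self.snp_ids):
            raise ValidationError(f"{len(self.snp_ids)} snp ids for {m} columns")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("individual ids are not unique")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("snp ids are not unique")
        ok = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not np.all(ok):
            bad = np.argwhere(~ok)[0]
            raise ValidationError(
                f"dosage at ({bad[0]}, {bad[1]}) is {self.calls[tuple(bad)]}, "
                "expected 0/1/2 or the missing sentinel"
            )

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the call is missing."""
        return self.calls == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Counted-allele frequency per SNP, excluding missing calls.

        Monomorphic columns yield 0 or 1; columns that are entirely missing
        yield NaN.
        """
        calls = self.calls.astype(float)
        calls[self.missing_mask()] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(calls, axis=0) / 2.0

    def polymorphic_mask(self) -> np.ndarray:
        freq = self.allele_frequencies()
        return (freq > 0) & (freq < 1)

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        """Column subset preserving the requested SNP order."""
        index = {s: j for j, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown SNP ids: {missing[:5]}")
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            snp_ids=list(snp_ids),
            calls=self.calls[:, cols],
            snp_positions=(
                self.snp_positions.loc[snp_ids] if self.snp_positions is not None else None
            ),
            counted_alleles=(
                [self.counted_alleles[c] for c in cols] if self.counted_alleles else None
            ),
        )

    def minor_allele_coded(self) -> "GenotypeMatrix":
        """Copy with every column recoded to count the minor allele.

        Columns whose counted-allele frequency exceeds 0.5 are flipped
        (dosage -> 2 - dosage); this is the coding ``read_plink_text``
        produces, and the coding under which a write/read round trip is
        exact.  Allele symbols are dropped for flipped data since the
        complementary symbol is not stored.
        """
        freq = self.allele_frequencies()
        flip = freq > 0.5
        calls = self.calls.copy()
        missing = self.missing_mask()
        calls[:, flip] = 2 - calls[:, flip]
        calls[missing] = MISSING
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            snp_ids=list(self.snp_ids),
            calls=calls,
            snp_positions=self.snp_positions,
            counted_alleles=None if flip.any() else self.counted_alleles,
        )

    def subset_individuals(self, individual_ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.individual_ids)}
        missing = [s for s in individual_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown individual ids: {missing[:5]}")
        rows = [index[s] for s in individual_ids]
        return dataclasses.replace(
            self, individual_ids=list(individual_ids), calls=self.calls[rows, :]
        )


@dataclass
class PhenotypeTable:
    """Phenotypes and categorical covariates keyed by individual id."""

    data: pd.DataFrame
    trait_names: list[str]
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate individual ids in phenotype table")
        for col in list(self.trait_names) + list(self.covariate_names):
            if col not in self.data.columns:
                raise ValidationError(f"column {col!r} absent from phenotype table")
        for cov in self.covariate_names:
            levels = self.data[cov].dropna().unique()
            if len(levels) < 1:
                raise ValidationError(f"covariate {cov!r} has no observed level")

    @property
    def individual_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def trait(self, name: str) -> pd.Series:
        if name not in self.trait_names:
            raise ValidationError(f"unknown trait {name!r}")
        return self.data[name].astype(float)


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval: 1-based inclusive coordinates on a named chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: coordinates must be positive")


@dataclass(frozen=True)
class QTLRecord:
    """A QTL confidence interval as catalogued in animal QTL databases."""

    qtl_id: str
    qtl_symbol: str
    trait_name: str
    start: int
    end: int
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"QTL {self.qtl_id}: start {self.start} > end {self.end}"
            )


@dataclass
class GeneSet:
    """A named, functionally related group of genes and their assigned SNPs."""

    name: str
    gene_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"gene set {self.name!r}: duplicate gene ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError(f"gene set {self.name!r}: duplicate snp ids")
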