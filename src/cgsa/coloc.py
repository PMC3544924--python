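"""SNP-to-gene assignment and gene-QTL co-localization.

Candidate genes are prioritized by overlap with QTL confidence intervals
from a QTL catalogue: a gene whose interval falls inside (or intersects)
the confidence interval of a QTL for a physiologically relevant trait is a
primary candidate, the more so when it overlaps many QTL.  All interval
arithmetic is on 1-based inclusive coordinates; two intervals overlap iff
``start1 <= end2 and start2 <= end1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datatypes import GeneRecord, QTLRecord, ValidationError

__all__ = [
    "GeneQTLMatch",
    "OverlapReport",
    "assign_snps_to_genes",
    "colocalize",
    "rank_by_multiplicity",
]

DEFAULT_FLANK_BP = 50_000


@dataclass(frozen=True)
class GeneQTLMatch:
    gene_id: str
    qtl: QTLRecord
    contained: bool  # gene interval entirely inside the QTL interval


@dataclass
class OverlapReport:
    """Per-gene QTL matches plus notes for genes with no testable records."""

    matches: dict[str, list[GeneQTLMatch]]
    notes: dict[str, str] = field(default_factory=dict)
    mode: str = "overlap"

    def count(self, gene_id: str) -> int:
        return len(self.matches.get(gene_id, []))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene_id in sorted(self.matches):
            for m in self.matches[gene_id]:
                rows.append(
                    {
                        "gene_id": gene_id,
                        "QTL_ID": m.qtl.qtl_id,
                        "QTL_symbol": m.qtl.qtl_symbol,
                        "Trait_name": m.qtl.trait_name,
                        "QTL_start": m.qtl.start,
                        "QTL_end": m.qtl.end,
                        "mode": "gene-contained-in-QTL" if m.contained else "partial",
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "QTL_ID",
                "QTL_symbol",
                "Trait_name",
                "QTL_start",
                "QTL_end",
                "mode",
            ],
        )


def assign_snps_to_genes(
    snp_positions: pd.DataFrame,
    genes: list[GeneRecord],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> tuple[dict[str, list[str]], list[str]]:
    """Assign SNPs to genes within a symmetric flanking window.

    A SNP is assigned to gene g when the chromosome labels match and its
    position lies in ``[start - flank_bp, end + flank_bp]`` (inclusive on
    both ends, floored at 1).  A SNP may be assigned to several genes.

    Parameters
    ----------
    snp_positions : DataFrame indexed by snp_id with columns chrom, pos
    genes : list of GeneRecord
    flank_bp : int
        Upstream/downstream window; the conventional choice for sparse
        livestock panels is 50 kb.

    Returns
    -------
    (assignments, unassigned) : dict snp_id -> gene ids, and the list of
    SNPs that hit no gene.
    """
    if flank_bp < 0:
        raise ValidationError("flank_bp must be >= 0")
    assignments: dict[str, list[str]] = {}
    unassigned: list[str] = []
    for snp_id, row in snp_positions.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        hits = [
            g.gene_id
            for g in genes
            if g.chrom == chrom and max(1, g.start - flank_bp) <= pos <= g.end + flank_bp
        ]
        if hits:
            assignments[str(snp_id)] = hits
        else:
            unassigned.append(str(snp_id))
    return assignments, unassigned


def colocalize(
    genes: list[GeneRecord],
    qtl_records: list[QTLRecord],
    mode: str = "overlap",
    max_qtl_width: int | None = None,
) -> OverlapReport:
    """Match candidate genes against QTL confidence intervals.

    Parameters
    ----------
    mode : {"overlap", "containment"}
        "overlap" counts any non-empty intersection; "containment" requires
        the gene interval to lie entirely within the QTL interval.
    max_qtl_width : int, optional
        Drop QTL whose confidence interval exceeds this width (end - start
        + 1); some catalogued QTL span most of a chromosome and match almost
        anything.

    A gene whose chromosome never appears in the QTL table is reported with
    zero matches and an explanatory note.  Output order is deterministic:
    genes alphabetically, QTL by ascending numeric-aware QTL_ID.
    """
    if mode not in ("overlap", "containment"):
        raise ValidationError(f"unknown co-localization mode {mode!r}")
    qtls = list(qtl_records)
    if max_qtl_width is not None:
        qtls = [q for q in qtls if (q.end - q.start + 1) <= max_qtl_width]
    qtl_chroms = {q.chrom for q in qtls}

    def qtl_key(q: QTLRecord):
        return (int(q.qtl_id), "") if q.qtl_id.isdigit() else (float("inf"), q.qtl_id)

    matches: dict[str, list[GeneQTLMatch]] = {}
    notes: dict[str, str] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom not in qtl_chroms:
            matches[g.gene_id] = []
            notes[g.gene_id] = f"chromosome {g.chrom!r} absent from the QTL table"
            continue
        found: list[GeneQTLMatch] = []
        seen: set[str] = set()
        for q in sorted(qtls, key=qtl_key):
            if q.chrom != g.chrom or q.qtl_id in seen:
                continue
            overlaps = g.start <= q.end and q.start <= g.end
            contained = q.start <= g.start and g.end <= q.end
            hit = contained if mode == "containment" else overlaps
            if hit:
                found.append(GeneQTLMatch(g.gene_id, q, contained))
                seen.add(q.qtl_id)
        matches[g.gene_id] = found
    return OverlapReport(matches=matches, notes=notes, mode=mode)


def rank_by_multiplicity(report: OverlapReport) -> list[tuple[str, int]]:
    """Genes by descending QTL-overlap count; ties alphabetically."""
    if not report.matches:
        raise ValidationError("empty overlap report")
    return sorted(
        ((g, report.count(g)) for g in report.matches),
        key=lambda item: (-item[1], item[0]),
    )
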