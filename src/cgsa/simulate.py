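"""Synthetic genotype panels and simulated quantitative traits.

The genotype generator draws unlinked biallelic SNPs under Hardy-Weinberg
equilibrium: each SNP gets a counted-allele frequency p uniform over a
configurable MAF range and each individual's dosage is Binomial(2, p).
This emulates a commercial-panel gene-set extract (tens of SNPs on a few
hundred outbred individuals) without linkage disequilibrium; LD-structured
simulation is out of scope.

Two trait designs are provided:

* additive-only: a subset of SNPs act as causal QTNs with effects drawn
  N(0, 1); the residual variance is scaled from the realized (in-sample)
  additive variance s2_a so that the trait has a target heritability h2,
  sigma2_e = s2_a * (1 - h2) / h2.  At h2 = 0 the genetic term is removed
  and the trait is pure N(0, 1) noise (the scaling formula is undefined
  there, and test decisions are scale invariant).
* full: additive + dominance + epistatic effects with a fixed residual
  variance.  Dominance effects act on heterozygotes; an epistatic pair
  contributes its effect only when an individual is heterozygous at both
  members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, ValidationError

__all__ = [
    "SimScenario",
    "SimulatedTrait",
    "simulate_genotypes",
    "simulate_additive_trait",
    "simulate_full_trait",
    "sample_qtns",
    "load_effect_table",
    "default_effect_table",
]


@dataclass
class SimScenario:
    """Parameters of a replicate study.

    Defaults mirror the study conditions used throughout the package: a
    57-SNP gene-set panel, MAF uniform on [0.05, 0.5], 15 additive QTNs,
    and heritability levels {0, 0.05, 0.1, 0.25, 0.5}.  ``n=300`` and
    ``n_replicates=500`` are the desk-scale profile; pass ``n=820`` and
    ``n_replicates=1000`` for the full-scale one.
    """

    n: int = 300
    m: int = 57
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtn: int = 15
    h2_levels: tuple[float, ...] = (0.0, 0.05, 0.1, 0.25, 0.5)
    n_replicates: int = 500
    seed: int = 0
    redraw_effects: bool = True
    # experiment-2 style extras
    effect_table: pd.DataFrame | None = None
    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    residual_var: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range {self.maf_range} not within (0, 0.5]")
        if self.n_replicates < 1:
            raise ValidationError("replicate count must be >= 1")
        for h2 in self.h2_levels:
            if not (0 <= h2 < 1):
                raise ValidationError(f"heritability {h2} outside [0, 1)")
        members = [m for p in self.pairs for m in p[:2]]
        if len(set(members)) != len(members):
            raise ValidationError("epistatic pairs must be disjoint")


@dataclass
class SimulatedTrait:
    """A simulated phenotype with its latent genetic decomposition."""

    phenotype: np.ndarray
    genetic_value: np.ndarray
    realized_additive_var: float
    residual_var: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.phenotype.shape != self.genetic_value.shape:
            raise ValidationError("phenotype/genetic value length mismatch")


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator | None = None,
) -> GenotypeMatrix:
    """HWE genotype panel: dosages Binomial(2, p), p ~ U(maf_range), no LD."""
    if n < 2 or m < 1:
        raise ValidationError("need n >= 2 individuals and m >= 1 SNPs")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValidationError(f"maf_range {maf_range} not within (0, 0.5]")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=m)
    calls = rng.binomial(2, freqs[None, :], size=(n, m)).astype(np.int16)
    positions = pd.DataFrame(
        {"chrom": "1", "pos": (np.arange(m) + 1) * 1000},
        index=[f"snp{j + 1}" for j in range(m)],
    )
    return GenotypeMatrix(
        individual_ids=[f"ind{i + 1}" for i in range(n)],
        snp_ids=list(positions.index),
        calls=calls,
        snp_positions=positions,
    )


def sample_qtns(
    G: GenotypeMatrix, n_qtn: int, seed: int | np.random.Generator | None = None
) -> list[str]:
    """Sample causal QTN ids uniformly without replacement from the panel."""
    if n_qtn > G.n_snps:
        raise ValidationError(f"cannot sample {n_qtn} QTNs from {G.n_snps} SNPs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(G.n_snps, size=n_qtn, replace=False)
    return [G.snp_ids[j] for j in sorted(idx)]


def _dosage_columns(G: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    sub = G.subset_snps(list(snp_ids))
    calls = sub.calls.astype(float)
    calls[sub.missing_mask()] = np.nan
    # mean-impute missing dosages for trait construction
    col_mean = np.nanmean(calls, axis=0)
    nan_idx = np.where(np.isnan(calls))
    calls[nan_idx] = np.take(col_mean, nan_idx[1])
    return calls


def simulate_additive_trait(
    G: GenotypeMatrix,
    qtn_ids: list[str],
    h2: float,
    seed: int | np.random.Generator | None = None,
    effects: np.ndarray | None = None,
) -> SimulatedTrait:
    """Additive-only trait at target heritability h2.

    Per-QTN effects are N(0, 1) unless supplied.  The residual variance is
    sigma2_e = s2_a (1 - h2) / h2 with s2_a the realized in-sample variance
    of the genetic values, so the in-sample heritability is close to h2 by
    construction.  h2 = 0 yields pure N(0, 1) noise.
    """
    if not (0 <= h2 < 1):
        raise ValidationError(f"heritability {h2} outside [0, 1)")
    if not qtn_ids:
        raise ValidationError("qtn_ids must be non-empty")
    rng = np.random.default_rng(seed)
    n = G.n_individuals
    if h2 == 0.0:
        noise = rng.standard_normal(n)
        return SimulatedTrait(
            phenotype=noise,
            genetic_value=np.zeros(n),
            realized_additive_var=0.0,
            residual_var=1.0,
        )
    dosages = _dosage_columns(G, qtn_ids)
    if np.all(dosages == dosages[:1, :]):
        raise ValidationError("all QTNs monomorphic: zero additive variance")
    beta = rng.standard_normal(len(qtn_ids)) if effects is None else np.asarray(effects, float)
    g = dosages @ beta
    s2_a = float(np.var(g, ddof=1))
    if s2_a <= 0:
        raise ValidationError("QTN effects yield zero additive variance")
    sigma2_e = s2_a * (1.0 - h2) / h2
    residual = rng.normal(0.0, np.sqrt(sigma2_e), size=n)
    return SimulatedTrait(
        phenotype=g + residual,
        genetic_value=g,
        realized_additive_var=s2_a,
        residual_var=sigma2_e,
    )


def simulate_full_trait(
    G: GenotypeMatrix,
    scenario: SimScenario,
    seed: int | np.random.Generator | None = None,
) -> SimulatedTrait:
    """Additive + dominance + pairwise-epistatic trait with fixed residual.

    The effect table (columns ``snp_id``, ``additive``, ``dominance``) lists
    the causal QTNs; ``scenario.pairs`` lists (snp1, snp2, effect) triples
    whose effect is expressed only in individuals heterozygous at both
    members.  The residual is N(0, scenario.residual_var).
    """
    table = scenario.effect_table
    if table is None:
        table = default_effect_table()
        table = table[table.snp_id.isin(G.snp_ids)]
        if table.empty:
            raise ValidationError("effect table covers no SNP of this panel")
    for col in ("snp_id", "additive", "dominance"):
        if col not in table.columns:
            raise ValidationError(f"effect table missing column {col!r}")
    qtn_ids = [str(s) for s in table.snp_id]
    for s1, s2, _ in scenario.pairs:
        if s1 not in qtn_ids or s2 not in qtn_ids:
            raise ValidationError(f"pair member not in QTN list: ({s1}, {s2})")
    rng = np.random.default_rng(seed)
    dosages = _dosage_columns(G, qtn_ids)
    het = np.isclose(dosages, 1.0)

    g = dosages @ table.additive.to_numpy(float)
    g = g + het @ table.dominance.to_numpy(float)
    col = {s: j for j, s in enumerate(qtn_ids)}
    for s1, s2, effect in scenario.pairs:
        g = g + float(effect) * (het[:, col[s1]] & het[:, col[s2]])
    residual = rng.normal(0.0, np.sqrt(scenario.residual_var), size=G.n_individuals)
    add_only = dosages @ table.additive.to_numpy(float)
    return SimulatedTrait(
        phenotype=g + residual,
        genetic_value=g,
        realized_additive_var=float(np.var(add_only, ddof=1)),
        residual_var=float(scenario.residual_var),
    )


def load_effect_table(path: str | Path) -> pd.DataFrame:
    """Read a QTN effect table TSV (snp_id, additive, dominance)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str})
    for col in ("snp_id", "additive", "dominance"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df


def default_effect_table() -> pd.DataFrame:
    """Packaged synthetic default effect table for the full-trait design.

    13 QTNs with additive effects drawn once from N(0, 1) and dominance
    effects from N(0, 0.5); see ``cgsa/data/effects_full_trait_synthetic.tsv``.
    Override with your own TSV via :func:`load_effect_table`.
    """
    ref = resources.files("cgsa.data").joinpath("effects_full_trait_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_effect_table(path)


def default_pairs() -> list[tuple[str, str, float]]:
    """Three synthetic interacting QTN pairs with unit-magnitude effects."""
    return [("snp3", "snp11", 1.0), ("snp17", "snp24", -1.0), ("snp30", "snp42", 1.0)]
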