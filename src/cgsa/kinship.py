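"""Gene-set relationship matrices from pairwise IBD-sharing probabilities.

The additive kernel A and dominance kernel D are built from
method-of-moments estimates of the probabilities that a pair of individuals
shares 0, 1 or 2 alleles identical by descent (IBD), estimated from the SNPs
assigned to the gene set.  Off-diagonal elements are

    A[i, j] = P(IBD=2) + 0.5 * P(IBD=1)        (pi-hat)
    D[i, j] = P(IBD=2)

and epistatic kernels are Hadamard (elementwise) products: AA = A*A,
AD = A*D, DD = D*D.

The moment estimator follows the classic genome-wide IBD screen: observed
identity-by-state (IBS) counts over the pair's non-missing SNPs are equated
to their expectations given sample allele frequencies,

    E[#IBS=s] = sum_m P(IBS=s | IBD=k, p_m)  for k = 0, 1, 2,

and the resulting triangular system is solved for (P0, P1, P2).  Raw
solutions can leave the probability simplex on small panels; they are
clamped at zero and renormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, ValidationError

__all__ = [
    "IBDEstimates",
    "KinshipMatrix",
    "estimate_ibd",
    "additive_matrix",
    "dominance_matrix",
    "hadamard_kernels",
    "gene_set_kernels",
]

KERNEL_KINDS = ("A", "D", "AA", "AD", "DD")


@dataclass
class IBDEstimates:
    """Pairwise P(IBD=0/1/2) for all unordered pairs of a panel.

    ``p0``/``p1``/``p2`` are full n x n symmetric matrices with the sharing
    probabilities; the diagonal is (0, 0, 1) by definition of self-pairs.
    ``informative`` holds the per-pair count of SNPs non-missing in both
    individuals; ``low_confidence`` flags pairs below the requested minimum.
    """

    individual_ids: list[str]
    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    informative: np.ndarray
    low_confidence: np.ndarray
    n_snps_used: int = 0

    @property
    def n(self) -> int:
        return len(self.individual_ids)


@dataclass
class KinshipMatrix:
    """A named n x n relationship matrix over a fixed individual order."""

    kind: str
    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValidationError(f"unknown kernel kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"kernel {self.kind}: shape {self.values.shape} does not match "
                f"{n} individuals"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError(f"kernel {self.kind} is not symmetric")


def _ibs_expectations(freq: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP P(IBS=s | IBD=k) for unrelated-pair allele drawing.

    Returns three (3,)-indexable arrays e0, e1, e2 of shape (3, m):
    ``ek[s, m]`` is P(IBS=s | IBD=k) at SNP m.  States with IBD=1 cannot give
    IBS=0 and IBD=2 always gives IBS=2, so the system is triangular.
    """
    p = freq
    q = 1.0 - p
    e_ibd0 = np.stack(
        [
            2 * p**2 * q**2,
            4 * p**3 * q + 4 * p * q**3,
            p**4 + q**4 + 4 * p**2 * q**2,
        ]
    )
    e_ibd1 = np.stack(
        [
            np.zeros_like(p),
            2 * p**2 * q + 2 * p * q**2,
            p**3 + q**3 + p**2 * q + p * q**2,
        ]
    )
    e_ibd2 = np.stack([np.zeros_like(p), np.zeros_like(p), np.ones_like(p)])
    return e_ibd0, e_ibd1, e_ibd2


def estimate_ibd(
    G: GenotypeMatrix,
    snp_subset: list[str] | None = None,
    min_informative: int = 20,
) -> IBDEstimates:
    """Method-of-moments IBD-sharing estimates for all unordered pairs.

    Parameters
    ----------
    G : GenotypeMatrix
        Dosage panel; allele frequencies are estimated from this same sample.
    snp_subset : list of str, optional
        SNP ids to use (e.g. the gene set's SNPs, or a TagSNP subset).
        Defaults to every SNP in ``G``.
    min_informative : int
        Pairs with fewer jointly non-missing SNPs are flagged low-confidence.

    Monomorphic SNPs carry no IBS information under the moment equations and
    are skipped with a warning.  Each pair's expected IBS counts are summed
    over only the SNPs observed in both of its members (pairwise-complete).
    """
    if G.n_individuals < 2:
        raise ValidationError("IBD estimation needs at least 2 individuals")
    sub = G if snp_subset is None else G.subset_snps(list(snp_subset))
    poly = sub.polymorphic_mask()
    n_mono = int((~poly).sum())
    if n_mono:
        warnings.warn(
            f"skipping {n_mono} monomorphic/all-missing SNP(s) for IBD estimation",
            stacklevel=2,
        )
    sub = sub.subset_snps([s for s, keep in zip(sub.snp_ids, poly) if keep])
    if sub.n_snps == 0:
        raise ValidationError("no polymorphic SNPs available for IBD estimation")

    calls = sub.calls
    observed = ~sub.missing_mask()
    freq = sub.allele_frequencies()

    # indicator matrices per genotype class; missing rows contribute nothing
    h = [((calls == g) & observed).astype(float) for g in (0, 1, 2)]
    obs = observed.astype(float)

    n_pairs_valid = obs @ obs.T
    ibs0 = h[0] @ h[2].T + h[2] @ h[0].T
    ibs2 = h[0] @ h[0].T + h[1] @ h[1].T + h[2] @ h[2].T
    ibs1 = n_pairs_valid - ibs0 - ibs2

    e_ibd0, e_ibd1, e_ibd2 = _ibs_expectations(freq)
    # pairwise-complete expected counts: sum_m e[s,m] * obs_i[m] * obs_j[m]
    def pairsum(v: np.ndarray) -> np.ndarray:
        return (obs * v) @ obs.T

    exp00 = pairsum(e_ibd0[0])
    exp10 = pairsum(e_ibd0[1])
    exp20 = pairsum(e_ibd0[2])
    exp11 = pairsum(e_ibd1[1])
    exp21 = pairsum(e_ibd1[2])
    exp22 = n_pairs_valid  # P(IBS=2 | IBD=2) = 1 at every SNP

    with np.errstate(divide="ignore", invalid="ignore"):
        # sequential back-substitution of the triangular moment equations,
        # bounding each probability to [0, 1] before it feeds the next one
        p0 = np.clip(ibs0 / exp00, 0.0, 1.0)
        p1 = np.clip((ibs1 - p0 * exp10) / exp11, 0.0, 1.0)
        p2 = np.clip((ibs2 - p0 * exp20 - p1 * exp21) / exp22, 0.0, 1.0)
    stacked = np.nan_to_num(np.stack([p0, p1, p2]), nan=0.0, posinf=0.0, neginf=0.0)
    total = stacked.sum(axis=0)
    safe_total = np.where(total > 0, total, 1.0)
    p0, p1, p2 = stacked / safe_total

    n = sub.n_individuals
    diag = np.arange(n)
    for arr, value in ((p0, 0.0), (p1, 0.0), (p2, 1.0)):
        arr[diag, diag] = value

    informative = n_pairs_valid.astype(int)
    low_conf = informative < min_informative
    low_conf[diag, diag] = False
    if low_conf.any():
        warnings.warn(
            f"{int(low_conf.sum() // 2)} pair(s) have fewer than "
            f"{min_informative} informative SNPs",
            stacklevel=2,
        )
    return IBDEstimates(
        individual_ids=list(sub.individual_ids),
        p0=p0,
        p1=p1,
        p2=p2,
        informative=informative,
        low_confidence=low_conf,
        n_snps_used=sub.n_snps,
    )


def additive_matrix(ibd: IBDEstimates, diagonal: float = 1.0) -> KinshipMatrix:
    """Additive kernel: off-diagonal pi-hat = P(IBD=2) + 0.5 P(IBD=1).

    The diagonal is a convention, not a pairwise estimate; the default 1.0
    assumes non-inbred individuals.
    """
    a = ibd.p2 + 0.5 * ibd.p1
    np.fill_diagonal(a, diagonal)
    return KinshipMatrix(kind="A", values=a, individual_ids=list(ibd.individual_ids))


def dominance_matrix(ibd: IBDEstimates, diagonal: float = 1.0) -> KinshipMatrix:
    """Dominance kernel: off-diagonal P(IBD=2); diagonal by convention."""
    d = ibd.p2.copy()
    np.fill_diagonal(d, diagonal)
    return KinshipMatrix(kind="D", values=d, individual_ids=list(ibd.individual_ids))


def hadamard_kernels(
    A: KinshipMatrix, D: KinshipMatrix
) -> dict[str, KinshipMatrix]:
    """Epistatic kernels as Hadamard products of the A and D kernels."""
    if A.values.shape != D.values.shape or A.individual_ids != D.individual_ids:
        raise ValidationError("A and D kernels must share dimension and individual order")
    ids = list(A.individual_ids)
    return {
        "AA": KinshipMatrix("AA", A.values * A.values, ids),
        "AD": KinshipMatrix("AD", A.values * D.values, ids),
        "DD": KinshipMatrix("DD", D.values * D.values, ids),
    }


def gene_set_kernels(
    G: GenotypeMatrix,
    snp_subset: list[str] | None = None,
    kinds: tuple[str, ...] = KERNEL_KINDS,
    min_informative: int = 20,
) -> dict[str, KinshipMatrix]:
    """Convenience: estimate IBD once and build the requested kernels."""
    unknown = [k for k in kinds if k not in KERNEL_KINDS]
    if unknown:
        raise ValidationError(f"unknown kernel kind(s) {unknown}")
    ibd = estimate_ibd(G, snp_subset=snp_subset, min_informative=min_informative)
    A = additive_matrix(ibd)
    D = dominance_matrix(ibd)
    out: dict[str, KinshipMatrix] = {}
    if set(kinds) & {"AA", "AD", "DD"}:
        out.update(hadamard_kernels(A, D))
    out["A"] = A
    out["D"] = D
    return {k: out[k] for k in kinds}
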