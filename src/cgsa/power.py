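"""Replicate power studies: set-level REML test vs single-SNP baseline.

Both methods are evaluated on the same simulated traits (paired,
per-replicate seeds) over a grid of heritabilities:

* the gene-set test fits the additive-kernel mixed model against a
  residual-only null and rejects on the boundary-mixture LRT p-value;
* the traditional candidate-gene baseline regresses the trait on each
  causal QTN's dosage separately and scores the proportion of QTNs whose
  single-SNP p-value passes alpha (optionally Bonferroni-corrected, or an
  any-hit rule).

Power is the mean per-replicate decision (gene-set test) or the mean
detection proportion (baseline); both carry binomial-style Monte-Carlo
standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, ValidationError
from .kinship import KinshipMatrix
from .model import GeneSetMixedModel, SingleKernelWorkspace, lrt
from .simulate import SimScenario, simulate_additive_trait

__all__ = [
    "PowerResult",
    "run_cgsa_power",
    "run_baseline_power",
    "summarize_power",
    "plot_power",
]


@dataclass
class PowerResult:
    """Estimated power of one method under one scenario."""

    method: str
    h2: float
    alpha: float
    n_replicates: int
    power: float
    decisions: np.ndarray = field(repr=False)
    n_excluded: int = 0
    scenario: SimScenario | None = field(default=None, repr=False)

    @property
    def se(self) -> float:
        """Binomial Monte-Carlo standard error of the power estimate."""
        return float(np.sqrt(self.power * (1.0 - self.power) / self.n_replicates))


def _replicate_seeds(base_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(base_seed).spawn(n)


def run_cgsa_power(
    scenario: SimScenario,
    G: GenotypeMatrix,
    kernel: KinshipMatrix | np.ndarray,
    h2: float,
    alpha: float = 0.01,
    qtn_ids: list[str] | None = None,
    exog: np.ndarray | None = None,
) -> PowerResult:
    """Power of the set-level additive LRT at one heritability level.

    The kernel is expected to be precomputed once per genotype panel; its
    eigendecomposition is cached across replicates.  Non-converged replicate
    fits are excluded from the denominator with a reported count (warning
    above 1% exclusions).
    """
    if not (0 < alpha <= 1):
        raise ValidationError(f"alpha {alpha} outside (0, 1]")
    K = kernel.values if isinstance(kernel, KinshipMatrix) else np.asarray(kernel, float)
    if qtn_ids is None:
        qtn_ids = _default_qtns(scenario, G)
    seeds = _replicate_seeds(scenario.seed, scenario.n_replicates)

    # one eigendecomposition amortized over all replicates
    probe = np.random.default_rng(0).standard_normal(G.n_individuals)
    base = GeneSetMixedModel(probe, kernels={"A": K}, exog=exog)
    ws = SingleKernelWorkspace(base)
    null_model_exog = base.exog

    decisions = []
    n_excluded = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        trait = simulate_additive_trait(G, qtn_ids, h2, seed=rng)
        y = trait.phenotype
        full = ws.fit(y)
        null = GeneSetMixedModel(y, kernels={}, exog=null_model_exog).fit()
        if not (full.converged and null.converged):
            n_excluded += 1
            continue
        result = lrt(full, null)
        decisions.append(result.p_value <= alpha)
    if n_excluded > 0.01 * scenario.n_replicates:
        warnings.warn(
            f"{n_excluded} of {scenario.n_replicates} replicates excluded for "
            "non-convergence",
            stacklevel=2,
        )
    decisions = np.asarray(decisions, dtype=float)
    return PowerResult(
        method="CGSA",
        h2=h2,
        alpha=alpha,
        n_replicates=len(decisions),
        power=float(decisions.mean()) if decisions.size else np.nan,
        decisions=decisions,
        n_excluded=n_excluded,
        scenario=scenario,
    )


def run_baseline_power(
    scenario: SimScenario,
    G: GenotypeMatrix,
    h2: float,
    alpha: float = 0.01,
    qtn_ids: list[str] | None = None,
    correction: str = "none",
    any_hit: bool = False,
) -> PowerResult:
    """Power of the single-SNP candidate-gene baseline, paired by seed.

    Each causal QTN is tested by an ordinary linear regression of the trait
    on its dosage; a QTN is detected when its p-value passes alpha under the
    chosen correction ("none" or "bonferroni" across the QTNs).  The
    replicate score is the detected proportion (or, with ``any_hit``, the
    indicator that any QTN was detected).  Monomorphic QTNs are excluded
    from the denominator with a warning.
    """
    if correction not in ("none", "bonferroni"):
        raise ValidationError(f"unknown correction {correction!r}")
    if qtn_ids is None:
        qtn_ids = _default_qtns(scenario, G)
    seeds = _replicate_seeds(scenario.seed, scenario.n_replicates)

    sub = G.subset_snps(list(qtn_ids))
    poly = sub.polymorphic_mask()
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic QTN(s) from the "
            "detection denominator",
            stacklevel=2,
        )
    dosage = sub.calls.astype(float)[:, poly]
    dosage[sub.missing_mask()[:, poly]] = np.nan
    n_tests = dosage.shape[1]
    if n_tests == 0:
        raise ValidationError("no polymorphic QTNs to test")
    threshold = alpha / n_tests if correction == "bonferroni" else alpha

    scores = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        trait = simulate_additive_trait(G, qtn_ids, h2, seed=rng)
        pvals = _single_snp_pvalues(trait.phenotype, dosage)
        detected = pvals <= threshold
        scores.append(float(detected.any()) if any_hit else detected.mean())
    scores = np.asarray(scores, dtype=float)
    return PowerResult(
        method="single-SNP",
        h2=h2,
        alpha=alpha,
        n_replicates=len(scores),
        power=float(scores.mean()),
        decisions=scores,
        scenario=scenario,
    )


def _single_snp_pvalues(y: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Two-sided slope p-values of y ~ intercept + dosage, one SNP at a time
    via scipy.stats.linregress; NaN dosages are pairwise omitted."""
    pvals = np.empty(dosage.shape[1])
    for j in range(dosage.shape[1]):
        x = dosage[:, j]
        ok = ~np.isnan(x)
        res = stats.linregress(x[ok], y[ok])
        pvals[j] = res.pvalue
    return pvals


def _default_qtns(scenario: SimScenario, G: GenotypeMatrix) -> list[str]:
    """QTN draw tied to the scenario seed so paired runs share causal SNPs."""
    from .simulate import sample_qtns

    rng = np.random.default_rng(np.random.SeedSequence(entropy=scenario.seed, spawn_key=(97,)))
    return sample_qtns(G, scenario.n_qtn, seed=rng)


def summarize_power(results: list[PowerResult]) -> pd.DataFrame:
    """Tidy comparison table sorted by (method, h2)."""
    if not results:
        raise ValidationError("no power results to summarize")
    alphas = {r.alpha for r in results}
    if len(alphas) > 1:
        raise ValidationError(f"mixed alpha levels in one table: {sorted(alphas)}")
    rows = [
        {
            "method": r.method,
            "h2": r.h2,
            "alpha": r.alpha,
            "replicates": r.n_replicates,
            "power": r.power,
            "se": r.se,
            "excluded": r.n_excluded,
        }
        for r in results
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["method", "h2"], kind="mergesort")
        .reset_index(drop=True)
    )


def plot_power(table: pd.DataFrame, path: str | None = None):
    """Power-vs-heritability line plot, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    for method, grp in table.groupby("method"):
        ax.errorbar(
            grp.h2, grp.power, yerr=grp.se, marker="o", capsize=3, label=method
        )
    ax.set_xlabel("heritability $h^2$")
    ax.set_ylabel("statistical power")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
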