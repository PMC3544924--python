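# Methods

## The set-level mixed model

The core object is the mixed linear model

y = Xb + Σ_K u_K + e, with u_K ~ MVN(0, σ²_K K) for K ranging over a
subset of the five gene-set relationship kernels {A, D, AA, AD, DD} and
e ~ MVN(0, σ²_e I).

Every individual contributes one record, so the random-effect incidence
matrices are identities and the kernels enter the phenotypic covariance
directly: V = Σ_K σ²_K K + σ²_e I.  Repeated measures (Z ≠ I) are out of
scope.  Fixed effects are an intercept plus dummy-coded categorical
covariates with the first observed level as reference; the design must be
full rank after dropping references.

Assumptions worth stating explicitly:

* the trait is (conditionally) Gaussian on the scale analysed;
* relatedness relevant to the trait is captured by the gene-set SNPs used to
  build the kernels — there is no genome-wide background polygenic term;
* variance components are non-negative (no ASReml-style negative estimates).

## Kernels from IBD sharing

Pairwise P(IBD = 0, 1, 2) are estimated by the method of moments used in
standard genome-wide IBD screens.  For each pair, identity-by-state (IBS)
counts over the jointly observed SNPs are equated to their expectations
given in-sample allele frequencies; because IBS 0 is impossible under
IBD ≥ 1 and IBS < 2 impossible under IBD 2, the system is triangular and is
solved state by state, bounding each probability to [0, 1] before it feeds
the next equation and renormalizing to the simplex at the end (the bounded
behaviour of the standard tools).  Frequencies use no finite-sample
correction; with in-sample frequencies on small panels the estimates carry a
positive truncation bias of order 1/√m that the test suite checks decays
with SNP count.  Then A[i,j] = P2 + ½P1 (π̂), D[i,j] = P2, and the epistatic
kernels are elementwise products AA = A∘A, AD = A∘D, DD = D∘D.

Choices a user can change:

* **diagonal convention** — A[i,i] = D[i,i] = 1 (outbred, non-inbred
  self-relationship); configurable on the matrix builders.
* **SNP subset** — all gene-set SNPs by default; a TagSNP subset can be
  passed explicitly (`snp_subset`).
* **missing data** — pairwise-complete: each pair's moment equations use
  only its jointly observed SNPs; pairs below `min_informative` (default 20)
  jointly observed SNPs are flagged low-confidence.
* monomorphic SNPs carry no IBS information and are skipped with a warning.

π̂ matrices estimated from few SNPs need not be positive semidefinite; the
REML machinery only requires V to stay positive definite, which the
single-kernel profile enforces by capping the variance ratio at
0.999/|λ_min| when the kernel has a negative eigenvalue, and the dense path
enforces by penalizing failed Cholesky factorizations.

## REML estimation

The restricted log-likelihood is

l_R = −½ [ (n−p) log 2π + log|V| + log|XᵀV⁻¹X| + yᵀPy ].

* **No kernel** — closed form: σ̂²_e = RSS/(n−p).
* **One kernel** — eigendecompose K = UΛUᵀ once; in the rotated basis
  V = σ²_e(δΛ + I) is diagonal for the variance ratio δ = σ²_K/σ²_e, and
  σ²_e profiles out analytically.  The 1-D profile likelihood is scanned on
  a 41-point log-spaced δ grid (including δ = 0 exactly, which reproduces
  the null model) and refined by bounded Brent search in the bracketing
  interval.  A `SingleKernelWorkspace` caches the eigendecomposition and
  rotated design so that replicate studies pay O(n p) per fit after one
  O(n³) setup.
* **Several kernels** — bounded L-BFGS-B on log-variances from three starts
  (balanced, near-null, genetic-dominant), followed by a Nelder-Mead polish
  from the best point; the near-null start guarantees the fitted
  log-likelihood is never materially below the nested null's (likelihood
  monotonicity to 1e−6 is a tested invariant).  Bounds are
  [10⁻⁸, 10⁴] × var(y); components ending at the lower bound are reported
  as 0.

Convergence: L-BFGS-B relative-change tolerance 10⁻¹¹ with gradient
tolerance 10⁻⁸ (tight because weakly identified components leave flat
directions; the polish pass firms these up), maximum 200 iterations per
start; non-convergence is reported on the results object, never silently
dropped.  The reported log-likelihood is reproducible by direct dense
evaluation of l_R at the reported estimates (a 1e−6 oracle test).

## Likelihood-ratio tests

Nested kernel sets on identical y and X are compared by
Λ = max(0, 2(l_full − l_null)).  Because each tested component sits on the
boundary σ² = 0, the asymptotic null is not χ²_q but the binomial-weighted
mixture Σ_k C(q,k) 2⁻q χ²_k (χ²₀ = point mass at zero), giving
½χ²₀ + ½χ²₁ for one component.  A statistic of exactly zero has p = 1.
A naive χ²_q reference is available (`naive=True`) and is conservative.
Mixture weights assume independent boundary constraints; with correlated
kernels (AA vs A∘A share structure) the weights are approximate, which is
one reason the calibration of the additive test is verified by simulation
rather than assumed.

The standard testing plan is: additive (A vs none), dominance given
additive (A+D vs A), and the joint epistatic block (A+D+AA+AD+DD vs A+D).

## Synthetic data

The genotype generator draws per-SNP counted-allele frequencies uniformly
on a MAF range (default [0.05, 0.5]) and dosages Binomial(2, p) — HWE with
complete linkage equilibrium.  The default study conditions are a 57-SNP
gene-set panel, mirroring a sparse pathway extract from a commercial SNP
chip; the desk-scale profile uses n = 300 individuals and 500 replicates
(a full-scale profile at n = 820 and 1000 replicates is a parameter change).

What the generator does **not** emulate: linkage disequilibrium between the
set's SNPs, relatedness structure (litters, half-sib families), allele
ascertainment, and genotyping error.  Passing calibration and power tests
on these panels therefore demonstrates the statistical machinery under
idealized sampling, not robustness to LD-induced kernel structure or
pedigree confounding in real data.

Trait designs:

* **additive-only** — QTN effects ~ N(0,1) (redrawn each replicate by
  default; a fixed-effects mode exists), genetic value g = Σ dosage·β,
  residual variance σ²_e = s²_a(1−h²)/h² from the realized in-sample
  additive variance s²_a, so the in-sample heritability hits its target by
  construction.  At h² = 0 this formula is undefined; the null trait is
  pure N(0,1) noise with no genetic term, which is the correct null for
  type-I-error estimation and loses no generality because every test in the
  package is scale invariant.
* **full (a + d + epistasis)** — 13 QTNs with tabulated additive and
  dominance effects plus three interacting pairs whose effect is expressed
  only in individuals heterozygous at both members; residual variance fixed
  (default 10).  The packaged default effect table
  (`data/effects_full_trait_synthetic.tsv`) is synthetic — additive effects
  drawn once from N(0,1), dominance from N(0,0.5), pair effects of
  magnitude 1 — and is overridable by TSV.
* Missing dosages are mean-imputed per SNP for trait construction only;
  kinship estimation never imputes.

Seeding: every stochastic routine accepts a seed or Generator; replicate
studies expand a base seed through `numpy.random.SeedSequence.spawn`, so
paired method comparisons consume identical traits and re-runs are
bit-identical.

## Power study design

The set-level arm fits A vs residual-only per replicate and rejects at
p ≤ α (α = 0.01 by default, the study's nominal level).  The baseline
candidate-gene arm regresses the trait on each causal QTN separately and
scores the *proportion of QTNs detected* at α — the operational reading of
a per-QTN detection criterion; an any-hit rule and within-set Bonferroni
correction are available by flag, with no correction as the default since
the nominal per-test level is the stated error rate.  Monomorphic QTNs
leave the denominator with a warning; non-converged REML replicates are
excluded and counted, with a warning above 1%.

## Co-localization

SNPs are assigned to genes within a symmetric flanking window (default
50 kb, inclusive at both boundaries, floored at position 1; a SNP may hit
several genes).  Gene-QTL matching offers two modes — non-empty interval
intersection (default) and strict containment of the gene in the QTL
interval — plus an optional maximum-QTL-width filter, off by default,
because catalogue QTL with chromosome-scale confidence intervals match
almost anything.  Co-localization uses the gene body only, not the ±50 kb
SNP-assignment window.  Output order is deterministic (genes
alphabetically, QTL by ascending ID), and ranking is by descending match
count with alphabetical tie-break.

## Numerical conventions and edge cases

* Dosages are integer 0/1/2 with an explicit missing sentinel (−9); NaN
  never enters genotype arithmetic by accident.
* PLINK text reading counts the per-file minor allele; a frequency tie at
  0.5 is broken toward the lexicographically smaller allele symbol.
  Writing uses generic A/B symbols chosen so a read round trip reproduces
  dosages; columns coded on the major allele cannot round trip (the reader
  would flip them) and trigger a warning, with
  `GenotypeMatrix.minor_allele_coded()` as the canonicalizer.
* A kernel numerically equal to the identity is confounded with the
  residual and triggers a warning naming it.
* A pair with zero jointly observed SNPs gets probabilities (0, 0, 0) and
  the low-confidence flag rather than an arbitrary prior.

## Known limitations

* The boundary-mixture LRT is asymptotic; at small n or with near-identity
  kernels it runs somewhat conservative (the simulated rejection rate at
  α = 0.01 sits at roughly 0.002-0.015 across panel seeds).
* No BLUP of individual genetic values and no standard errors of variance
  components (point estimates and log-likelihoods only).
* Single-trait models only; no genome-wide background kernel alongside the
  gene-set kernels.
* LD-free genotype simulation overstates the effective number of
  independent markers relative to a real dense panel.
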