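"""REML variance components and boundary likelihood-ratio tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cgsa
from cgsa.datatypes import ValidationError
from cgsa.model import (
    GeneSetMixedModel,
    SingleKernelWorkspace,
    build_design,
    default_plan,
    fit_reml,
    lrt,
    mixture_pvalue,
)
from cgsa.model import test_gene_set as run_gene_set_tests


def reml_loglike_oracle(y, X, kernels, variances):
    """Direct dense restricted log-likelihood, written from the definition.

    Builds V explicitly, uses explicit inverses and slogdet (no Cholesky
    shortcuts), and evaluates
    -0.5 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py ].
    Independent of the package's evaluation and optimization code paths.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    V = variances[-1] * np.eye(n)
    for s, K in zip(variances[:-1], kernels):
        V = V + s * K
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtViX) @ X.T @ Vinv
    _, logdet_v = np.linalg.slogdet(V)
    _, logdet_x = np.linalg.slogdet(XtViX)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi) + logdet_v + logdet_x + y @ P @ y
    )


@pytest.fixture(scope="module")
def panel50():
    G = cgsa.simulate_genotypes(50, 40, maf_range=(0.1, 0.5), seed=31)
    kernels = cgsa.gene_set_kernels(G)
    rng = np.random.default_rng(32)
    trait = cgsa.simulate_additive_trait(G, cgsa.sample_qtns(G, 8, seed=rng), 0.4, seed=rng)
    return G, kernels, trait.phenotype


class TestFitReml:
    def test_residual_only_equals_sample_variance(self, rng):
        y = rng.standard_normal(80) * 3 + 5
        res = fit_reml(y)
        assert res.params["sigma2_e"] == pytest.approx(np.var(y, ddof=1), rel=1e-12)
        assert res.converged

    def test_loglik_matches_direct_oracle_all_kernel_subsets(self, panel50):
        _, kernels, y = panel50
        X = np.ones((len(y), 1))
        for names in itertools.chain.from_iterable(
            itertools.combinations(("A", "D", "AA"), r) for r in range(3)
        ):
            sub = {k: kernels[k] for k in names}
            res = fit_reml(y, kernels=sub)
            mats = [kernels[k].values for k in names]
            variances = np.r_[
                [res.params[f"sigma2_{k}"] for k in names], res.params["sigma2_e"]
            ]
            # evaluation at the reported optimum must agree with the
            # independent dense implementation
            expected = reml_loglike_oracle(y, X, mats, np.clip(variances, 1e-12, None))
            assert res.llf == pytest.approx(expected, abs=1e-6)

    def test_eig_and_dense_paths_agree(self, panel50):
        _, kernels, y = panel50
        res_eig = GeneSetMixedModel(y, kernels={"A": kernels["A"]}).fit(method="eig")
        res_dense = GeneSetMixedModel(y, kernels={"A": kernels["A"]}).fit(method="dense")
        assert res_eig.llf == pytest.approx(res_dense.llf, abs=1e-4)
        assert res_eig.params["sigma2_A"] == pytest.approx(
            res_dense.params["sigma2_A"], rel=0.02, abs=1e-3
        )

    def test_parameter_recovery_mvn(self):
        """y ~ MVN(0, 2A + I): mean REML estimates recover (2, 1)."""
        G = cgsa.simulate_genotypes(200, 400, maf_range=(0.1, 0.5), seed=41)
        A = cgsa.gene_set_kernels(G, kinds=("A",))["A"].values
        lam, U = np.linalg.eigh(2 * A + np.eye(200))
        assert lam.min() > 0
        root = U * np.sqrt(lam)
        ws = SingleKernelWorkspace(
            GeneSetMixedModel(np.zeros(200) + np.arange(200.0), kernels={"A": A})
        )
        rng = np.random.default_rng(42)
        est_a, est_e = [], []
        for _ in range(60):
            y = root @ rng.standard_normal(200)
            res = ws.fit(y)
            est_a.append(res.params["sigma2_A"])
            est_e.append(res.params["sigma2_e"])
        for est, truth in ((est_a, 2.0), (est_e, 1.0)):
            mean = np.mean(est)
            se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(mean - truth) < 3 * se + 0.05

    def test_monotonicity_in_kernels(self, panel50):
        _, kernels, y = panel50
        prev = fit_reml(y).llf
        for names in (("A",), ("A", "D"), ("A", "D", "AA")):
            cur = fit_reml(y, kernels={k: kernels[k] for k in names}).llf
            assert cur >= prev - 1e-6
            prev = cur

    def test_scale_equivariance(self, panel50):
        _, kernels, y = panel50
        sub = {"A": kernels["A"], "D": kernels["D"]}
        base = fit_reml(y, kernels=sub)
        scaled = fit_reml(2.5 * y, kernels=sub)
        total = base.params.sum()
        for name in base.params.index:
            # components pinned near the zero boundary carry no scale signal
            if base.params[name] > 1e-3 * total:
                assert scaled.params[name] / base.params[name] == pytest.approx(
                    6.25, rel=5e-3
                )
        s_base = lrt(base, fit_reml(y)).statistic
        s_scaled = lrt(scaled, fit_reml(2.5 * y)).statistic
        assert s_scaled == pytest.approx(s_base, abs=1e-6)

    def test_identity_kernel_warns(self, rng):
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="identity"):
            GeneSetMixedModel(y, kernels={"A": np.eye(30)})

    def test_fixed_effects_recovered_design(self):
        cov = pd.DataFrame(
            {"gender": ["m", "f"] * 15, "sire": (["s1", "s2", "s3"] * 10)}
        )
        X, names = build_design(cov)
        assert X.shape == (30, 4)  # intercept + 1 gender + 2 sire contrasts
        assert names[0] == "intercept"


class TestLRT:
    def test_zero_statistic_gives_p_one(self):
        assert mixture_pvalue(0.0, 1) == 1.0
        assert mixture_pvalue(-1e-12, 3) == 1.0

    def test_half_chi2_quantile(self):
        # 0.5 * P(chi2_1 >= 2.706) = 0.05: 2.706 is the 0.90 quantile of chi2_1
        assert stats.chi2.ppf(0.90, 1) == pytest.approx(2.706, abs=5e-4)
        assert mixture_pvalue(2.706, 1) == pytest.approx(0.05, abs=5e-4)

    @pytest.mark.parametrize("statistic", [0.5, 2.0, 5.99])
    def test_two_component_mixture_matches_monte_carlo(self, statistic):
        # null draw: chi2_0 / chi2_1 / chi2_2 with weights 1/4, 1/2, 1/4
        rng = np.random.default_rng(7)
        n = 10**6
        df = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
        draws = np.zeros(n)
        draws[df == 1] = rng.chisquare(1, (df == 1).sum())
        draws[df == 2] = rng.chisquare(2, (df == 2).sum())
        p_mc = (draws >= statistic).mean()
        se = np.sqrt(p_mc * (1 - p_mc) / n)
        assert abs(mixture_pvalue(statistic, 2) - p_mc) < 3 * se

    def test_requires_strict_nesting(self, panel50):
        _, kernels, y = panel50
        full = fit_reml(y, kernels={"A": kernels["A"]})
        with pytest.raises(ValidationError, match="strict subset"):
            lrt(full, full)

    def test_null_better_than_full_is_an_error(self, panel50):
        _, kernels, y = panel50
        full = fit_reml(y, kernels={"A": kernels["A"]})
        null = fit_reml(y)
        null.llf = full.llf + 1.0  # corrupt: simulates optimizer failure
        with pytest.raises(ValidationError, match="refit"):
            lrt(full, null)

    def test_naive_reference_is_more_conservative(self, panel50):
        _, kernels, y = panel50
        full = fit_reml(y, kernels={"A": kernels["A"]})
        null = fit_reml(y)
        if lrt(full, null).statistic > 0:
            assert lrt(full, null, naive=True).p_value > lrt(full, null).p_value


class TestGeneSetTest:
    def test_default_plan_structure(self):
        plan = default_plan(["A", "D", "AA", "AD", "DD"])
        assert [p[0] for p in plan] == ["additive", "dominance", "epistasis"]
        assert plan[2][1] == ["A", "D", "AA", "AD", "DD"]

    def test_duplicate_kernel_in_plan_rejected(self, panel50):
        _, kernels, y = panel50
        with pytest.raises(ValidationError, match="duplicate"):
            run_gene_set_tests(
                y, kernels, plan=[("bad", ["A", "A"], [])]
            )

    def test_strong_additive_signal_detected(self):
        """h2 = 0.5 at n = 300: the additive set-level test rejects at 0.01
        in nearly every replicate."""
        G = cgsa.simulate_genotypes(300, 57, maf_range=(0.05, 0.5), seed=51)
        A = cgsa.gene_set_kernels(G, kinds=("A",))["A"]
        qtns = cgsa.sample_qtns(G, 15, seed=52)
        ws = SingleKernelWorkspace(
            GeneSetMixedModel(np.arange(300.0), kernels={"A": A})
        )
        hits = 0
        n_reps = 40
        for rep in range(n_reps):
            trait = cgsa.simulate_additive_trait(G, qtns, 0.5, seed=1000 + rep)
            full = ws.fit(trait.phenotype)
            null = fit_reml(trait.phenotype)
            if lrt(full, null).p_value < 0.01:
                hits += 1
        assert hits >= 0.95 * n_reps

    def test_table_columns_and_audit_fits(self, panel50):
        _, kernels, y = panel50
        table = run_gene_set_tests(y, {k: kernels[k] for k in ("A", "D")})
        assert list(table.test) == ["additive", "dominance"]
        assert set(table.columns) >= {"statistic", "p_value", "llf_full", "llf_null"}
        assert ("A",) in table.attrs["fits"]

    def test_covariates_change_design_not_crash(self, panel50):
        _, kernels, y = panel50
        rng = np.random.default_rng(9)
        cov = pd.DataFrame(
            {
                "gender": rng.choice(["m", "f"], size=len(y)),
                "sire": rng.choice(["s1", "s2", "s3"], size=len(y)),
            }
        )
        table = run_gene_set_tests(y, {"A": kernels["A"]}, covariates=cov)
        assert len(table) == 1
        assert np.isfinite(table.p_value.iloc[0])
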