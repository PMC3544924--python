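"""Gene-set mixed linear model: REML variance components and boundary LRTs.

The model for a quantitative trait y on n individuals is

    y = X b + u_A + u_D + u_AA + u_AD + u_DD + e,
    u_K ~ MVN(0, sigma2_K * K),   e ~ MVN(0, sigma2_e * I),

where X holds an intercept and categorical covariates, and each K is a
gene-set relationship kernel (additive, dominance, or a Hadamard epistatic
product).  Any subset of the five kernels may be fitted.  Estimation is by
restricted maximum likelihood (REML),

    l_R = -1/2 [ (n-p) log 2*pi + log|V| + log|X' V^-1 X| + y' P y ],

with V = sum_K sigma2_K K + sigma2_e I and P the REML projection.

Significance of a component (or block of components) is assessed by a
likelihood-ratio test of nested kernel sets.  Because the null value
sigma2_K = 0 sits on the boundary of the parameter space, the null
distribution of the statistic is not chi-square but the mixture
sum_k C(q,k) 2^-q chi2_k for q components tested (one component:
0.5 chi2_0 + 0.5 chi2_1).  A naive chi2_q reference is available for
comparison; it is conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .datatypes import ValidationError
from .kinship import KinshipMatrix

__all__ = [
    "GeneSetMixedModel",
    "GeneSetMixedModelResults",
    "SingleKernelWorkspace",
    "LRTResult",
    "fit_reml",
    "lrt",
    "mixture_pvalue",
    "test_gene_set",
    "default_plan",
    "build_design",
]

_LOG2PI = np.log(2.0 * np.pi)


def build_design(
    covariates: pd.DataFrame | None, n: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept plus dummy-coded categorical covariates.

    The first observed level of each covariate is the reference and is
    dropped, keeping the design full rank.
    """
    if covariates is None or covariates.shape[1] == 0:
        if n is None:
            raise ValidationError("need n when no covariates are given")
        return np.ones((n, 1)), ["intercept"]
    dummies = pd.get_dummies(covariates.astype("category"), drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(covariates)), dummies.to_numpy()])
    names = ["intercept"] + list(dummies.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("fixed-effect design is rank deficient")
    return X, names


def _as_kernel_dict(
    kernels,
) -> dict[str, np.ndarray]:
    """Accept a mapping of name -> (KinshipMatrix | ndarray) or a list."""
    if kernels is None:
        return {}
    if isinstance(kernels, (list, tuple)):
        out = {}
        for k in kernels:
            if not isinstance(k, KinshipMatrix):
                raise ValidationError("list form requires KinshipMatrix items")
            if k.kind in out:
                raise ValidationError(f"duplicate kernel {k.kind!r}")
            out[k.kind] = k.values
        return out
    out = {}
    for name, k in kernels.items():
        out[str(name)] = k.values if isinstance(k, KinshipMatrix) else np.asarray(k, float)
    return out


class GeneSetMixedModel:
    """Mixed linear model with gene-set variance-component kernels.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Trait values.  Missing values are not allowed here; drop them when
        building the model (``from_dataframe`` does so, with a report).
    kernels : mapping of str -> KinshipMatrix or ndarray, or list of KinshipMatrix
        Ordered relationship kernels entering the covariance.  May be empty
        (residual-only model).
    exog : ndarray, optional
        Fixed-effect design matrix; defaults to an intercept column.
    exog_names : list of str, optional
    """

    def __init__(self, endog, kernels=None, exog=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        n = self.endog.size
        if np.isnan(self.endog).any():
            raise ValidationError(
                "endog contains missing values; subset before model construction"
            )
        self.kernels = _as_kernel_dict(kernels)
        for name, K in self.kernels.items():
            if K.shape != (n, n):
                raise ValidationError(f"kernel {name!r} shape {K.shape} != ({n}, {n})")
            if np.allclose(K, np.eye(n), atol=1e-10):
                warnings.warn(
                    f"kernel {name!r} is numerically an identity matrix and is "
                    "confounded with the residual variance",
                    stacklevel=2,
                )
        if exog is None:
            exog = np.ones((n, 1))
            exog_names = ["intercept"]
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        self.exog_names = list(exog_names or [f"x{j}" for j in range(self.exog.shape[1])])
        p = self.exog.shape[1]
        if np.linalg.matrix_rank(self.exog) < p:
            raise ValidationError("exog is rank deficient")
        if n < p + 2:
            raise ValidationError(f"need n >= p + 2 (n={n}, p={p})")
        self.nobs = n

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        trait: str,
        kernels,
        covariates: list[str] | tuple[str, ...] = (),
    ) -> "GeneSetMixedModel":
        """Build from a phenotype DataFrame aligned to the kernels' order.

        Rows with a missing trait value are dropped, with a warning naming
        the count, and the kernels are subset accordingly.
        """
        kd = _as_kernel_dict(kernels)
        keep = data[trait].notna().to_numpy()
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} individual(s) with missing "
                f"{trait!r}",
                stacklevel=2,
            )
        sub = data.loc[keep]
        X, names = build_design(
            sub[list(covariates)] if covariates else None, n=len(sub)
        )
        kd = {name: K[np.ix_(keep, keep)] for name, K in kd.items()}
        return cls(sub[trait].to_numpy(float), kernels=kd, exog=X, exog_names=names)

    # -- likelihood -----------------------------------------------------

    def loglike_reml(self, variances: dict[str, float] | np.ndarray) -> float:
        """Restricted log-likelihood at the given variance components.

        ``variances`` maps each kernel name plus ``"e"`` (residual) to a
        variance, or gives them as an array ordered like the kernels with the
        residual last.  Dense O(n^3) evaluation; used for reporting and for
        the multi-kernel optimizer.
        """
        sig = self._variance_vector(variances)
        n, p = self.nobs, self.exog.shape[1]
        V = sig[-1] * np.eye(n)
        for s, K in zip(sig[:-1], self.kernels.values()):
            V += s * K
        if not np.all(np.isfinite(V)):
            return -np.inf
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return -np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi_X = linalg.cho_solve(cf, self.exog)
        Vi_y = linalg.cho_solve(cf, self.endog)
        XtViX = self.exog.T @ Vi_X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtViX, self.exog.T @ Vi_y)
        resid = self.endog - self.exog @ beta
        quad = resid @ linalg.cho_solve(cf, resid)
        return -0.5 * ((n - p) * _LOG2PI + logdet_v + logdet_x + quad)

    def _variance_vector(self, variances) -> np.ndarray:
        k = len(self.kernels)
        if isinstance(variances, dict):
            vec = [variances[name] for name in self.kernels] + [variances["e"]]
            return np.asarray(vec, float)
        vec = np.asarray(variances, float).ravel()
        if vec.size != k + 1:
            raise ValidationError(f"expected {k + 1} variances, got {vec.size}")
        return vec

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        method: str = "auto",
        n_starts: int = 3,
        maxiter: int = 200,
        tol: float = 1e-8,
    ) -> "GeneSetMixedModelResults":
        """Maximize the restricted likelihood over non-negative components.

        Single-kernel models are profiled on the variance ratio after an
        eigendecomposition of the kernel (each evaluation is O(n p));
        multi-kernel models use bounded quasi-Newton on log-variances with
        multiple starting points.  Residual-only models are closed form.
        """
        if method not in ("auto", "eig", "dense"):
            raise ValidationError(f"unknown fit method {method!r}")
        if len(self.kernels) == 0:
            return self._fit_residual_only()
        if len(self.kernels) == 1 and method in ("auto", "eig"):
            ws = SingleKernelWorkspace(self)
            return ws.fit(self.endog)
        return self._fit_dense(n_starts=n_starts, maxiter=maxiter, tol=tol)

    def _fit_residual_only(self) -> "GeneSetMixedModelResults":
        n, p = self.nobs, self.exog.shape[1]
        beta, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        rss = float(np.sum((self.endog - self.exog @ beta) ** 2))
        sigma2_e = rss / (n - p)
        llf = self.loglike_reml(np.array([sigma2_e]))
        return GeneSetMixedModelResults(
            model=self,
            params=pd.Series({"sigma2_e": sigma2_e}),
            llf=float(llf),
            converged=True,
            n_iter=0,
            method="closed-form",
        )

    def _fit_dense(self, n_starts: int, maxiter: int, tol: float):
        k = len(self.kernels)
        vy = float(np.var(self.endog, ddof=1))
        if vy <= 0:
            raise ValidationError("endog has zero variance")
        lo, hi = np.log(vy * 1e-8), np.log(vy * 1e4)
        bounds = [(lo, hi)] * (k + 1)

        def negloglike(theta: np.ndarray) -> float:
            # large finite penalty keeps L-BFGS-B's finite differences sane
            if not np.all(np.isfinite(theta)):
                return 1e12
            ll = self.loglike_reml(np.exp(theta))
            return -ll if np.isfinite(ll) else 1e12

        starts = [
            np.log(np.r_[np.full(k, vy / (2 * k)), vy / 2]),
            np.log(np.r_[np.full(k, vy * 1e-6), vy]),  # near-null
            np.log(np.r_[np.full(k, 0.9 * vy / k), 0.1 * vy]),
        ][: max(n_starts, 1)]
        best = None
        total_iter = 0
        for x0 in starts:
            res = optimize.minimize(
                negloglike,
                np.clip(x0, lo, hi),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": tol * 1e-3, "gtol": 1e-8},
            )
            total_iter += int(res.nit)
            if best is None or res.fun < best.fun:
                best = res
        # polish: flat directions (weakly identified components) can stall the
        # line search; a derivative-free pass from the best point firms them up
        polish = optimize.minimize(
            negloglike,
            best.x,
            method="Nelder-Mead",
            options={"maxiter": 200 * (k + 1), "xatol": 1e-10, "fatol": 1e-12},
        )
        if polish.fun < best.fun and np.all(polish.x >= lo) and np.all(polish.x <= hi):
            best = polish
            best.success = True
        sig = np.exp(best.x)
        names = [f"sigma2_{name}" for name in self.kernels] + ["sigma2_e"]
        # components pinned at the tiny lower bound are zero for reporting
        sig = np.where(sig <= vy * 2e-8, 0.0, sig)
        llf = self.loglike_reml(np.where(sig == 0.0, vy * 1e-8, sig))
        return GeneSetMixedModelResults(
            model=self,
            params=pd.Series(sig, index=names),
            llf=float(max(llf, -best.fun)),
            converged=bool(best.success),
            n_iter=total_iter,
            method="reml-lbfgsb",
        )


class SingleKernelWorkspace:
    """Cached eigendecomposition for repeated single-kernel REML fits.

    Rotating by the kernel's eigenvectors diagonalizes V = sigma2_e
    (delta K + I), so each restricted-likelihood evaluation during the 1-D
    search over the variance ratio delta costs O(n p^2).  Build once per
    (kernel, design) pair and call :meth:`fit` for each trait replicate.
    """

    def __init__(self, model: GeneSetMixedModel):
        if len(model.kernels) != 1:
            raise ValidationError("workspace requires exactly one kernel")
        self.model = model
        (self.kernel_name, K), = model.kernels.items()
        self.eigvals, self.U = np.linalg.eigh(K)
        self.X_rot = self.U.T @ model.exog
        self.n, self.p = model.nobs, model.exog.shape[1]
        lam_min = float(self.eigvals.min())
        # keep V positive definite when the kernel has negative eigenvalues
        self.delta_max = 1e5 if lam_min >= 0 else 0.999 / abs(lam_min)

    def _profile_negloglike(self, delta: float, y_rot: np.ndarray) -> float:
        w = delta * self.eigvals + 1.0
        if np.any(w <= 0):
            return np.inf
        n, p = self.n, self.p
        Xw = self.X_rot / w[:, None]
        XtWX = self.X_rot.T @ Xw
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, Xw.T @ y_rot)
        resid = y_rot - self.X_rot @ beta
        r = float(resid @ (resid / w))
        if r <= 0:
            return np.inf
        return 0.5 * (
            (n - p) * (_LOG2PI + 1.0 + np.log(r / (n - p)))
            + float(np.sum(np.log(w)))
            + logdet_x
        )

    def fit(self, y: np.ndarray) -> "GeneSetMixedModelResults":
        """REML fit for one trait vector; grid + Brent search over delta."""
        y_rot = self.U.T @ np.asarray(y, float).ravel()
        f = lambda d: self._profile_negloglike(d, y_rot)

        grid = np.concatenate(
            [[0.0], np.logspace(-5, np.log10(self.delta_max), 40)]
        )
        vals = np.array([f(d) for d in grid])
        j = int(np.argmin(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        n_iter = len(grid)
        if j == 0 and vals[0] <= vals[1]:
            delta, fmin = 0.0, vals[0]
            converged = True
        else:
            res = optimize.minimize_scalar(
                f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
            )
            n_iter += int(res.nfev)
            converged = bool(res.success)
            delta, fmin = float(res.x), float(res.fun)
            if vals[j] < fmin:  # guard: keep the grid optimum if refinement lost it
                delta, fmin = float(grid[j]), float(vals[j])
        # recover sigma2_e at the profiled optimum
        w = delta * self.eigvals + 1.0
        Xw = self.X_rot / w[:, None]
        XtWX = self.X_rot.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ y_rot)
        resid = y_rot - self.X_rot @ beta
        sigma2_e = float(resid @ (resid / w)) / (self.n - self.p)
        sigma2_g = delta * sigma2_e
        model = self.model
        if not np.shares_memory(y, model.endog) and not np.array_equal(y, model.endog):
            model = GeneSetMixedModel(
                y,
                kernels={self.kernel_name: next(iter(self.model.kernels.values()))},
                exog=self.model.exog,
                exog_names=self.model.exog_names,
            )
        return GeneSetMixedModelResults(
            model=model,
            params=pd.Series(
                {f"sigma2_{self.kernel_name}": sigma2_g, "sigma2_e": sigma2_e}
            ),
            llf=float(-fmin),
            converged=converged,
            n_iter=n_iter,
            method="reml-eig",
        )


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested variance-component models."""

    statistic: float
    n_components: int
    p_value: float
    null_distribution: str
    llf_full: float
    llf_null: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LRT({self.n_components} component(s)): stat={self.statistic:.4f}, "
            f"p={self.p_value:.4g} [{self.null_distribution}]"
        )


class GeneSetMixedModelResults:
    """REML estimates, restricted log-likelihood and diagnostics."""

    def __init__(self, model, params, llf, converged, n_iter, method):
        self.model = model
        self.params = params
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.method = method

    @property
    def kernel_names(self) -> tuple[str, ...]:
        return tuple(self.model.kernels)

    def lrt(self, null: "GeneSetMixedModelResults", naive: bool = False) -> LRTResult:
        """Boundary likelihood-ratio test against a nested null fit."""
        return lrt(self, null, naive=naive)

    def summary(self) -> str:
        lines = [
            "Gene-set mixed model (REML)",
            "=" * 45,
            f"No. observations: {self.model.nobs}",
            f"Fixed effects:    {', '.join(self.model.exog_names)}",
            f"Kernels:          {', '.join(self.kernel_names) or '(none)'}",
            f"Method:           {self.method}",
            f"Converged:        {self.converged}  (iterations: {self.n_iter})",
            f"Restricted logLik: {self.llf:.6f}",
            "-" * 45,
            f"{'component':<16}{'estimate':>14}",
        ]
        for name, value in self.params.items():
            lines.append(f"{name:<16}{value:>14.6g}")
        lines.append("=" * 45)
        return "\n".join(lines)


def fit_reml(
    y,
    kernels=None,
    exog=None,
    exog_names=None,
    **fit_kwargs,
) -> GeneSetMixedModelResults:
    """Convenience: construct a :class:`GeneSetMixedModel` and fit it."""
    return GeneSetMixedModel(
        y, kernels=kernels, exog=exog, exog_names=exog_names
    ).fit(**fit_kwargs)


def mixture_pvalue(statistic: float, n_components: int) -> float:
    """Upper tail of the boundary chi-square mixture sum_k C(q,k) 2^-q chi2_k.

    chi2_0 is a point mass at zero, so a statistic of exactly 0 has p = 1.
    """
    q = int(n_components)
    if q < 1:
        raise ValidationError("n_components must be >= 1")
    s = float(statistic)
    if s <= 0:
        return 1.0
    weight = 0.5**q
    p = sum(comb(q, k) * weight * stats.chi2.sf(s, df=k) for k in range(1, q + 1))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def lrt(
    full: GeneSetMixedModelResults,
    null: GeneSetMixedModelResults,
    naive: bool = False,
    tol: float = 1e-6,
) -> LRTResult:
    """Likelihood-ratio test between nested kernel sets on the same data.

    ``naive=True`` uses a chi2_q reference instead of the boundary mixture
    (conservative, for comparison with textbook LRTs).
    """
    full_set, null_set = set(full.kernel_names), set(null.kernel_names)
    if not (null_set < full_set):
        raise ValidationError(
            f"null kernels {sorted(null_set)} must be a strict subset of "
            f"full kernels {sorted(full_set)}"
        )
    if not np.array_equal(full.model.endog, null.model.endog) or not np.array_equal(
        full.model.exog, null.model.exog
    ):
        raise ValidationError("full and null fits must share endog and exog")
    if null.llf > full.llf + tol:
        raise ValidationError(
            f"null logLik {null.llf:.6f} exceeds full logLik {full.llf:.6f}; "
            "refit the full model (optimizer failure)"
        )
    q = len(full_set - null_set)
    statistic = max(0.0, 2.0 * (full.llf - null.llf))
    if naive:
        p = float(stats.chi2.sf(statistic, df=q)) if statistic > 0 else 1.0
        label = f"chi2_{q}"
    else:
        p = mixture_pvalue(statistic, q)
        label = f"mixture sum_k C({q},k) 2^-{q} chi2_k"
    return LRTResult(
        statistic=statistic,
        n_components=q,
        p_value=p,
        null_distribution=label,
        llf_full=full.llf,
        llf_null=null.llf,
    )


def default_plan(kernel_names) -> list[tuple[str, list[str], list[str]]]:
    """Standard testing plan: additive; dominance given additive; epistatic
    block given additive + dominance.  Comparisons whose kernels are absent
    are omitted."""
    names = list(kernel_names)
    plan = []
    if "A" in names:
        plan.append(("additive", ["A"], []))
    if "A" in names and "D" in names:
        plan.append(("dominance", ["A", "D"], ["A"]))
    epi = [k for k in ("AA", "AD", "DD") if k in names]
    if epi and "A" in names and "D" in names:
        plan.append(("epistasis", ["A", "D"] + epi, ["A", "D"]))
    return plan


def test_gene_set(
    y,
    kernels,
    covariates: pd.DataFrame | None = None,
    plan: list[tuple[str, list[str], list[str]]] | None = None,
    naive: bool = False,
    **fit_kwargs,
) -> pd.DataFrame:
    """Run the planned nested likelihood-ratio tests for a gene set.

    Parameters
    ----------
    y : array-like
        Trait values aligned to the kernels.
    kernels : mapping of kernel name -> KinshipMatrix/ndarray
    covariates : DataFrame, optional
        Categorical fixed effects (gender, sire, ...), aligned to ``y``.
    plan : list of (label, full_kernels, null_kernels), optional
        Defaults to :func:`default_plan`.

    Returns a DataFrame with one row per comparison; the fitted results
    objects are retained in ``df.attrs["fits"]`` for audit.
    """
    kd = _as_kernel_dict(kernels)
    y = np.asarray(y, float).ravel()
    X, names = build_design(covariates, n=y.size)
    if plan is None:
        plan = default_plan(kd)
    fits: dict[tuple[str, ...], GeneSetMixedModelResults] = {}

    def get_fit(kernel_list: list[str]) -> GeneSetMixedModelResults:
        if len(set(kernel_list)) != len(kernel_list):
            raise ValidationError(f"duplicate kernel in plan: {kernel_list}")
        missing = [k for k in kernel_list if k not in kd]
        if missing:
            raise ValidationError(f"plan names unavailable kernel(s) {missing}")
        key = tuple(kernel_list)
        if key not in fits:
            fits[key] = fit_reml(
                y,
                kernels={k: kd[k] for k in kernel_list},
                exog=X,
                exog_names=names,
                **fit_kwargs,
            )
        return fits[key]

    rows = []
    for label, full_kernels, null_kernels in plan:
        full = get_fit(full_kernels)
        null = get_fit(null_kernels)
        result = lrt(full, null, naive=naive)
        rows.append(
            {
                "test": label,
                "n_components": result.n_components,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "llf_full": result.llf_full,
                "llf_null": result.llf_null,
                "converged": full.converged and null.converged,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["fits"] = fits
    return df
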