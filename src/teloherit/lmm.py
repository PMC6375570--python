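"""Gaussian linear mixed models by REML, statsmodels-style.

:class:`MixedModel` is built from a DataFrame (or arrays) and supports
crossed and nested random intercepts plus independent random slopes — the
structure needed for pedigree-style data where offspring share fathers
(crossed with gels and years) and nests are nested inside fathers.  ``fit()``
returns a :class:`MixedModelResults` with coefficient estimates, standard
errors, Satterthwaite degrees of freedom, two-tailed t p-values, variance
components and the REML log-likelihood.

Implementation notes
--------------------
The covariance is ``V = sigma2_e * (I + sum_k gamma_k Z_k Z_k')`` with one
variance ratio ``gamma_k`` per random term; the residual variance and the
fixed effects are profiled out, and the profiled REML criterion is minimised
over ``log gamma`` by L-BFGS-B with an analytic gradient and a small
multi-start to guard against boundary traps.  Random slopes are modelled
with zero intercept-slope correlation (each slope is its own variance
component), which matches reporting slope contributions as a separate
variance share and is far better behaved at small slope variances.
Variance ratios hitting the lower bound are reported as variance 0 with a
boundary flag, not as an error.  Degrees of freedom use the Satterthwaite
approximation from the finite-difference Hessian of the unprofiled REML
criterion on the variance scale, falling back to the residual df ``n - p``
with a warning flag if that Hessian is singular.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.linalg import slogdet
from scipy import linalg, optimize, stats

__all__ = ["ModelSpec", "MixedModel", "MixedModelResults", "satterthwaite_df"]

_GAMMA_FLOOR = 1e-8
_GAMMA_CEIL = 1e5
_BOUNDARY_TOL = 1e-6


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model description.

    ``random_intercepts`` entries are grouping columns; nesting is written
    ``"outer/inner"`` (expands to the outer factor plus the composite
    ``outer:inner``) or given directly as a composite ``"outer:inner"``.
    ``random_slopes`` are ``(covariate, group)`` pairs fitted as independent
    variance components.
    """

    response: str
    fixed_terms: tuple[str, ...]
    random_intercepts: tuple[str, ...] = ()
    random_slopes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        seen = set()
        for t in self.fixed_terms:
            if t in seen:
                raise ValueError(f"duplicate fixed term {t!r}")
            seen.add(t)
        expanded = self.expanded_intercepts()
        if len(set(expanded)) != len(expanded):
            raise ValueError("duplicate random intercept term")

    def expanded_intercepts(self) -> list[str]:
        out = []
        for term in self.random_intercepts:
            if "/" in term:
                outer, inner = (s.strip() for s in term.split("/", 1))
                out.extend([outer, f"{outer}:{inner}"])
            else:
                out.append(term.strip())
        return out

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        """Parse e.g.
        ``"tl ~ age + mean_age, random = father_id/nest_id + gel_id, slope = delta_age|father_id"``.
        """
        parts = [p.strip() for p in text.split(",")]
        m = re.match(r"^(\S+)\s*~\s*(.+)$", parts[0])
        if not m:
            raise ValueError(f"cannot parse model formula {parts[0]!r}")
        response = m.group(1)
        fixed = tuple(t.strip() for t in m.group(2).split("+") if t.strip())
        intercepts: tuple[str, ...] = ()
        slopes: list[tuple[str, str]] = []
        for part in parts[1:]:
            key, _, rhs = part.partition("=")
            key = key.strip()
            if key == "random":
                intercepts = tuple(t.strip() for t in rhs.split("+") if t.strip())
            elif key == "slope":
                for item in rhs.split("+"):
                    cov, _, grp = item.partition("|")
                    slopes.append((cov.strip(), grp.strip()))
            else:
                raise ValueError(f"unknown model-spec clause {key!r}")
        return cls(response, fixed, intercepts, tuple(slopes))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _composite_factor(df: pd.DataFrame, term: str) -> pd.Series:
    cols = [c.strip() for c in term.split(":")]
    for c in cols:
        if c not in df.columns:
            raise KeyError(f"grouping column {c!r} not in data")
    if len(cols) == 1:
        return df[cols[0]].astype(str)
    return df[cols[0]].astype(str).str.cat([df[c].astype(str) for c in cols[1:]],
                                           sep=":")


class MixedModel:
    """Linear mixed model with crossed/nested random intercepts and
    independent random slopes, estimated by REML."""

    def __init__(self, endog: np.ndarray, exog: np.ndarray,
                 re_design: list[tuple[str, np.ndarray]],
                 exog_names: list[str] | None = None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if len(y) != n:
            raise ValueError("endog/exog length mismatch")
        if n <= p:
            raise ValueError("need more rows than fixed-effect terms")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed-effect design is rank-deficient: a term "
                             "is constant or collinear (e.g. a delta column "
                             "with no multi-year parents)")
        for name, Z in re_design:
            if Z.shape[0] != n:
                raise ValueError(f"random term {name!r} has wrong length")
            if Z.shape[1] < 2:
                raise ValueError(f"grouping factor {name!r} has < 2 levels")
        self.endog = y
        self.exog = X
        self.re_design = list(re_design)
        self.exog_names = list(exog_names) if exog_names else [
            f"x{j}" for j in range(p)]
        self.nobs = n
        self.data: pd.DataFrame | None = None
        self.spec: ModelSpec | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec) -> "MixedModel":
        """Build design matrices from a long-format frame.

        Rows with missing response or covariates are dropped listwise for
        this model only (mirroring how analyses with incomplete parental
        measurements run on reduced n).
        """
        cols_needed = [spec.response, *spec.fixed_terms]
        for t in spec.expanded_intercepts():
            cols_needed += [c.strip() for c in t.split(":")]
        for cov, grp in spec.random_slopes:
            cols_needed += [cov, grp]
        missing = [c for c in dict.fromkeys(cols_needed) if c not in data.columns]
        if missing:
            raise KeyError(f"columns not in data: {missing}")

        numeric = [spec.response, *spec.fixed_terms] + [
            cov for cov, _ in spec.random_slopes]
        sub = data.copy()
        keep = np.ones(len(sub), dtype=bool)
        for c in dict.fromkeys(numeric):
            vals = pd.to_numeric(sub[c], errors="coerce")
            sub[c] = vals
            keep &= vals.notna().to_numpy()
        sub = sub.loc[keep].reset_index(drop=True)

        y = sub[spec.response].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[t].to_numpy(dtype=float)
                                   for t in spec.fixed_terms])
        names = ["(intercept)", *spec.fixed_terms]

        re_design: list[tuple[str, np.ndarray]] = []
        for term in spec.expanded_intercepts():
            codes, levels = pd.factorize(_composite_factor(sub, term))
            Z = np.zeros((len(sub), len(levels)))
            Z[np.arange(len(sub)), codes] = 1.0
            re_design.append((term, Z))
        for cov, grp in spec.random_slopes:
            codes, levels = pd.factorize(_composite_factor(sub, grp))
            Z = np.zeros((len(sub), len(levels)))
            Z[np.arange(len(sub)), codes] = sub[cov].to_numpy(dtype=float)
            re_design.append((f"{cov}|{grp}", Z))

        model = cls(y, X, re_design, exog_names=names)
        model.data = sub
        model.spec = spec
        model.n_dropped = int((~keep).sum())
        return model

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "MixedModel":
        return cls.from_dataframe(data, ModelSpec.from_string(formula))

    # -- REML machinery -----------------------------------------------------

    def _profiled(self, log_gamma: np.ndarray, want_grad: bool = False):
        """Profiled REML criterion (and gradient wrt log gamma)."""
        n, p = self.exog.shape
        gamma = np.exp(log_gamma)
        V = np.eye(n)
        for g, (_, Z) in zip(gamma, self.re_design):
            V += g * (Z @ Z.T)
        L = linalg.cholesky(V, lower=True)
        Xi = linalg.solve_triangular(L, self.exog, lower=True)
        yi = linalg.solve_triangular(L, self.endog, lower=True)
        XtX = Xi.T @ Xi
        Lx = linalg.cholesky(XtX, lower=True)
        beta = linalg.cho_solve((Lx, True), Xi.T @ yi)
        r = yi - Xi @ beta
        rss = float(r @ r)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
        logdet_xtx = 2.0 * float(np.sum(np.log(np.diag(Lx))))
        crit = (n - p) * np.log(rss) + logdet_v + logdet_xtx
        if not want_grad:
            return crit
        u = linalg.solve_triangular(L, r, lower=True, trans="T")  # P y
        grad = np.empty(len(gamma))
        for k, (g, (_, Z)) in enumerate(zip(gamma, self.re_design)):
            W = linalg.solve_triangular(L, Z, lower=True)          # L^-1 Z
            tr_v = float(np.sum(W * W))
            B = Xi.T @ W                                           # X'V^-1 Z
            C = linalg.solve_triangular(Lx, B, lower=True)
            tr_x = float(np.sum(C * C))
            zu = Z.T @ u
            d_rss = -float(zu @ zu)
            grad[k] = g * (tr_v - tr_x + (n - p) * d_rss / rss)
        return crit, grad

    def _unprofiled_m2loglik(self, variances: np.ndarray) -> float:
        """-2 REML loglik as a function of (sigma2_1..q, sigma2_e)."""
        n, p = self.exog.shape
        s2 = variances[:-1]
        s2e = variances[-1]
        V = s2e * np.eye(n)
        for s, (_, Z) in zip(s2, self.re_design):
            V += s * (Z @ Z.T)
        L = linalg.cholesky(V, lower=True)
        Xi = linalg.solve_triangular(L, self.exog, lower=True)
        yi = linalg.solve_triangular(L, self.endog, lower=True)
        XtX = Xi.T @ Xi
        Lx = linalg.cholesky(XtX, lower=True)
        beta = linalg.cho_solve((Lx, True), Xi.T @ yi)
        r = yi - Xi @ beta
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
        logdet_xtx = 2.0 * float(np.sum(np.log(np.diag(Lx))))
        return logdet_v + logdet_xtx + float(r @ r) + (n - p) * np.log(2 * np.pi)

    def _vcov_beta(self, variances: np.ndarray) -> np.ndarray:
        n = self.nobs
        s2 = variances[:-1]
        s2e = variances[-1]
        V = s2e * np.eye(n)
        for s, (_, Z) in zip(s2, self.re_design):
            V += s * (Z @ Z.T)
        L = linalg.cholesky(V, lower=True)
        Xi = linalg.solve_triangular(L, self.exog, lower=True)
        return linalg.inv(Xi.T @ Xi)

    def fit(self, n_starts: int = 2, maxiter: int = 200,
            tol: float = 1e-10) -> "MixedModelResults":
        """REML fit.

        ``n_starts`` initial variance-ratio vectors (1.0 and 0.05) guard
        against boundary traps; non-convergence is reported on the results
        object, never raised silently.
        """
        n, p = self.exog.shape
        q = len(self.re_design)

        if q == 0:
            return self._fit_ols()

        starts = [np.zeros(q), np.log(np.full(q, 0.05))][:max(1, n_starts)]
        best = None
        converged = False
        for x0 in starts:
            res = optimize.minimize(
                lambda lg: self._profiled(lg, want_grad=True),
                x0, jac=True, method="L-BFGS-B",
                bounds=[(np.log(_GAMMA_FLOOR), np.log(_GAMMA_CEIL))] * q,
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            converged = converged or bool(res.success)

        gamma = np.exp(best.x)
        # final pass at the optimum for estimates
        V = np.eye(n)
        for g, (_, Z) in zip(gamma, self.re_design):
            V += g * (Z @ Z.T)
        L = linalg.cholesky(V, lower=True)
        Xi = linalg.solve_triangular(L, self.exog, lower=True)
        yi = linalg.solve_triangular(L, self.endog, lower=True)
        XtX = Xi.T @ Xi
        beta = linalg.solve(XtX, Xi.T @ yi, assume_a="pos")
        r = yi - Xi @ beta
        sigma2_e = float(r @ r) / (n - p)
        vcov = sigma2_e * linalg.inv(XtX)
        m2ll = best.fun + (n - p) * (1.0 + np.log(2 * np.pi) - np.log(n - p))

        boundary = {name for g, (name, _) in zip(gamma, self.re_design)
                    if g <= _BOUNDARY_TOL}
        varcomps = {}
        for g, (name, _) in zip(gamma, self.re_design):
            varcomps[name] = 0.0 if name in boundary else g * sigma2_e
        varcomps["residual"] = sigma2_e

        return MixedModelResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            vcov_fixed=pd.DataFrame(vcov, index=self.exog_names,
                                    columns=self.exog_names),
            varcomps=varcomps,
            boundary=boundary,
            reml_loglik=-0.5 * m2ll,
            converged=converged,
            _gamma=gamma,
        )

    def _fit_ols(self) -> "MixedModelResults":
        n, p = self.exog.shape
        beta, _, _, _ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        r = self.endog - self.exog @ beta
        sigma2 = float(r @ r) / (n - p)
        vcov = sigma2 * linalg.inv(self.exog.T @ self.exog)
        sign, logdet_xtx = slogdet(self.exog.T @ self.exog)
        m2ll = ((n - p) * np.log(2 * np.pi * sigma2) + logdet_xtx
                + float(r @ r) / sigma2)
        res = MixedModelResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            vcov_fixed=pd.DataFrame(vcov, index=self.exog_names,
                                    columns=self.exog_names),
            varcomps={"residual": sigma2},
            boundary=set(),
            reml_loglik=-0.5 * m2ll,
            converged=True,
            _gamma=np.empty(0),
        )
        res._df = pd.Series(float(n - p), index=self.exog_names)
        return res


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResults:
    """REML estimates with Wald inference and Satterthwaite df."""

    model: MixedModel
    params: pd.Series
    vcov_fixed: pd.DataFrame
    varcomps: dict[str, float]
    boundary: set[str]
    reml_loglik: float
    converged: bool
    _gamma: np.ndarray
    _df: pd.Series | None = None
    df_fallback: bool = field(default=False)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov_fixed.to_numpy())),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def df(self) -> pd.Series:
        """Satterthwaite denominator df per coefficient (lazy)."""
        if self._df is None:
            self._df = self._satterthwaite_all()
        return self._df

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues.to_numpy()), self.df.to_numpy()),
            index=self.params.index)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fixed-effects (marginal) fitted values."""
        return self.model.exog @ self.params.to_numpy()

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        crit = stats.t.ppf(1 - alpha / 2, self.df.to_numpy())
        lo = self.params - crit * self.bse
        hi = self.params + crit * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    # -- Satterthwaite ------------------------------------------------------

    def _theta_hat(self) -> np.ndarray:
        names = [name for name, _ in self.model.re_design]
        return np.array([self.varcomps[nm] for nm in names]
                        + [self.varcomps["residual"]])

    def _satterthwaite_all(self) -> pd.Series:
        n, p = self.model.exog.shape
        resid_df = float(n - p)
        if not self.model.re_design:
            return pd.Series(resid_df, index=self.params.index)

        theta_full = self._theta_hat()
        # components at (or numerically indistinguishable from) the boundary
        # stay fixed at 0: the REML surface is one-sided there and would make
        # the Hessian singular.  "Negligible" is judged by the component's
        # contribution to response variance relative to the residual.
        contrib = np.array([
            theta_full[i] * float(np.mean(np.sum(Z * Z, axis=1)))
            for i, (_, Z) in enumerate(self.model.re_design)])
        free = [i for i in range(len(theta_full) - 1)
                if contrib[i] > 1e-4 * theta_full[-1]]
        free.append(len(theta_full) - 1)  # residual variance always free
        theta = theta_full[free]
        d = len(theta)
        scale = np.maximum(np.abs(theta), 1e-3 * theta[-1])
        h = 1e-4 * scale

        def expand(t):
            full = np.zeros_like(theta_full)
            full[free] = np.maximum(t, 1e-12 * theta[-1])
            return full

        def f(t):
            return self.model._unprofiled_m2loglik(expand(t))

        # Hessian of -2 loglik on the variance scale (central differences)
        H = np.empty((d, d))
        f0 = f(theta)
        try:
            for i in range(d):
                for j in range(i, d):
                    ei = np.zeros(d); ei[i] = h[i]
                    ej = np.zeros(d); ej[j] = h[j]
                    if i == j:
                        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
                    else:
                        H[i, j] = H[j, i] = (
                            f(theta + ei + ej) - f(theta + ei - ej)
                            - f(theta - ei + ej) + f(theta - ei - ej)
                        ) / (4 * h[i] * h[j])
            A = 2.0 * linalg.inv(H)   # asymptotic vcov of the variance estimates
        except linalg.LinAlgError:
            A = None

        dfs = np.full(p, resid_df)
        if A is not None and np.all(np.isfinite(A)):
            # gradient of c' vcov(beta) c wrt each variance, per coefficient
            grads = np.empty((d, p))
            ok = True
            for i in range(d):
                ei = np.zeros(d); ei[i] = h[i]
                try:
                    vp = np.diag(self.model._vcov_beta(expand(theta + ei)))
                    vm = np.diag(self.model._vcov_beta(expand(theta - ei)))
                except linalg.LinAlgError:
                    ok = False
                    break
                grads[i] = (vp - vm) / (2 * h[i])
            if ok:
                var_beta = np.diag(self.vcov_fixed.to_numpy())
                for j in range(p):
                    g = grads[:, j]
                    denom = float(g @ A @ g)
                    if denom > 0:
                        dfs[j] = min(2.0 * var_beta[j] ** 2 / denom, resid_df)
                    else:
                        self.df_fallback = True
            else:
                self.df_fallback = True
        else:
            self.df_fallback = True
        if self.df_fallback:
            warnings.warn("Satterthwaite Hessian singular; falling back to "
                          "residual df", stacklevel=2)
        return pd.Series(dfs, index=self.params.index)

    # -- presentation -------------------------------------------------------

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params,
            "s.e.": self.bse,
            "df": self.df,
            "t": self.tvalues,
            "p": self.pvalues,
        })

    def summary(self) -> str:
        lines = ["Linear mixed model (REML)",
                 f"n = {self.nobs}   REML loglik = {self.reml_loglik:.2f}   "
                 f"converged = {self.converged}", ""]
        tab = self.coef_table()
        lines.append(tab.to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append("Variance components:")
        for name, v in self.varcomps.items():
            flag = "  (boundary)" if name in self.boundary else ""
            lines.append(f"  {name:<28s} {v:12.1f}{flag}")
        return "\n".join(lines)


def satterthwaite_df(fit: MixedModelResults, term: str) -> float:
    """Satterthwaite denominator df for one fixed term."""
    if not fit.converged:
        raise ValueError("fit did not converge; df approximation unreliable")
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not in model")
    return float(fit.df[term])
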