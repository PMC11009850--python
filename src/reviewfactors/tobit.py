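"""Two-limit Tobit (censored Gaussian) regression by maximum likelihood.

The latent model is y* = X beta + e, e ~ N(0, sigma^2), with the observed
response censored at known limits: y = lower when y* <= lower, y = upper
when y* >= upper, y = y* otherwise.  The log-likelihood mixes density terms
for uncensored rows with normal-CDF mass terms at each limit:

    sum_unc [ log phi((y - Xb)/s) - log s ]
  + sum_low   log Phi((L - Xb)/s)
  + sum_upp   log(1 - Phi((U - Xb)/s))

Estimation is quasi-Newton (BFGS) on (beta, log sigma) with the analytic
gradient, started from the least-squares fit on the uncensored rows.
Standard errors come from the inverse observed information (numerical
Hessian at the optimum, in the (beta, sigma) parameterization); inference
uses asymptotic normal theory (z statistics, 95% CIs at +/-1.96 SE).

Here the covariates are per-review topic probabilities and the response is
a rating deviation bounded in [0, 4], but the class is a generic two-limit
Tobit.  Note a full probability simplex plus an intercept is exactly
collinear: drop one topic column (a reference topic) or the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, EstimationError

__all__ = ["TobitModel", "TobitResults", "tobit_loglik", "vif"]


def _design(X, names):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def tobit_loglik(
    beta: np.ndarray,
    log_sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    lower: float = 0.0,
    upper: float | None = 4.0,
) -> float:
    """Two-limit Tobit log-likelihood at (beta, log sigma).

    Parameterized in log sigma so the scale is unconstrained during
    optimization.  Rows must satisfy lower <= y <= upper.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    sigma = np.exp(log_sigma)
    if (y < lower).any():
        raise DataError("response below the lower limit")
    if upper is not None and (y > upper).any():
        raise DataError("response above the upper limit")
    xb = X @ beta
    at_low = y <= lower
    at_up = np.zeros_like(at_low) if upper is None else (y >= upper)
    unc = ~(at_low | at_up)
    ll = 0.0
    if unc.any():
        r = (y[unc] - xb[unc]) / sigma
        ll += stats.norm.logpdf(r).sum() - unc.sum() * np.log(sigma)
    if at_low.any():
        ll += stats.norm.logcdf((lower - xb[at_low]) / sigma).sum()
    if at_up.any():
        ll += stats.norm.logsf((upper - xb[at_up]) / sigma).sum()
    return float(ll)


class TobitModel:
    """Censored Gaussian regression model.

    Parameters
    ----------
    endog
        Response vector, each value within [lower, upper].
    exog
        Design matrix (add an intercept column yourself or via
        ``from_dataframe``).  Must have full column rank; the constructor
        names the collinear columns otherwise.
    lower, upper
        Censoring limits.  ``upper=None`` disables the upper limit
        (classical one-sided Tobit).
    """

    def __init__(
        self,
        endog,
        exog,
        lower: float = 0.0,
        upper: float | None = 4.0,
        exog_names: Sequence[str] | None = None,
    ):
        X, names = _design(exog, exog_names)
        y = np.asarray(endog, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise DataError("endog and exog row counts differ")
        if upper is not None and not lower < upper:
            raise DataError("lower limit must be below upper limit")
        if (y < lower).any() or (upper is not None and (y > upper).any()):
            raise DataError("response outside the censoring limits")
        n, p = X.shape
        if n <= p + 2:
            raise DataError(f"need n > p + 2 observations (n={n}, p={p})")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise EstimationError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(self._collinear_columns(X, names))
            )
        self.endog = y
        self.exog = X
        self.exog_names = names
        self.lower = float(lower)
        self.upper = None if upper is None else float(upper)
        self._at_low = y <= self.lower
        self._at_up = (
            np.zeros(n, dtype=bool) if self.upper is None else y >= self.upper
        )
        self._unc = ~(self._at_low | self._at_up)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        covariates: Sequence[str],
        lower: float = 0.0,
        upper: float | None = 4.0,
        intercept: bool = True,
    ) -> "TobitModel":
        X = data[list(covariates)].to_numpy(dtype=float)
        names = list(covariates)
        if intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["const"] + names
        return cls(data[response].to_numpy(dtype=float), X,
                   lower=lower, upper=upper, exog_names=names)

    @staticmethod
    def _collinear_columns(X, names) -> list[str]:
        # columns with weight in the null space of X
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        tol = s.max() * max(X.shape) * np.finfo(float).eps
        null = vt[s < tol]
        if null.size == 0:
            return []
        weight = np.abs(null).max(axis=0)
        return [names[j] for j in np.nonzero(weight > 1e-8)[0]]

    # --- likelihood ------------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at params = (beta, log sigma)."""
        return tobit_loglik(
            params[:-1], params[-1], self.exog, self.endog,
            self.lower, self.upper,
        )

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of ``loglike`` wrt (beta, log sigma)."""
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        X, y = self.exog, self.endog
        xb = X @ beta
        g_beta = np.zeros(X.shape[1])
        g_ls = 0.0
        unc, at_low, at_up = self._unc, self._at_low, self._at_up
        if unc.any():
            r = (y[unc] - xb[unc]) / sigma
            g_beta += X[unc].T @ r / sigma
            g_ls += float((r**2 - 1.0).sum())
        if at_low.any():
            a = (self.lower - xb[at_low]) / sigma
            lam = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))
            g_beta -= X[at_low].T @ lam / sigma
            g_ls -= float((lam * a).sum())
        if at_up.any():
            b = (self.upper - xb[at_up]) / sigma
            lam = np.exp(stats.norm.logpdf(b) - stats.norm.logsf(b))
            g_beta += X[at_up].T @ lam / sigma
            g_ls += float((lam * b).sum())
        return np.append(g_beta, g_ls)

    def _start_params(self) -> np.ndarray:
        """OLS on the uncensored rows; falls back to all rows if too few."""
        mask = self._unc if self._unc.sum() > self.exog.shape[1] + 1 else slice(None)
        Xu, yu = self.exog[mask], self.endog[mask]
        beta0, *_ = np.linalg.lstsq(Xu, yu, rcond=None)
        resid = yu - Xu @ beta0
        dof = max(1, len(yu) - self.exog.shape[1])
        sigma0 = max(np.sqrt(resid @ resid / dof), 1e-3)
        return np.append(beta0, np.log(sigma0))

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 500,
        gtol: float = 1e-8,
    ) -> "TobitResults":
        """Maximize the likelihood; non-convergence is flagged, not raised."""
        x0 = self._start_params() if start_params is None else np.asarray(start_params)
        n = self.endog.shape[0]
        # optimize the mean log-likelihood so the gradient tolerance is
        # independent of the sample size
        res = optimize.minimize(
            lambda p: -self.loglike(p) / n,
            x0,
            jac=lambda p: -self.score(p) / n,
            method="BFGS",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        res.fun *= n
        beta = res.x[:-1]
        sigma = float(np.exp(res.x[-1]))
        cov = self._covariance(beta, sigma)
        return TobitResults(
            model=self,
            params=beta,
            sigma=sigma,
            cov_params=cov,
            llf=float(-res.fun),
            llf_start=self.loglike(x0),
            converged=bool(res.success),
            n_iter=int(res.get("nit", -1)),
        )

    def _covariance(self, beta, sigma) -> np.ndarray:
        """Inverse observed information in the (beta, sigma) parameterization,
        from a central-difference Hessian of the log-likelihood."""
        theta = np.append(beta, sigma)

        def ll(t):
            return tobit_loglik(
                t[:-1], np.log(t[-1]), self.exog, self.endog,
                self.lower, self.upper,
            )

        k = theta.size
        h = np.maximum(np.abs(theta), 1.0) * 1e-5
        H = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                f = (
                    ll(theta + ei + ej) - ll(theta + ei - ej)
                    - ll(theta - ei + ej) + ll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
                H[i, j] = H[j, i] = f
        info = -H
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
        return cov


@dataclass
class TobitResults:
    """MLE output: coefficients, scale, asymptotic inference, censoring
    bookkeeping."""

    model: TobitModel
    params: np.ndarray
    sigma: float
    cov_params: np.ndarray
    llf: float
    llf_start: float
    converged: bool
    n_iter: int

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the regression coefficients."""
        d = np.diag(self.cov_params)[:-1]
        return np.sqrt(np.where(d > 0, d, np.nan))

    @property
    def bse_sigma(self) -> float:
        d = self.cov_params[-1, -1]
        return float(np.sqrt(d)) if d > 0 else float("nan")

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided normal p-values."""
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        zc = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - zc * self.bse, self.params + zc * self.bse]
        )

    @property
    def n_obs(self) -> int:
        return self.model.endog.shape[0]

    @property
    def n_lower_censored(self) -> int:
        return int(self.model._at_low.sum())

    @property
    def n_upper_censored(self) -> int:
        return int(self.model._at_up.sum())

    @property
    def n_uncensored(self) -> int:
        return int(self.model._unc.sum())

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table shaped like a published regression table:
        factor, beta, 95% CI, SE, z, p."""
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "factor": self.model.exog_names,
                "beta": self.params,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "se": self.bse,
                "z": self.zvalues,
                "p_value": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            "Two-limit Tobit regression (maximum likelihood)",
            f"n = {self.n_obs}  (lower-censored {self.n_lower_censored}, "
            f"upper-censored {self.n_upper_censored}, "
            f"uncensored {self.n_uncensored})",
            f"log-likelihood = {self.llf:.3f}   sigma = {self.sigma:.4f} "
            f"(SE {self.bse_sigma:.4f})   converged = {self.converged}",
            "",
            self.to_frame().to_string(
                index=False, float_format=lambda v: f"{v: .4f}"
            ),
        ]
        return "\n".join(lines)


def vif(X, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j), where R2_j is
    from regressing column j on the other columns plus an intercept.

    Perfect collinearity yields infinity with a warning rather than an
    exception.  Values below 5 are conventionally read as no problematic
    multicollinearity.
    """
    X, names = _design(X, names)
    n, p = X.shape
    if p < 2:
        raise DataError("VIF requires at least 2 covariates")
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0.0 or ss_res / ss_tot < 1e-12:
            warnings.warn(
                f"perfect collinearity involving column {names[j]!r}; VIF = inf"
            )
            out[j] = np.inf
        else:
            out[j] = 1.0 / (ss_res / ss_tot)
    return pd.Series(out, index=names, name="vif")
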