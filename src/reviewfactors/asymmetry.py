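"""Two-factor (motivational/hygienic) asymmetry analysis.

Two Tobit models with identical topic-probability covariates are fitted,
one for the positive rating deviation (satisfaction) and one for the
negative deviation (dissatisfaction).  For each topic a Wald statistic
compares the absolute effect sizes across the two models,

    W = (|b_PD| - |b_ND|)^2 / (SE_PD^2 + SE_ND^2),   W ~ chi2(1) under H0,

treating the cross-model covariance as zero (the two fits share the same
observations, so this is a working assumption; a paired bootstrap variant
quantifies its error).  Each topic is then classified: motivational if it
significantly raises satisfaction but not dissatisfaction, hygienic for
the converse, mixed if both, not significant otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, EstimationError
from .tobit import TobitModel, TobitResults

__all__ = [
    "wald_statistic",
    "wald_asymmetry",
    "classify_factor",
    "TwoFactorAnalysis",
    "TwoFactorResults",
    "run_two_factor_analysis",
    "holm_adjust",
]


def wald_statistic(
    beta_a: float, se_a: float, beta_b: float, se_b: float
) -> tuple[float, float]:
    """Wald test of |beta_a| = |beta_b| across two independent fits."""
    if se_a <= 0 or se_b <= 0:
        raise EstimationError("standard errors must be positive for the Wald test")
    w = (abs(beta_a) - abs(beta_b)) ** 2 / (se_a**2 + se_b**2)
    p = float(stats.chi2.sf(w, df=1))
    return float(w), p


def wald_asymmetry(
    fit_pd: TobitResults, fit_nd: TobitResults, topic: str
) -> tuple[float, float]:
    """Wald asymmetry test for one named covariate of two fitted models."""
    for fit in (fit_pd, fit_nd):
        if topic not in fit.model.exog_names:
            raise DataError(f"covariate {topic!r} not present in both fits")
    ia = fit_pd.model.exog_names.index(topic)
    ib = fit_nd.model.exog_names.index(topic)
    return wald_statistic(
        fit_pd.params[ia], fit_pd.bse[ia], fit_nd.params[ib], fit_nd.bse[ib]
    )


def classify_factor(
    beta_pd: float,
    p_pd: float,
    beta_nd: float,
    p_nd: float,
    alpha: float = 0.05,
) -> str:
    """Herzberg-style classification from the two per-topic effects.

    A significant positive effect on the satisfaction (PD) model alone is
    motivational; on the dissatisfaction (ND) model alone, hygienic; on
    both, mixed; otherwise not significant.
    """
    if not (0.0 <= p_pd <= 1.0 and 0.0 <= p_nd <= 1.0):
        raise DataError("p-values must lie in [0, 1]")
    pos_pd = p_pd < alpha and beta_pd > 0
    pos_nd = p_nd < alpha and beta_nd > 0
    if pos_pd and not pos_nd:
        return "motivational"
    if pos_nd and not pos_pd:
        return "hygienic"
    if pos_pd and pos_nd:
        return "mixed"
    return "not_significant"


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


class TwoFactorAnalysis:
    """Paired PD/ND Tobit analysis over topic-probability covariates.

    Parameters
    ----------
    theta
        (n, K) per-review topic probabilities (rows on or near the simplex).
    pd_dev, nd_dev
        Positive and negative rating deviations, each in [lower, upper].
    topic_labels
        Optional names per topic column.
    exclude
        Topic indices left out of both models entirely (e.g. a topic that
        carries pure attitude rather than an app attribute).
    reference
        Topic dropped to break the simplex/intercept collinearity when an
        intercept is included; default is the largest-share topic.  Ignored
        when ``intercept=False``.
    """

    def __init__(
        self,
        theta: np.ndarray,
        pd_dev: np.ndarray,
        nd_dev: np.ndarray,
        topic_labels: Sequence[str] | None = None,
        exclude: Sequence[int] = (),
        reference: int | None = None,
        intercept: bool = True,
        lower: float = 0.0,
        upper: float | None = 4.0,
        alpha: float = 0.05,
    ):
        theta = np.asarray(theta, dtype=float)
        pd_dev = np.asarray(pd_dev, dtype=float)
        nd_dev = np.asarray(nd_dev, dtype=float)
        if not (theta.shape[0] == pd_dev.shape[0] == nd_dev.shape[0]):
            raise DataError("theta rows and deviation rows must align")
        k = theta.shape[1]
        if topic_labels is None:
            topic_labels = [f"topic_{j}" for j in range(k)]
        if len(topic_labels) != k:
            raise DataError("one label per topic column is required")
        exclude = set(int(j) for j in exclude)
        included = [j for j in range(k) if j not in exclude]
        if intercept:
            if reference is None:
                shares = theta[:, included].mean(axis=0)
                reference = included[int(np.argmax(shares))]
            elif reference not in included:
                raise DataError("reference topic must be an included topic")
            covar_idx = [j for j in included if j != reference]
        else:
            reference = None
            covar_idx = included
        self.theta = theta
        self.pd_dev = pd_dev
        self.nd_dev = nd_dev
        self.topic_labels = list(topic_labels)
        self.exclude = sorted(exclude)
        self.reference = reference
        self.intercept = bool(intercept)
        self.covar_idx = covar_idx
        self.lower = lower
        self.upper = upper
        self.alpha = float(alpha)

    def _design(self, theta: np.ndarray):
        X = theta[:, self.covar_idx]
        names = [self.topic_labels[j] for j in self.covar_idx]
        if self.intercept:
            X = np.column_stack([np.ones(theta.shape[0]), X])
            names = ["const"] + names
        return X, names

    def fit(self) -> "TwoFactorResults":
        X, names = self._design(self.theta)
        fit_pd = TobitModel(
            self.pd_dev, X, lower=self.lower, upper=self.upper, exog_names=names
        ).fit()
        fit_nd = TobitModel(
            self.nd_dev, X, lower=self.lower, upper=self.upper, exog_names=names
        ).fit()
        rows = []
        for j in self.covar_idx:
            name = self.topic_labels[j]
            i = names.index(name)
            w, pw = wald_statistic(
                fit_pd.params[i], fit_pd.bse[i], fit_nd.params[i], fit_nd.bse[i]
            )
            rows.append(
                {
                    "topic": j,
                    "label": name,
                    "beta_pd": fit_pd.params[i],
                    "se_pd": fit_pd.bse[i],
                    "p_pd": fit_pd.pvalues[i],
                    "beta_nd": fit_nd.params[i],
                    "se_nd": fit_nd.bse[i],
                    "p_nd": fit_nd.pvalues[i],
                    "wald_stat": w,
                    "wald_p": pw,
                    "factor_class": classify_factor(
                        fit_pd.params[i], fit_pd.pvalues[i],
                        fit_nd.params[i], fit_nd.pvalues[i],
                        self.alpha,
                    ),
                }
            )
        table = pd.DataFrame(rows)
        table["wald_p_holm"] = holm_adjust(table["wald_p"].to_numpy())
        return TwoFactorResults(model=self, fit_pd=fit_pd, fit_nd=fit_nd,
                                table=table)

    def fit_bootstrap(self, n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
        """Paired-bootstrap sensitivity check for the independence working
        assumption: resample reviews, refit both models, and use the
        bootstrap SE of |b_PD| - |b_ND| in the Wald denominator."""
        rng = np.random.default_rng(seed)
        n = self.theta.shape[0]
        base = self.fit()
        diffs = np.empty((n_boot, len(self.covar_idx)))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb, names = self._design(self.theta[idx])
            try:
                fp = TobitModel(self.pd_dev[idx], Xb, lower=self.lower,
                                upper=self.upper, exog_names=names).fit()
                fn = TobitModel(self.nd_dev[idx], Xb, lower=self.lower,
                                upper=self.upper, exog_names=names).fit()
            except EstimationError:
                diffs[b] = np.nan
                continue
            for c, j in enumerate(self.covar_idx):
                i = names.index(self.topic_labels[j])
                diffs[b, c] = abs(fp.params[i]) - abs(fn.params[i])
        out = base.table[["topic", "label", "wald_stat", "wald_p"]].copy()
        boot_se = np.nanstd(diffs, axis=0, ddof=1)
        point = np.abs(base.table["beta_pd"].to_numpy()) - np.abs(
            base.table["beta_nd"].to_numpy()
        )
        w_boot = point**2 / boot_se**2
        out["boot_se_diff"] = boot_se
        out["wald_stat_boot"] = w_boot
        out["wald_p_boot"] = stats.chi2.sf(w_boot, df=1)
        return out


@dataclass
class TwoFactorResults:
    """Per-topic asymmetry table plus the two underlying Tobit fits."""

    model: TwoFactorAnalysis
    fit_pd: TobitResults
    fit_nd: TobitResults
    table: pd.DataFrame

    def summary(self) -> str:
        cols = [
            "label", "beta_pd", "p_pd", "beta_nd", "p_nd",
            "wald_stat", "wald_p", "factor_class",
        ]
        head = (
            "Two-factor asymmetry analysis "
            f"(alpha = {self.model.alpha}, "
            f"loglik PD = {self.fit_pd.llf:.3f}, ND = {self.fit_nd.llf:.3f})"
        )
        return head + "\n" + self.table[cols].to_string(
            index=False, float_format=lambda v: f"{v: .4f}"
        )


def run_two_factor_analysis(
    theta: np.ndarray,
    pd_dev: np.ndarray,
    nd_dev: np.ndarray,
    **kwargs,
) -> TwoFactorResults:
    """One-call wrapper: build the paired analysis and fit it."""
    return TwoFactorAnalysis(theta, pd_dev, nd_dev, **kwargs).fit()
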