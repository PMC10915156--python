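"""Regression layer: linear mediator models, logistic outcome models,
Wald interaction screens, Tjur's coefficient of discrimination and
group-wise descriptives.

Fits are ordinary least squares / maximum-likelihood logistic
regressions (via statsmodels) wrapped in a :class:`GLMFit` that carries
exactly what the mediation decomposition needs: named coefficients,
their covariance, the residual variance of linear fits, and the design
column means used for covariate conditioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GLMFit",
    "PerfectSeparationError",
    "RankDeficientError",
    "fit_linear",
    "fit_logistic",
    "wald_interaction_test",
    "tjur_r2",
    "association_table",
    "describe_by_group",
]

INTERCEPT = "const"


class PerfectSeparationError(RuntimeError):
    """Logistic likelihood unbounded: a predictor separates the classes."""


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (collinear or constant columns)."""


@dataclass
class GLMFit:
    """A fitted linear or logistic model.

    Attributes
    ----------
    kind : ``"linear"`` or ``"logistic"``.
    coef : named coefficient vector (intercept under ``"const"``).
    vcov : coefficient covariance matrix.
    sigma2 : residual variance (linear fits only).
    n : rows used in the fit.
    x_means : mean of each design column over the fitted rows, used as
        the default covariate-conditioning point downstream.
    """

    kind: str
    coef: pd.Series
    vcov: pd.DataFrame
    n: int
    sigma2: Optional[float] = None
    x_means: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    fitted: Optional[np.ndarray] = None
    response: Optional[np.ndarray] = None
    response_name: str = ""

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.coef.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        se = self.se()
        return pd.DataFrame(
            {"lower": self.coef - z * se, "upper": self.coef + z * se}
        )

    def pvalues(self) -> pd.Series:
        z = self.coef / self.se()
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.coef.index)


def _design(
    table: pd.DataFrame, response: str, terms: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series]:
    cols = [response] + list(terms)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    data = table[cols].dropna()
    y = data[response]
    x = sm.add_constant(data[list(terms)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        kept: list[str] = []
        for c in x.columns:
            sub = x[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(sub) == len(kept) + 1:
                kept.append(c)
            else:
                bad.append(c)
        raise RankDeficientError(
            f"design matrix rank deficient; offending column(s): {bad}"
        )
    return x, y


def fit_linear(
    table: pd.DataFrame, response: str, terms: Sequence[str] = ()
) -> GLMFit:
    """Ordinary least squares of ``response`` on ``terms`` (+ intercept).

    Rows with a missing value in any used column are dropped. The
    residual variance uses the n - p denominator and the coefficient
    covariance is sigma2 * (X'X)^-1.
    """
    x, y = _design(table, response, terms)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"n={n} rows insufficient for {p} parameters")
    res = sm.OLS(y.astype(float), x).fit()
    sigma2 = float(res.ssr / (n - p))
    xtx_inv = np.linalg.inv(x.T.to_numpy() @ x.to_numpy())
    vcov = pd.DataFrame(sigma2 * xtx_inv, index=x.columns, columns=x.columns)
    return GLMFit(
        kind="linear",
        coef=res.params,
        vcov=vcov,
        n=n,
        sigma2=sigma2,
        x_means=x.mean(),
        fitted=np.asarray(res.fittedvalues),
        response=y.to_numpy(dtype=float),
        response_name=response,
    )


def fit_logistic(
    table: pd.DataFrame, response: str, terms: Sequence[str] = ()
) -> GLMFit:
    """Maximum-likelihood logistic regression with Wald covariance.

    Requires both outcome classes present; perfect separation is
    detected and reported rather than returning runaway coefficients.
    """
    x, y = _design(table, response, terms)
    yv = y.to_numpy(dtype=float)
    classes = np.unique(yv)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError(f"response {response!r} must be coded 0/1")
    if len(classes) < 2:
        raise ValueError(f"response {response!r} has a single class")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yv, x).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on hard separation
            raise PerfectSeparationError(str(exc)) from exc
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if (
        not np.all(np.isfinite(params))
        or not np.all(np.isfinite(bse))
        or np.any(np.abs(params) > 50)
    ):
        raise PerfectSeparationError(
            f"logistic fit of {response!r} did not stabilise "
            "(perfect or quasi-complete separation)"
        )
    vcov = pd.DataFrame(
        np.asarray(res.cov_params()), index=x.columns, columns=x.columns
    )
    return GLMFit(
        kind="logistic",
        coef=pd.Series(params, index=x.columns),
        vcov=vcov,
        n=len(yv),
        x_means=x.mean(),
        fitted=np.asarray(res.predict(x)),
        response=yv,
        response_name=response,
    )


def wald_interaction_test(fit: GLMFit, term: str) -> float:
    """Two-sided normal Wald p-value for one coefficient (used to screen
    exposure-mediator and exposure-sex product terms)."""
    if term not in fit.coef.index:
        raise KeyError(f"term {term!r} not in fit")
    se = math.sqrt(fit.vcov.loc[term, term])
    if se == 0:
        return 0.0 if fit.coef[term] != 0 else 1.0
    z = fit.coef[term] / se
    return float(2 * stats.norm.sf(abs(z)))


def tjur_r2(fit: GLMFit, table: Optional[pd.DataFrame] = None) -> float:
    """Tjur's coefficient of discrimination: mean fitted probability
    among cases minus mean among controls."""
    if fit.kind != "logistic":
        raise ValueError("Tjur R2 applies to logistic fits")
    if table is not None:
        terms = [c for c in fit.coef.index if c != INTERCEPT]
        x, y = _design(table, fit.response_name, terms)
        lp = x.to_numpy() @ fit.coef.reindex(x.columns).to_numpy()
        p = 1.0 / (1.0 + np.exp(-lp))
        yv = y.to_numpy(dtype=float)
    else:
        p, yv = fit.fitted, fit.response
    if p is None or yv is None:
        raise ValueError("fit carries no fitted values")
    return float(p[yv == 1].mean() - p[yv == 0].mean())


def association_table(fit: GLMFit, level: float = 0.95) -> pd.DataFrame:
    """Per-term report: estimate (B for linear, OR for logistic),
    Wald confidence interval and p-value."""
    ci = fit.conf_int(level)
    out = pd.DataFrame(
        {
            "term": fit.coef.index,
            "estimate": fit.coef.to_numpy(),
            "ci_lower": ci["lower"].to_numpy(),
            "ci_upper": ci["upper"].to_numpy(),
            "p_value": fit.pvalues().to_numpy(),
        }
    )
    if fit.kind == "logistic":
        for c in ("estimate", "ci_lower", "ci_upper"):
            out[c] = np.exp(out[c])
    return out.reset_index(drop=True)


def describe_by_group(
    table: pd.DataFrame,
    group: str,
    continuous: Sequence[str],
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Descriptive comparison of two groups defined by a binary column.

    Continuous variables: mean (SD) per group and a two-sided Welch
    t-test. Categorical (binary) variables: count (%) per group and a
    chi-square test without continuity correction. Missing counts are
    reported per group.
    """
    g = table[group]
    if set(g.dropna().unique()) - {0, 1, 0.0, 1.0}:
        raise ValueError(f"group column {group!r} must be binary")
    g0 = table[g == 0]
    g1 = table[g == 1]
    rows = []
    for var in continuous:
        a, b = g0[var].dropna(), g1[var].dropna()
        if len(a) > 1 and len(b) > 1:
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "group0_stat": f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                "group1_stat": f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                "group0_value": a.mean(),
                "group1_value": b.mean(),
                "p_value": p,
                "missing0": int(g0[var].isna().sum()),
                "missing1": int(g1[var].isna().sum()),
            }
        )
    for var in categorical:
        a, b = g0[var].dropna(), g1[var].dropna()
        tab = np.array(
            [
                [(a == 0).sum(), (a == 1).sum()],
                [(b == 0).sum(), (b == 1).sum()],
            ]
        )
        if tab.sum(axis=0).min() > 0 and tab.sum(axis=1).min() > 0:
            p = float(stats.chi2_contingency(tab, correction=False)[1])
        else:
            p = float("nan")
        pct0 = 100 * (a == 1).mean() if len(a) else float("nan")
        pct1 = 100 * (b == 1).mean() if len(b) else float("nan")
        rows.append(
            {
                "variable": var,
                "type": "categorical",
                "group0_stat": f"{int((a == 1).sum())} ({pct0:.1f}%)",
                "group1_stat": f"{int((b == 1).sum())} ({pct1:.1f}%)",
                "group0_value": pct0,
                "group1_value": pct1,
                "p_value": p,
                "missing0": int(g0[var].isna().sum()),
                "missing1": int(g1[var].isna().sum()),
            }
        )
    return pd.DataFrame(rows)
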