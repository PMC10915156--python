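"""Regression-based counterfactual mediation on the odds-ratio scale.

For a binary exposure A, a continuous mediator M and a binary outcome Y,
two models are fitted:

    M = beta0 + beta1 A + beta2' C + eps,  eps ~ N(0, sigma^2)
    logit P(Y=1) = theta0 + theta1 A + theta2 M + theta3 A*M + theta4' C

and the natural direct (NDE), natural indirect (NIE) and total (TE)
effects for a change a* -> a are combinations of the coefficients.

Without exposure-mediator interaction (theta3 = 0):

    log OR_NDE = theta1 (a - a*)
    log OR_NIE = theta2 beta1 (a - a*)
    log OR_TE  = log OR_NDE + log OR_NIE        (exact product identity)

With interaction:

    log OR_NDE = [theta1 + theta3 (beta0 + beta1 a* + beta2'c
                  + theta2 sigma^2)](a - a*)
                 + 0.5 theta3^2 sigma^2 (a^2 - a*^2)
    log OR_NIE = (theta2 beta1 + theta3 beta1 a)(a - a*)

Standard errors come from the delta method: the gradient of each
log-effect with respect to the stacked (beta, theta) coefficient vector
is propagated through the block-diagonal covariance of the two fits
(the models are estimated separately, so cross-model covariance is
zero; sigma^2 is treated as fixed). These are odds-ratio-scale effects
conditional on the covariates, an approximation to risk-ratio-scale
natural effects that is accurate when the outcome is not too common.

The proportion mediated is NDE (NIE - 1) / (TE - 1) on the OR scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .impute import ImputedStack, pool_scalar
from .models import GLMFit, INTERCEPT, fit_linear, fit_logistic

__all__ = [
    "MediationSpec",
    "MediationDecomposition",
    "decompose",
    "delta_ci",
    "proportion_mediated",
    "mediate_pooled",
]


@dataclass(frozen=True)
class MediationSpec:
    """What to decompose: exposure/mediator/outcome columns, covariates,
    the exposure contrast (a vs a*), the interaction flag, and optional
    covariate-conditioning values (default: sample means)."""

    exposure: str
    mediator: str
    outcome: str
    covariates: tuple[str, ...] = ()
    a: float = 1.0
    a_star: float = 0.0
    interaction: bool = False
    cov_values: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.a == self.a_star:
            raise ValueError("exposure levels a and a_star must differ")


@dataclass
class Effect:
    """One effect on the OR scale with its log-scale uncertainty."""

    odds_ratio: float
    log_se: float
    ci_lower: float
    ci_upper: float

    @property
    def log(self) -> float:
        return math.log(self.odds_ratio)


@dataclass
class MediationDecomposition:
    """OR-scale total/natural-direct/natural-indirect effects plus the
    proportion mediated."""

    te: Effect
    nde: Effect
    nie: Effect
    proportion_mediated: float
    mediator: str = ""
    exposure: str = ""
    n: int = 0
    m: int = 1  # imputations pooled over

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name, eff in (("total", self.te), ("direct", self.nde), ("indirect", self.nie)):
            rows.append(
                {
                    "exposure": self.exposure,
                    "mediator": self.mediator,
                    "effect": name,
                    "odds_ratio": eff.odds_ratio,
                    "ci_lower": eff.ci_lower,
                    "ci_upper": eff.ci_upper,
                    "log_se": eff.log_se,
                }
            )
        out = pd.DataFrame(rows)
        out["proportion_mediated"] = [
            float("nan"), float("nan"), self.proportion_mediated,
        ]
        return out


def proportion_mediated(or_nde: float, or_nie: float, or_te: float) -> float:
    """Share of the total association transmitted through the mediator:
    NDE (NIE - 1) / (TE - 1). Negative values indicate inconsistent
    mediation; undefined at a null total effect."""
    if or_te <= 0 or or_nde <= 0 or or_nie <= 0:
        raise ValueError("odds ratios must be positive")
    if abs(or_te - 1.0) < 1e-12:
        raise ZeroDivisionError(
            "proportion mediated undefined: total-effect OR equals 1"
        )
    return or_nde * (or_nie - 1.0) / (or_te - 1.0)


def _cov_point(
    mediator_fit: GLMFit, spec: MediationSpec
) -> dict[str, float]:
    """Covariate values c at which conditional effects are reported."""
    if spec.cov_values is not None:
        return {k: float(spec.cov_values[k]) for k in spec.covariates}
    return {k: float(mediator_fit.x_means[k]) for k in spec.covariates}


def _log_effects_and_gradients(
    mediator_fit: GLMFit, outcome_fit: GLMFit, spec: MediationSpec
) -> tuple[dict[str, float], dict[str, dict[str, float]], list[str]]:
    """Log NDE/NIE/TE and their gradients w.r.t. the stacked coefficient
    vector. Stacked names are 'med:<term>' then 'out:<term>'."""
    a, a_star = spec.a, spec.a_star
    d = a - a_star
    b = mediator_fit.coef
    t = outcome_fit.coef
    beta1 = float(b[spec.exposure])
    theta1 = float(t[spec.exposure])
    theta2 = float(t[spec.mediator])
    int_term = f"{spec.exposure}:{spec.mediator}"
    med_names = [f"med:{k}" for k in b.index]
    out_names = [f"out:{k}" for k in t.index]
    stacked = med_names + out_names
    g_nde: dict[str, float] = {}
    g_nie: dict[str, float] = {}

    if not spec.interaction:
        log_nde = theta1 * d
        log_nie = theta2 * beta1 * d
        g_nde[f"out:{spec.exposure}"] = d
        g_nie[f"out:{spec.mediator}"] = beta1 * d
        g_nie[f"med:{spec.exposure}"] = theta2 * d
    else:
        if int_term not in t.index:
            raise KeyError(
                f"interaction requested but term {int_term!r} absent from outcome fit"
            )
        if mediator_fit.sigma2 is None:
            raise ValueError("mediator fit carries no residual variance sigma2")
        theta3 = float(t[int_term])
        sigma2 = float(mediator_fit.sigma2)
        beta0 = float(b[INTERCEPT])
        c = _cov_point(mediator_fit, spec)
        b2c = sum(float(b[k]) * c[k] for k in spec.covariates)
        kappa = beta0 + beta1 * a_star + b2c + theta2 * sigma2
        log_nde = (theta1 + theta3 * kappa) * d + 0.5 * theta3**2 * sigma2 * (
            a**2 - a_star**2
        )
        log_nie = (theta2 * beta1 + theta3 * beta1 * a) * d
        g_nde[f"out:{spec.exposure}"] = d
        g_nde[f"out:{int_term}"] = kappa * d + theta3 * sigma2 * (a**2 - a_star**2)
        g_nde[f"out:{spec.mediator}"] = theta3 * sigma2 * d
        g_nde[f"med:{INTERCEPT}"] = theta3 * d
        g_nde[f"med:{spec.exposure}"] = theta3 * a_star * d
        for k in spec.covariates:
            g_nde[f"med:{k}"] = theta3 * c[k] * d
        g_nie[f"out:{spec.mediator}"] = beta1 * d
        g_nie[f"out:{int_term}"] = beta1 * a * d
        g_nie[f"med:{spec.exposure}"] = (theta2 + theta3 * a) * d

    g_te = {k: g_nde.get(k, 0.0) + g_nie.get(k, 0.0) for k in set(g_nde) | set(g_nie)}
    effects = {"log_nde": log_nde, "log_nie": log_nie, "log_te": log_nde + log_nie}
    grads = {"log_nde": g_nde, "log_nie": g_nie, "log_te": g_te}
    return effects, grads, stacked


def delta_ci(
    mediator_fit: GLMFit,
    outcome_fit: GLMFit,
    spec: MediationSpec,
    level: float = 0.95,
) -> dict[str, dict[str, float]]:
    """Delta-method log-scale SEs and OR-scale CIs for NDE/NIE/TE.

    The stacked covariance is block diagonal (the two models are fitted
    separately); it must be positive semi-definite.
    """
    effects, grads, stacked = _log_effects_and_gradients(
        mediator_fit, outcome_fit, spec
    )
    nb = len(mediator_fit.coef)
    cov = np.zeros((len(stacked), len(stacked)))
    cov[:nb, :nb] = mediator_fit.vcov.to_numpy()
    cov[nb:, nb:] = outcome_fit.vcov.to_numpy()
    eig_min = float(np.linalg.eigvalsh((cov + cov.T) / 2).min())
    if eig_min < -1e-8 * max(1.0, float(np.abs(cov).max())):
        raise ValueError("assembled covariance is not positive semi-definite")
    idx = {name: i for i, name in enumerate(stacked)}
    z = stats.norm.ppf(0.5 + level / 2)
    out: dict[str, dict[str, float]] = {}
    for key, log_eff in effects.items():
        g = np.zeros(len(stacked))
        for name, val in grads[key].items():
            g[idx[name]] = val
        var = float(g @ cov @ g)
        se = math.sqrt(max(var, 0.0))
        out[key] = {
            "log": log_eff,
            "se": se,
            "ci_lower": math.exp(log_eff - z * se),
            "ci_upper": math.exp(log_eff + z * se),
        }
    return out


def decompose(
    mediator_fit: GLMFit,
    outcome_fit: GLMFit,
    spec: MediationSpec,
    level: float = 0.95,
) -> MediationDecomposition:
    """Counterfactual decomposition of the exposure-outcome odds ratio
    into natural direct and indirect effects, with delta-method CIs and
    the proportion mediated."""
    if mediator_fit.kind != "linear":
        raise ValueError("mediator model must be linear")
    if outcome_fit.kind != "logistic":
        raise ValueError("outcome model must be logistic")
    for term, fit in ((spec.exposure, mediator_fit), (spec.mediator, outcome_fit)):
        if term not in fit.coef.index:
            raise KeyError(f"term {term!r} missing from fit")
    res = delta_ci(mediator_fit, outcome_fit, spec, level=level)
    effs = {}
    for key in ("log_te", "log_nde", "log_nie"):
        r = res[key]
        effs[key] = Effect(
            odds_ratio=math.exp(r["log"]),
            log_se=r["se"],
            ci_lower=r["ci_lower"],
            ci_upper=r["ci_upper"],
        )
    try:
        pm = proportion_mediated(
            effs["log_nde"].odds_ratio,
            effs["log_nie"].odds_ratio,
            effs["log_te"].odds_ratio,
        )
    except ZeroDivisionError:
        pm = float("nan")
    return MediationDecomposition(
        te=effs["log_te"],
        nde=effs["log_nde"],
        nie=effs["log_nie"],
        proportion_mediated=pm,
        mediator=spec.mediator,
        exposure=spec.exposure,
        n=outcome_fit.n,
    )


def _fit_pair(
    table: pd.DataFrame, spec: MediationSpec
) -> tuple[GLMFit, GLMFit]:
    """Fit the mediator (linear) and outcome (logistic) models a single
    decomposition needs, on rows with observed exposure and outcome."""
    covs = list(spec.covariates)
    med_fit = fit_linear(table, spec.mediator, [spec.exposure] + covs)
    out_terms = [spec.exposure, spec.mediator]
    data = table
    if spec.interaction:
        int_term = f"{spec.exposure}:{spec.mediator}"
        data = table.copy()
        data[int_term] = data[spec.exposure] * data[spec.mediator]
        out_terms.append(int_term)
    out_fit = fit_logistic(data, spec.outcome, out_terms + covs)
    return med_fit, out_fit


def mediate_single(
    table: pd.DataFrame, spec: MediationSpec, level: float = 0.95
) -> MediationDecomposition:
    """Fit both models on one completed dataset and decompose."""
    med_fit, out_fit = _fit_pair(table, spec)
    return decompose(med_fit, out_fit, spec, level=level)


def mediate_pooled(
    stack: ImputedStack | Sequence[pd.DataFrame],
    spec: MediationSpec,
    level: float = 0.95,
) -> MediationDecomposition:
    """Decomposition over an imputed stack: both models are fitted per
    completed dataset, the log-scale effects and their delta variances
    are pooled by Rubin's rules, and the pooled effects are
    exponentiated. The proportion mediated is recomputed from the
    pooled odds ratios."""
    datasets = stack.datasets if isinstance(stack, ImputedStack) else list(stack)
    if not datasets:
        raise ValueError("empty stack")
    logs = {"log_te": [], "log_nde": [], "log_nie": []}
    vars_ = {"log_te": [], "log_nde": [], "log_nie": []}
    n = 0
    for ds in datasets:
        med_fit, out_fit = _fit_pair(ds, spec)
        res = delta_ci(med_fit, out_fit, spec, level=level)
        n = out_fit.n
        for key in logs:
            logs[key].append(res[key]["log"])
            vars_[key].append(res[key]["se"] ** 2)
    effs = {}
    for key in logs:
        q_bar, _w, _b, t_var, df = pool_scalar(logs[key], vars_[key])
        se = math.sqrt(t_var)
        q = stats.t.ppf(0.5 + level / 2, df)
        effs[key] = Effect(
            odds_ratio=math.exp(q_bar),
            log_se=se,
            ci_lower=math.exp(q_bar - q * se),
            ci_upper=math.exp(q_bar + q * se),
        )
    try:
        pm = proportion_mediated(
            effs["log_nde"].odds_ratio,
            effs["log_nie"].odds_ratio,
            effs["log_te"].odds_ratio,
        )
    except ZeroDivisionError:
        pm = float("nan")
    return MediationDecomposition(
        te=effs["log_te"],
        nde=effs["log_nde"],
        nie=effs["log_nie"],
        proportion_mediated=pm,
        mediator=spec.mediator,
        exposure=spec.exposure,
        n=n,
        m=len(datasets),
    )
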