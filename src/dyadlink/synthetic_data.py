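"""Synthetic parent-offspring dyad cohorts with known causal structure.

The generator emulates a two-generation loneliness study: parental
loneliness (exposure A, dichotomized UCLA-3) acts on five offspring
mediators through linear structural equations, and the binary offspring
loneliness outcome Y follows a logistic model in A, the mediators M and
shared confounders C:

    M_j = beta0_j + beta1_j * A + beta2_j' C + Normal(0, sigma_j)
    P(Y=1) = expit(theta0 + theta1*A + theta2'M + theta3'(A*M) + theta4'C)

Because the coefficients are inputs, every downstream estimator
(association models, imputation, counterfactual decomposition) can be
checked against a planted truth.

Default coefficients and confounder marginals are fixed at study-like
values (cohort descriptives of roughly a thousand pairs, offspring
loneliness prevalence near 29%, mediator effects of the size reported
for such cohorts); see ``docs/methods.md`` for the full rationale.

Bounded instruments are mapped to their support after the structural
draw: the subjective-SES ladder is rounded and clipped to 1..10, the
anxiety item-mean clipped to [0, 3] and sociability to [1, 5]. The
unbounded composites (cognitive composite, depressive total) follow the
equations exactly and are the natural carriers for sharp
parameter-recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import schema

__all__ = ["MediatorCoefs", "OutcomeCoefs", "SimulationParams", "simulate_dyads",
           "true_log_effects", "write_table", "read_table"]


#: Documented marginal means of the confounders (used to anchor default
#: intercepts so planted effects stay on a realistic scale).
CONFOUNDER_MEANS = {
    "g0_age": 74.0,
    "g1_age": 47.0,
    "sex": 0.563,
    "marital": 0.766,
    "n_children": 3.0,
    "n_siblings": 2.3,
    "education_years": 16.0,
    "parental_education_years": 11.0,
    "income": 9.7,
}


@dataclass(frozen=True)
class MediatorCoefs:
    """Structural coefficients of one mediator's linear equation."""

    beta0: float
    beta1: float
    beta2: Mapping[str, float] = field(default_factory=dict)
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        unknown = set(self.beta2) - set(schema.CONFOUNDERS)
        if unknown:
            raise ValueError(f"beta2 refers to unknown confounders: {unknown}")


@dataclass(frozen=True)
class OutcomeCoefs:
    """Log-odds coefficients of the outcome logistic equation.

    ``theta0=None`` requests auto-calibration: the intercept is solved
    at generation time so the cohort's mean outcome probability equals
    ``target_prevalence``.
    """

    theta0: Optional[float] = None
    theta1: float = 0.0
    theta2: Mapping[str, float] = field(default_factory=dict)
    theta3: Mapping[str, float] = field(default_factory=dict)
    theta4: Mapping[str, float] = field(default_factory=dict)
    target_prevalence: float = 0.29

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        for name, keys in (("theta2", self.theta2), ("theta3", self.theta3)):
            unknown = set(keys) - set(schema.MEDIATORS)
            if unknown:
                raise ValueError(f"{name} refers to unknown mediators: {unknown}")
        unknown = set(self.theta4) - set(schema.CONFOUNDERS)
        if unknown:
            raise ValueError(f"theta4 refers to unknown confounders: {unknown}")


def _default_mediators() -> dict[str, MediatorCoefs]:
    # Exposure effects (beta1) sized like adjusted mediator-model
    # estimates in cohorts of this kind; residual SDs from typical
    # instrument dispersions; intercepts anchor the not-exposed mean.
    return {
        "subj_ses": MediatorCoefs(
            beta0=5.8, beta1=-0.33,
            beta2={"income": 0.08, "education_years": 0.04}, sigma=1.6,
        ),
        "sociability": MediatorCoefs(
            beta0=3.25, beta1=-0.08, beta2={"sex": 0.10}, sigma=0.70,
        ),
        "cognition": MediatorCoefs(
            beta0=0.6, beta1=0.05,
            beta2={"education_years": 0.05, "g1_age": -0.03}, sigma=2.3,
        ),
        "depressive": MediatorCoefs(
            beta0=6.0, beta1=1.76,
            beta2={"income": -0.15, "marital": -1.0}, sigma=5.5,
        ),
        "anxiety": MediatorCoefs(
            beta0=0.22, beta1=0.08, beta2={"sex": 0.08}, sigma=0.33,
        ),
    }


def _default_outcome() -> OutcomeCoefs:
    # Direct exposure effect ~log(1.5); per-unit mediator log-ORs sized
    # so the indirect paths are modest except the mental-health ones;
    # confounder log-ORs echo typical adjusted outcome models.
    return OutcomeCoefs(
        theta0=None,
        theta1=math.log(1.51),
        theta2={
            "subj_ses": -0.119,
            "sociability": -0.20,
            "cognition": 0.02,
            "depressive": 0.118,
            "anxiety": 0.80,
        },
        theta3={},
        theta4={
            "g0_age": -0.02,
            "g1_age": 0.0,
            "sex": 0.215,
            "marital": -0.89,
            "n_children": -0.03,
            "n_siblings": 0.049,
            "education_years": 0.0,
            "parental_education_years": 0.068,
            "income": -0.062,
        },
    )


def _default_missing_rate() -> dict[str, float]:
    # Per-column missingness echoing observed questionnaire gaps:
    # heaviest on the cognitive and depressive composites.
    return {
        "cognition": 0.094,
        "depressive": 0.065,
        "anxiety": 0.007,
        "sociability": 0.005,
        "subj_ses": 0.010,
        "income": 0.025,
        "education_years": 0.010,
        "n_children": 0.009,
        "n_siblings": 0.002,
        "parental_education_years": 0.004,
    }


@dataclass(frozen=True)
class SimulationParams:
    """Full specification of a synthetic dyad cohort.

    ``seed`` fully determines the output. ``missing_rate`` may be a
    single proportion applied to all missable columns or a per-column
    mapping. ``mother_available``/``father_available`` give the
    probability that each parent responded (every pair keeps at least
    one parent), which is what makes per-exposure sample sizes differ.
    """

    n_pairs: int = 991
    seed: int = 0
    mediator_coefs: Mapping[str, MediatorCoefs] = field(
        default_factory=_default_mediators
    )
    outcome_coefs: OutcomeCoefs = field(default_factory=_default_outcome)
    parent_lonely_prevalence: float = 0.25
    mother_available: float = 0.881
    father_available: float = 0.579
    missing_rate: float | Mapping[str, float] = field(
        default_factory=_default_missing_rate
    )
    missing_mechanism: str = "MAR"  # "MCAR" or "MAR"

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        if not 0 < self.parent_lonely_prevalence < 1:
            raise ValueError("parent_lonely_prevalence must be in (0, 1)")
        for name in ("mother_available", "father_available"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR'")
        missing = set(self.mediator_coefs) ^ set(schema.MEDIATORS)
        if missing:
            raise ValueError(f"mediator_coefs must cover exactly {schema.MEDIATORS}")
        rates = self._rates()
        for col, r in rates.items():
            if not 0 <= r < 1:
                raise ValueError(f"missing rate for {col} must be in [0, 1)")

    def _rates(self) -> dict[str, float]:
        missable = schema.MEDIATORS + [
            "income", "education_years", "marital", "n_children",
            "n_siblings", "parental_education_years",
        ]
        if isinstance(self.missing_rate, Mapping):
            unknown = set(self.missing_rate) - set(missable)
            if unknown:
                raise ValueError(f"missing_rate given for non-missable columns: {unknown}")
            return {c: float(self.missing_rate.get(c, 0.0)) for c in missable}
        return {c: float(self.missing_rate) for c in missable}

    def null(self) -> "SimulationParams":
        """Copy with all exposure->mediator and ->outcome paths removed."""
        meds = {
            k: replace(v, beta1=0.0) for k, v in self.mediator_coefs.items()
        }
        out = replace(
            self.outcome_coefs,
            theta1=0.0,
            theta2={m: 0.0 for m in schema.MEDIATORS},
            theta3={},
        )
        return replace(self, mediator_coefs=meds, outcome_coefs=out)

    def single_mediator(self, mediator: str) -> "SimulationParams":
        """Copy in which only ``mediator`` carries an indirect path."""
        if mediator not in schema.MEDIATORS:
            raise ValueError(f"unknown mediator {mediator!r}")
        theta2 = {
            m: (self.outcome_coefs.theta2.get(m, 0.0) if m == mediator else 0.0)
            for m in schema.MEDIATORS
        }
        return replace(
            self, outcome_coefs=replace(self.outcome_coefs, theta2=theta2)
        )


def true_log_effects(params: SimulationParams, mediator: str) -> dict[str, float]:
    """Planted log-scale NDE/NIE/TE for a single-mediator decomposition
    (no exposure-mediator interaction, exposure moving 0 -> 1).

    Only exact when the other mediators carry no outcome effect
    (``params.single_mediator``)."""
    oc = params.outcome_coefs
    if oc.theta3.get(mediator, 0.0) != 0.0:
        raise ValueError("closed-form truth assumes no interaction")
    beta1 = params.mediator_coefs[mediator].beta1
    theta2 = oc.theta2.get(mediator, 0.0)
    log_nde = oc.theta1
    log_nie = theta2 * beta1
    return {
        "log_nde": log_nde,
        "log_nie": log_nie,
        "log_te": log_nde + log_nie,
    }


def _truncated_normal(rng, mean, sd, lo, hi, n):
    x = rng.normal(mean, sd, size=n)
    # Redraw out-of-range values; bounds are several SDs out so this
    # converges immediately in practice.
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(x, lo, hi)


def _draw_confounders(rng, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "g0_age": np.round(_truncated_normal(rng, 74.0, 5.7, 60, 92, n), 1),
            "g1_age": np.round(_truncated_normal(rng, 47.0, 4.7, 34, 60, n), 1),
            "sex": (rng.random(n) < 0.563).astype(float),
            "marital": (rng.random(n) < 0.766).astype(float),
            "n_children": rng.poisson(3.0, size=n).astype(float),
            "n_siblings": rng.poisson(2.3, size=n).astype(float),
            "education_years": np.round(
                _truncated_normal(rng, 16.0, 3.7, 6, 28, n), 0
            ),
            "parental_education_years": np.round(
                _truncated_normal(rng, 11.0, 3.2, 4, 24, n), 0
            ),
            "income": np.clip(np.round(rng.normal(9.7, 4.9, size=n)), 1, 21),
        }
    )


def _draw_parent_sums(rng, n: int, prevalence: float) -> np.ndarray:
    """UCLA-3 totals (3-9) with P(total >= 6) = prevalence: lonely
    parents draw uniformly from 6..9, others from 3..5."""
    lonely = rng.random(n) < prevalence
    sums = np.where(
        lonely,
        rng.integers(6, 10, size=n),
        rng.integers(3, 6, size=n),
    )
    return sums.astype(float)


def backfill_items(total: float, n_items: int, item_min: int) -> list[float]:
    """Deterministically split a scale total into item responses.

    Each item gets the integer base; the remainder is spread one point
    at a time left to right, keeping every item within its range.
    """
    if math.isnan(total):
        return [float("nan")] * n_items
    s = int(round(total))
    base, rem = divmod(s, n_items)
    items = [base + 1 if i < rem else base for i in range(n_items)]
    if min(items) < item_min:
        raise ValueError(f"total {total} too small for {n_items} items >= {item_min}")
    return [float(v) for v in items]


def _items_frame(sums: np.ndarray, cols: list[str]) -> pd.DataFrame:
    k = len(cols)
    out = np.full((len(sums), k), np.nan)
    for i, s in enumerate(sums):
        if not math.isnan(s):
            out[i] = backfill_items(s, k, 1)
    return pd.DataFrame(out, columns=cols)


def _apply_missingness(
    rng, table: pd.DataFrame, rates: Mapping[str, float], mechanism: str
) -> pd.DataFrame:
    out = table.copy()
    if mechanism == "MAR":
        # Missingness driven by always-observed covariates (offspring
        # age and sex) through a logistic link; intercept solved so the
        # marginal rate matches the target.
        z = (out["g1_age"].to_numpy() - 47.0) / 4.7 + (
            out["sex"].to_numpy() - 0.563
        )
        slope = 0.7
    for col, rate in rates.items():
        if rate <= 0:
            continue
        if mechanism == "MCAR":
            mask = rng.random(len(out)) < rate
        else:
            a = brentq(
                lambda a_, r=rate: float(np.mean(expit(a_ + slope * z))) - r,
                -30.0,
                30.0,
            )
            mask = rng.random(len(out)) < expit(a + slope * z)
        out.loc[mask, col] = np.nan
    return out


def simulate_dyads(params: SimulationParams) -> pd.DataFrame:
    """Generate a dyad table from the structural model.

    Returns a raw table (items + mediators + confounders, no derived
    loneliness columns); pass it through
    :func:`dyadlink.scales.score_dyad_table` for the analysis columns.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_pairs
    conf = _draw_confounders(rng, n)

    mother_avail = rng.random(n) < params.mother_available
    father_avail = rng.random(n) < params.father_available
    neither = ~mother_avail & ~father_avail
    mother_avail[neither] = True  # every pair links to at least one parent

    mother_sums = _draw_parent_sums(rng, n, params.parent_lonely_prevalence)
    father_sums = _draw_parent_sums(rng, n, params.parent_lonely_prevalence)
    mother_sums[~mother_avail] = np.nan
    father_sums[~father_avail] = np.nan

    # Exposure: mean of available parents' totals, dichotomized at 6.
    parent_mean = np.nanmean(
        np.column_stack([mother_sums, father_sums]), axis=1
    )
    a = (parent_mean >= 6).astype(float)

    c_mat = conf[schema.CONFOUNDERS].to_numpy()
    mediators = {}
    for name in schema.MEDIATORS:
        mc = params.mediator_coefs[name]
        b2 = np.array([mc.beta2.get(k, 0.0) for k in schema.CONFOUNDERS])
        m = mc.beta0 + mc.beta1 * a + c_mat @ b2 + rng.normal(0, mc.sigma, n)
        if name == "subj_ses":
            m = np.clip(np.round(m), 1, 10)
        elif name == "anxiety":
            m = np.clip(m, 0.0, 3.0)
        elif name == "sociability":
            m = np.clip(m, 1.0, 5.0)
        mediators[name] = m
    med = pd.DataFrame(mediators)

    oc = params.outcome_coefs
    t2 = np.array([oc.theta2.get(k, 0.0) for k in schema.MEDIATORS])
    t3 = np.array([oc.theta3.get(k, 0.0) for k in schema.MEDIATORS])
    t4 = np.array([oc.theta4.get(k, 0.0) for k in schema.CONFOUNDERS])
    m_mat = med[schema.MEDIATORS].to_numpy()
    lp_rest = oc.theta1 * a + m_mat @ t2 + (a[:, None] * m_mat) @ t3 + c_mat @ t4
    if oc.theta0 is None:
        # solve the intercept so the cohort's mean outcome probability
        # equals the target prevalence exactly
        if not np.all(np.isfinite(lp_rest)):
            bad = int(np.flatnonzero(~np.isfinite(lp_rest))[0])
            raise FloatingPointError(
                f"non-finite outcome linear predictor at row {bad}; "
                "check coefficient magnitudes"
            )
        theta0 = float(
            brentq(
                lambda t: float(np.mean(expit(t + lp_rest)))
                - oc.target_prevalence,
                -60.0,
                60.0,
            )
        )
    else:
        theta0 = float(oc.theta0)
    lp = theta0 + lp_rest
    if not np.all(np.isfinite(lp)):
        bad = int(np.flatnonzero(~np.isfinite(lp))[0])
        raise FloatingPointError(
            f"non-finite outcome linear predictor at row {bad}; "
            "check coefficient magnitudes"
        )
    y = (rng.random(n) < expit(lp)).astype(float)

    # Offspring UCLA-3 totals consistent with the drawn class.
    off_sums = np.where(
        y == 1, rng.integers(6, 10, size=n), rng.integers(3, 6, size=n)
    ).astype(float)

    table = pd.concat(
        [
            pd.DataFrame({"pair_id": np.arange(1, n + 1)}),
            _items_frame(mother_sums, schema.MOTHER_ITEMS),
            _items_frame(father_sums, schema.FATHER_ITEMS),
            _items_frame(off_sums, schema.OFFSPRING_ITEMS),
            med,
            conf,
        ],
        axis=1,
    )
    table = _apply_missingness(rng, table, params._rates(), params.missing_mechanism)
    return table


def write_table(table: pd.DataFrame, path) -> None:
    """Write a dyad table as comma-separated text (empty field = missing).

    Floats are written with their shortest round-trippable
    representation so a write/read cycle reproduces the table exactly.
    """
    table.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_table(path) -> pd.DataFrame:
    """Read a dyad table written by :func:`write_table` (exact float
    round-trip)."""
    return pd.read_csv(path, float_precision="round_trip")
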