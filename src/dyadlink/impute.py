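"""Multiple imputation by chained equations and Rubin's-rules pooling.

The chained-equation sampler is implemented here directly. For each
incomplete column a conditional model is fitted on the currently
completed predictors over the rows where the column is observed, the
model parameters are perturbed by a proper Bayesian draw, and the
missing cells are replaced:

* continuous columns — Bayesian linear regression, with either
  predictive mean matching (PMM, default: the drawn prediction is
  matched to the k nearest observed predictions and one donor's real
  value is copied) or a parametric normal draw;
* binary 0/1 columns — logistic regression with a multivariate-normal
  coefficient draw and a Bernoulli draw of the missing cells.

Columns are visited in order of ascending missingness and the whole
sweep is repeated for a fixed number of burn-in cycles. Each of the m
datasets runs its own independently seeded chain. The outcome variable
is never imputed and exposure (loneliness) variables can be excluded
from the predictor set, matching the analysis protocol.

Pooling follows Rubin's rules: pooled estimate = mean of per-dataset
estimates; total variance T = W + (1 + 1/m) B where W is the mean
within-imputation variance and B the between-imputation variance; the
classical degrees of freedom (m-1)(1 + W/((1+1/m)B))^2 apply.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import GLMFit

__all__ = ["ImputedStack", "PooledFit", "mice_impute", "rubin_pool", "pool_scalar"]

_DF_CAP = 1e12


@dataclass
class ImputedStack:
    """m completed copies of one incomplete table."""

    datasets: list[pd.DataFrame]
    cycle_count: int
    predictor_set: list[str]
    imputed_columns: list[str]
    seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)

    def save(self, directory) -> None:
        """Serialize as m CSV files plus a JSON manifest."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, ds in enumerate(self.datasets, start=1):
            ds.to_csv(
                d / f"imputed_{i}.csv", index=False,
                float_format=lambda x: repr(float(x)),
            )
        manifest = {
            "m": self.m,
            "cycles": self.cycle_count,
            "seed": self.seed,
            "predictor_set": self.predictor_set,
            "imputed_columns": self.imputed_columns,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ImputedStack":
        from pathlib import Path

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        datasets = [
            pd.read_csv(d / f"imputed_{i}.csv", float_precision="round_trip")
            for i in range(1, manifest["m"] + 1)
        ]
        return cls(
            datasets=datasets,
            cycle_count=manifest["cycles"],
            predictor_set=manifest["predictor_set"],
            imputed_columns=manifest["imputed_columns"],
            seed=manifest["seed"],
        )


@dataclass
class PooledFit:
    """Rubin-combined coefficients over m imputations."""

    names: list[str]
    q_bar: np.ndarray
    W: np.ndarray
    B: np.ndarray
    T: np.ndarray
    df: np.ndarray
    m: int
    pooled: bool = True

    def se(self) -> np.ndarray:
        return np.sqrt(self.T)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        from scipy import stats

        q = stats.t.ppf(0.5 + level / 2, np.minimum(self.df, _DF_CAP))
        se = self.se()
        return np.column_stack([self.q_bar - q * se, self.q_bar + q * se])

    def pvalues(self) -> np.ndarray:
        from scipy import stats

        se = self.se()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, self.q_bar / se, np.inf * np.sign(self.q_bar))
        return 2 * stats.t.sf(np.abs(t), np.minimum(self.df, _DF_CAP))

    def as_series(self) -> pd.Series:
        return pd.Series(self.q_bar, index=self.names)


def pool_scalar(
    estimates: Sequence[float], variances: Sequence[float]
) -> tuple[float, float, float, float, float]:
    """Rubin's rules for one scalar: (q_bar, W, B, T, df)."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        return float(q[0]), float(u[0]), 0.0, float(u[0]), _DF_CAP
    q_bar = q.mean()
    w = u.mean()
    b = q.var(ddof=1)
    t = w + (1 + 1 / m) * b
    if b > 0:
        df = (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2
    else:
        df = _DF_CAP
    return float(q_bar), float(w), float(b), float(t), float(min(df, _DF_CAP))


def rubin_pool(fits: Sequence[GLMFit]) -> PooledFit:
    """Pool a list of per-imputation model fits.

    With a single fit, pooling is refused: the fit's own estimates and
    variances are returned with ``pooled=False``.
    """
    if len(fits) == 0:
        raise ValueError("no fits to pool")
    names = list(fits[0].coef.index)
    for f in fits[1:]:
        if list(f.coef.index) != names:
            raise ValueError("fits do not share coefficient names")
        if f.n != fits[0].n:
            raise ValueError("fits were computed on different sample sizes")
    est = np.array([f.coef.to_numpy() for f in fits])
    var = np.array([np.diag(f.vcov.to_numpy()) for f in fits])
    m = len(fits)
    if m < 2:
        return PooledFit(
            names=names,
            q_bar=est[0],
            W=var[0],
            B=np.zeros_like(var[0]),
            T=var[0],
            df=np.full(len(names), _DF_CAP),
            m=1,
            pooled=False,
        )
    q_bar = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    t = w + (1 + 1 / m) * b
    with np.errstate(divide="ignore"):
        df = np.where(
            b > 0, (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2, _DF_CAP
        )
    return PooledFit(
        names=names,
        q_bar=q_bar,
        W=w,
        B=b,
        T=t,
        df=np.minimum(df, _DF_CAP),
        m=m,
    )


def _drop_collinear(x: np.ndarray, names: list[str]) -> list[int]:
    """Indices of a maximal linearly independent column subset (greedy);
    warns when columns are dropped."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(x.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(x[:, cand]) == len(cand):
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(
            f"dropping collinear imputation predictors: {dropped}",
            stacklevel=3,
        )
    return keep


def _bayes_linear_draw(rng, x_obs, y_obs, x_mis, method: str) -> np.ndarray:
    n, p = x_obs.shape
    xtx = x_obs.T @ x_obs
    xtx_inv = np.linalg.pinv(xtx)
    beta_hat = xtx_inv @ (x_obs.T @ y_obs)
    resid = y_obs - x_obs @ beta_hat
    df = max(n - p, 1)
    sse = float(resid @ resid)
    sigma2_star = sse / rng.chisquare(df) if sse > 0 else 0.0
    cov = sigma2_star * xtx_inv
    # symmetrise before factorisation; pinv can leave tiny asymmetries
    cov = (cov + cov.T) / 2
    try:
        l_chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
        beta_star = beta_hat + l_chol @ rng.standard_normal(p)
    except np.linalg.LinAlgError:
        beta_star = beta_hat
    if method == "norm":
        return x_mis @ beta_star + rng.normal(0, np.sqrt(sigma2_star), len(x_mis))
    # PMM: match drawn predictions for missing rows against observed
    # predictions under beta_hat; copy a random donor among k nearest.
    pred_obs = x_obs @ beta_hat
    pred_mis = x_mis @ beta_star
    k = min(5, n)
    out = np.empty(len(x_mis))
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    for i, pm in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, pm)
        lo = max(0, pos - k)
        hi = min(n, pos + k)
        cand = order[lo:hi]
        d = np.abs(pred_obs[cand] - pm)
        donors = cand[np.argsort(d)[:k]]
        out[i] = y_obs[donors[rng.integers(len(donors))]]
    return out


def _logistic_draw(rng, x_obs, y_obs, x_mis) -> np.ndarray:
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y_obs, x_obs).fit(disp=0, maxiter=100)
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))):
            raise np.linalg.LinAlgError
        cov = (cov + cov.T) / 2
        l_chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(beta)))
        beta_star = beta + l_chol @ rng.standard_normal(len(beta))
        p = expit(x_mis @ beta_star)
    except Exception:
        # degenerate conditional model: fall back to the observed margin
        p = np.full(len(x_mis), float(np.mean(y_obs)))
    return (rng.random(len(x_mis)) < p).astype(float)


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return len(u) <= 2 and np.isin(u, [0.0, 1.0]).all()


def mice_impute(
    table: pd.DataFrame,
    m: int = 5,
    cycles: int = 10,
    seed: int = 0,
    exclude: Sequence[str] = (),
    outcome: Optional[str] = None,
    columns: Optional[Sequence[str]] = None,
    method: str = "pmm",
) -> ImputedStack:
    """Impute an incomplete table m times by chained equations.

    Parameters
    ----------
    table : incomplete dyad table (numeric columns).
    m : number of completed datasets (default 5).
    cycles : burn-in sweeps per dataset (default 10).
    seed : base seed; dataset d uses the stream (seed, d).
    exclude : columns neither imputed nor used as predictors (e.g. the
        loneliness exposure variables and identifiers).
    outcome : column never imputed (rows keep their missing outcome) but
        still excluded from predictors.
    columns : restrict imputation to these columns (default: every
        non-excluded column with missing values).
    method : ``"pmm"`` (default) or ``"norm"`` for continuous columns.

    Originally observed cells are identical across the m datasets.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if method not in ("pmm", "norm"):
        raise ValueError("method must be 'pmm' or 'norm'")
    excluded = set(exclude)
    if outcome is not None:
        excluded.add(outcome)
    numeric = [
        c
        for c in table.columns
        if c not in excluded and pd.api.types.is_numeric_dtype(table[c])
    ]
    if columns is None:
        target = [c for c in numeric if table[c].isna().any()]
    else:
        bad = set(columns) & excluded
        if bad:
            raise ValueError(f"cannot impute excluded columns: {bad}")
        target = [c for c in columns if table[c].isna().any()]
    for c in target:
        if table[c].notna().sum() == 0:
            raise ValueError(f"column {c!r} has no observed values")
    predictors = [c for c in numeric if c not in target]
    complete_predictors = [c for c in predictors if table[c].notna().all()]
    if not complete_predictors:
        raise ValueError("need at least one fully observed predictor column")
    # visit order: ascending missingness
    target = sorted(target, key=lambda c: table[c].isna().sum())
    predictor_set = complete_predictors + [c for c in target]

    datasets = []
    for d in range(m):
        rng = np.random.default_rng([int(seed) % (2**31), d])
        work = table.copy()
        # initial fill: random draws from each column's observed values
        for c in target:
            obs = work[c].dropna().to_numpy()
            miss = work[c].isna()
            work.loc[miss, c] = rng.choice(obs, size=int(miss.sum()))
        if not target:
            datasets.append(work)
            continue
        miss_masks = {c: table[c].isna().to_numpy() for c in target}
        for _ in range(cycles):
            for c in target:
                mask = miss_masks[c]
                if not mask.any():
                    continue
                pred_cols = [p for p in complete_predictors if p != c] + [
                    t for t in target if t != c
                ]
                x_all = np.column_stack(
                    [np.ones(len(work))]
                    + [work[p].to_numpy(dtype=float) for p in pred_cols]
                )
                names = ["const"] + pred_cols
                keep = _drop_collinear(x_all[~mask], names)
                x_all = x_all[:, keep]
                y_obs = table[c].to_numpy(dtype=float)[~mask]
                x_obs, x_mis = x_all[~mask], x_all[mask]
                if _is_binary(table[c].to_numpy(dtype=float)):
                    draws = _logistic_draw(rng, x_obs, y_obs, x_mis)
                else:
                    draws = _bayes_linear_draw(rng, x_obs, y_obs, x_mis, method)
                col = work[c].to_numpy(dtype=float)
                col[mask] = draws
                work[c] = col
        datasets.append(work)
    return ImputedStack(
        datasets=datasets,
        cycle_count=cycles,
        predictor_set=predictor_set,
        imputed_columns=list(target),
        seed=int(seed),
    )
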