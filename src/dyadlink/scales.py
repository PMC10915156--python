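"""Questionnaire scale scoring and dichotomization.

Instruments used in the dyad analysis:

* UCLA-3 loneliness: three items scored 1-3, summed to a 3-9 total;
  a total of at least 6 classifies the respondent as lonely (the 5/6
  cut-off). Parental loneliness is the mean of the two parents' totals,
  classified with the same cut-off; when only one parent responded, that
  parent's total stands in for the mean.
* BDI depressive symptoms: 21 items, summed.
* GAD-7 anxiety: 7 items scored 0-3, aggregated as the item mean so the
  score stays on the 0-3 response scale.
* EAS sociability temperament: 5 items, item mean on the 1-5 scale.

A scale with any missing item yields a missing score — no prorating;
missing data are handled downstream at the variable level by multiple
imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import schema

__all__ = [
    "ScaleSpec",
    "ScaleScore",
    "UCLA3",
    "BDI",
    "GAD7",
    "EAS_SOCIABILITY",
    "score_scale",
    "parental_mean_class",
    "cronbach_alpha",
    "score_dyad_table",
]


@dataclass(frozen=True)
class ScaleSpec:
    """Definition of a fixed-length questionnaire scale.

    Parameters
    ----------
    n_items : number of items.
    item_range : inclusive (low, high) bounds of a single response.
    aggregation : ``"sum"`` or ``"mean"``.
    cutoff : optional threshold; scores >= cutoff form the positive class.
    """

    n_items: int
    item_range: tuple[float, float]
    aggregation: str = "sum"
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        lo, hi = self.item_range
        if not lo < hi:
            raise ValueError("item_range must be increasing")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.cutoff is not None:
            rmin, rmax = self.score_range
            if not rmin <= self.cutoff <= rmax:
                raise ValueError(
                    f"cutoff {self.cutoff} outside attainable range "
                    f"[{rmin}, {rmax}]"
                )

    @property
    def score_range(self) -> tuple[float, float]:
        """Attainable (min, max) of the aggregated score."""
        lo, hi = self.item_range
        if self.aggregation == "sum":
            return (self.n_items * lo, self.n_items * hi)
        return (float(lo), float(hi))


@dataclass(frozen=True)
class ScaleScore:
    """Scored scale: raw value, binary class (if a cutoff applies) and
    the number of missing items. ``raw``/``lonely_class`` are NaN when
    any item is missing."""

    raw: float
    lonely_class: float
    n_missing_items: int


#: Three-item UCLA loneliness scale; total >= 6 (of 9) means lonely.
UCLA3 = ScaleSpec(n_items=3, item_range=(1, 3), aggregation="sum", cutoff=6.0)
#: 21-item Beck Depression Inventory, items coded 0-3, summed.
BDI = ScaleSpec(n_items=21, item_range=(0, 3), aggregation="sum")
#: GAD-7 anxiety, items 0-3, reported as the item mean.
GAD7 = ScaleSpec(n_items=7, item_range=(0, 3), aggregation="mean")
#: EAS sociability, five items on a 1-5 scale, item mean.
EAS_SOCIABILITY = ScaleSpec(n_items=5, item_range=(1, 5), aggregation="mean")


def score_scale(items: Sequence[float], spec: ScaleSpec) -> ScaleScore:
    """Aggregate one respondent's item vector into a :class:`ScaleScore`.

    Any missing item (None/NaN) makes the raw score and class missing.
    Out-of-range responses are rejected with the offending item index.
    """
    if len(items) != spec.n_items:
        raise ValueError(
            f"expected {spec.n_items} items, got {len(items)}"
        )
    lo, hi = spec.item_range
    vals = []
    n_missing = 0
    for i, x in enumerate(items):
        if x is None or (isinstance(x, float) and math.isnan(x)):
            n_missing += 1
            continue
        if not lo <= x <= hi:
            raise ValueError(
                f"item {i} response {x} outside range [{lo}, {hi}]"
            )
        vals.append(float(x))
    if n_missing > 0:
        return ScaleScore(float("nan"), float("nan"), n_missing)
    raw = sum(vals) if spec.aggregation == "sum" else sum(vals) / len(vals)
    cls = float("nan")
    if spec.cutoff is not None:
        cls = float(raw >= spec.cutoff)
    return ScaleScore(raw, cls, 0)


def parental_mean_class(
    mother_raw: float, father_raw: float, spec: ScaleSpec
) -> ScaleScore:
    """Combine the two parents' raw totals into the parental exposure.

    The mean of the available parent scores is classified with the same
    cut-off as the individual scale; with a single responding parent the
    mean reduces to that parent's score. Both missing yields a missing
    score.
    """
    vals = [v for v in (mother_raw, father_raw) if v is not None and not math.isnan(v)]
    n_missing = 2 - len(vals)
    if not vals:
        return ScaleScore(float("nan"), float("nan"), n_missing)
    raw = sum(vals) / len(vals)
    cls = float("nan")
    if spec.cutoff is not None:
        cls = float(raw >= spec.cutoff)
    return ScaleScore(raw, cls, n_missing)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums),
    with sample (ddof=1) variances over complete rows only.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("item_matrix must be 2-dimensional")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 2:
        raise ValueError("need at least 2 complete rows")
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var <= 0:
        raise ValueError("total score variance is zero; alpha undefined")
    item_vars = np.var(x, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def _score_items_frame(
    table: pd.DataFrame, cols: list[str], spec: ScaleSpec
) -> tuple[pd.Series, pd.Series]:
    """Vectorised score_scale over item columns: (raw, class) series."""
    items = table[cols].astype(float)
    lo, hi = spec.item_range
    bad = (items < lo) | (items > hi)
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ValueError(
            f"out-of-range response in column {col!r}, row {row}: "
            f"{items.loc[row, col]}"
        )
    complete = items.notna().all(axis=1)
    raw = items.sum(axis=1) if spec.aggregation == "sum" else items.mean(axis=1)
    raw = raw.where(complete)
    cls = pd.Series(np.nan, index=table.index)
    if spec.cutoff is not None:
        cls = (raw >= spec.cutoff).astype(float).where(raw.notna())
    return raw, cls


def score_dyad_table(table: pd.DataFrame, spec: ScaleSpec = UCLA3) -> pd.DataFrame:
    """Append the derived loneliness columns to a dyad table.

    Adds per-respondent raw totals and lonely classes for mother, father
    and offspring, plus the mean-parental exposure
    (``g0_parent_lonely_raw`` / ``g0_parent_lonely_class``).
    """
    out = table.copy()
    for who, cols, prefix in (
        ("mother", schema.MOTHER_ITEMS, "g0_mother"),
        ("father", schema.FATHER_ITEMS, "g0_father"),
        ("offspring", schema.OFFSPRING_ITEMS, "g1"),
    ):
        raw, cls = _score_items_frame(out, cols, spec)
        out[f"{prefix}_lonely_raw"] = raw
        out[f"{prefix}_lonely_class"] = cls
    mother = out["g0_mother_lonely_raw"]
    father = out["g0_father_lonely_raw"]
    parent_raw = pd.concat([mother, father], axis=1).mean(axis=1)
    out["g0_parent_lonely_raw"] = parent_raw
    out["g0_parent_lonely_class"] = (
        (parent_raw >= spec.cutoff).astype(float).where(parent_raw.notna())
        if spec.cutoff is not None
        else np.nan
    )
    return out
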