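"""End-to-end analysis pipeline.

Orchestrates: load-or-simulate -> scale scoring -> (optional) multiple
imputation -> group descriptives, mediator models, adjusted outcome
odds ratios with Tjur R2, interaction screens, counterfactual
decompositions with proportions mediated, and E-value sensitivity rows
— per exposure variant (mean-parental, mother, father).

All randomness flows from the single seed in the configuration; running
the same configuration twice yields byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import schema
from .evalue import evalue_for_or
from .impute import mice_impute, rubin_pool
from .mediation import MediationSpec, mediate_pooled
from .models import (
    describe_by_group,
    fit_linear,
    fit_logistic,
    tjur_r2,
)
from .scales import ScaleSpec, UCLA3, score_dyad_table
from .synthetic_data import SimulationParams, read_table, simulate_dyads

__all__ = ["AnalysisConfig", "run_all", "load_config"]

log = logging.getLogger("dyadlink")

VERSION = "0.1.0"


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pipeline run.

    Either ``input_path`` (a dyad CSV) or ``sim_params`` (synthetic
    generation) supplies the data; with neither, default synthetic
    parameters at ``seed`` are used.
    """

    input_path: Optional[str] = None
    sim_params: Optional[SimulationParams] = None
    seed: int = 0
    cutoff: float = 6.0
    m: int = 5
    cycles: int = 10
    exposures: tuple[str, ...] = ("parental", "mother", "father")
    continuous_loneliness: bool = False
    complete_case: bool = False
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        bad = [e for e in self.exposures if e not in schema.EXPOSURE_CLASS]
        if bad:
            raise ValueError(f"unknown exposure variant(s): {bad}")
        if self.m < 1 or self.cycles < 1:
            raise ValueError("m and cycles must be positive")


def load_config(path) -> AnalysisConfig:
    """Read a flat key-value (YAML mapping) config file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key: value mapping")
    known = {
        "input_path", "seed", "cutoff", "m", "cycles", "exposures",
        "continuous_loneliness", "complete_case", "outdir", "n_pairs",
        "parent_lonely_prevalence", "missing_rate", "missing_mechanism",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_keys = {
        k: raw.pop(k)
        for k in (
            "n_pairs", "parent_lonely_prevalence", "missing_rate",
            "missing_mechanism",
        )
        if k in raw
    }
    if "exposures" in raw:
        val = raw["exposures"]
        raw["exposures"] = tuple(
            v.strip() for v in (val.split(",") if isinstance(val, str) else val)
        )
    sim = None
    if sim_keys and not raw.get("input_path"):
        sim = SimulationParams(seed=int(raw.get("seed", 0)), **sim_keys)
    return AnalysisConfig(sim_params=sim, **raw)


def _config_hash(config: AnalysisConfig) -> str:
    # hash the analysis-relevant fields only (not where output lands)
    payload = asdict(config)
    payload.pop("outdir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def prepare_table(config: AnalysisConfig) -> pd.DataFrame:
    """Load or simulate the raw dyad table and append derived scores."""
    if config.input_path is not None:
        table = read_table(config.input_path)
        log.info("loaded %d pairs from %s", len(table), config.input_path)
    else:
        params = config.sim_params or SimulationParams(seed=config.seed)
        table = simulate_dyads(params)
        log.info("simulated %d pairs (seed=%d)", len(table), params.seed)
    spec = ScaleSpec(
        n_items=UCLA3.n_items,
        item_range=UCLA3.item_range,
        aggregation=UCLA3.aggregation,
        cutoff=config.cutoff,
    )
    return score_dyad_table(table, spec)


def _exposure_column(config: AnalysisConfig, variant: str) -> str:
    if config.continuous_loneliness:
        return schema.EXPOSURE_RAW[variant]
    return schema.EXPOSURE_CLASS[variant]


def _analysis_subset(
    scored: pd.DataFrame, exposure_col: str
) -> pd.DataFrame:
    """Rows with observed exposure and outcome, analysis columns only."""
    cols = [exposure_col, schema.OUTCOME] + schema.MEDIATORS + schema.CONFOUNDERS
    sub = scored.loc[
        scored[exposure_col].notna() & scored[schema.OUTCOME].notna(), cols
    ].reset_index(drop=True)
    return sub


def _datasets_for(
    config: AnalysisConfig, sub: pd.DataFrame, exposure_col: str
) -> list[pd.DataFrame]:
    """Completed datasets: m imputations, or the complete cases."""
    if config.complete_case:
        out = sub.dropna().reset_index(drop=True)
        log.info(
            "complete-case analysis: %d of %d rows retained", len(out), len(sub)
        )
        return [out]
    if not sub.isna().any().any():
        return [sub.copy() for _ in range(config.m)]
    stack = mice_impute(
        sub,
        m=config.m,
        cycles=config.cycles,
        seed=config.seed,
        exclude=[exposure_col],
        outcome=schema.OUTCOME,
    )
    log.info(
        "imputed %d columns, m=%d, cycles=%d",
        len(stack.imputed_columns),
        stack.m,
        stack.cycle_count,
    )
    return stack.datasets


def _pooled_association(
    datasets: Sequence[pd.DataFrame],
    fit_fn,
    response: str,
    terms: Sequence[str],
    logistic: bool,
) -> pd.DataFrame:
    fits = [fit_fn(ds, response, terms) for ds in datasets]
    pooled = rubin_pool(fits)
    ci = pooled.conf_int()
    est, lo, hi = pooled.q_bar, ci[:, 0], ci[:, 1]
    if logistic:
        est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
    return pd.DataFrame(
        {
            "term": pooled.names,
            "estimate": est,
            "ci_lower": lo,
            "ci_upper": hi,
            "p_value": pooled.pvalues(),
        }
    )


def _interaction_screens(
    datasets: Sequence[pd.DataFrame], exposure_col: str
) -> pd.DataFrame:
    """Pooled Wald p-values for exposure x mediator and exposure x sex
    product terms in the outcome model."""
    rows = []
    covs = schema.MEDIATION_COVARIATES
    for med in schema.MEDIATORS:
        term = f"{exposure_col}:{med}"
        fits = []
        for ds in datasets:
            d = ds.copy()
            d[term] = d[exposure_col] * d[med]
            fits.append(
                fit_logistic(
                    d, schema.OUTCOME, [exposure_col, med, term] + covs
                )
            )
        pooled = rubin_pool(fits)
        i = pooled.names.index(term)
        rows.append(
            {
                "interaction": term,
                "estimate": pooled.q_bar[i],
                "p_value": float(pooled.pvalues()[i]),
            }
        )
    term = f"{exposure_col}:sex"
    fits = []
    covs_nosex = [c for c in schema.OUTCOME_MODEL_COVARIATES if c != "sex"]
    for ds in datasets:
        d = ds.copy()
        d[term] = d[exposure_col] * d["sex"]
        fits.append(
            fit_logistic(
                d, schema.OUTCOME, [exposure_col, "sex", term] + covs_nosex
            )
        )
    pooled = rubin_pool(fits)
    i = pooled.names.index(term)
    rows.append(
        {
            "interaction": term,
            "estimate": pooled.q_bar[i],
            "p_value": float(pooled.pvalues()[i]),
        }
    )
    return pd.DataFrame(rows)


def run_variant(
    config: AnalysisConfig, scored: pd.DataFrame, variant: str
) -> dict:
    """All analysis outputs for one exposure variant."""
    exposure_col = _exposure_column(config, variant)
    sub = _analysis_subset(scored, exposure_col)
    log.info("variant=%s exposure=%s n=%d", variant, exposure_col, len(sub))
    datasets = _datasets_for(config, sub, exposure_col)

    mediator_rows = []
    for med in schema.MEDIATORS:
        tab = _pooled_association(
            datasets,
            fit_linear,
            med,
            [exposure_col] + schema.MEDIATOR_MODEL_COVARIATES,
            logistic=False,
        )
        row = tab.loc[tab["term"] == exposure_col].iloc[0].to_dict()
        row["mediator"] = med
        mediator_rows.append(row)
    mediator_models = pd.DataFrame(mediator_rows)[
        ["mediator", "estimate", "ci_lower", "ci_upper", "p_value"]
    ]

    outcome_terms = [exposure_col] + schema.OUTCOME_MODEL_COVARIATES
    outcome_model = _pooled_association(
        datasets, fit_logistic, schema.OUTCOME, outcome_terms, logistic=True
    )
    tjur = float(
        np.mean(
            [
                tjur_r2(fit_logistic(ds, schema.OUTCOME, outcome_terms))
                for ds in datasets
            ]
        )
    )

    interactions = _interaction_screens(datasets, exposure_col)

    decomposition_rows = []
    evalue_rows = []
    for med in schema.MEDIATORS:
        spec = MediationSpec(
            exposure=exposure_col,
            mediator=med,
            outcome=schema.OUTCOME,
            covariates=tuple(schema.MEDIATION_COVARIATES),
        )
        dec = mediate_pooled(datasets, spec)
        decomposition_rows.append(dec.as_frame())
        for eff_name, eff in (("direct", dec.nde), ("indirect", dec.nie)):
            ev = evalue_for_or(
                eff.odds_ratio,
                (eff.ci_lower, eff.ci_upper),
                outcome_common=True,
            )
            evalue_rows.append(
                {
                    "mediator": med,
                    "effect": eff_name,
                    "odds_ratio": eff.odds_ratio,
                    "rr_used": ev.rr_used,
                    "e_value": ev.e_point,
                    "e_value_ci": ev.e_ci,
                    "conversion": ev.conversion,
                }
            )
    decomposition = pd.concat(decomposition_rows, ignore_index=True)
    evalues = pd.DataFrame(evalue_rows)

    return {
        "n": len(sub),
        "exposure_column": exposure_col,
        "mediator_models": mediator_models,
        "outcome_model": outcome_model,
        "tjur_r2": tjur,
        "interactions": interactions,
        "decomposition": decomposition,
        "evalues": evalues,
    }


def run_all(config: AnalysisConfig) -> dict:
    """Run every stage and (optionally) write the report bundle.

    Returns a dict with the scored table, the descriptives table, one
    result block per exposure variant, and the run manifest.
    """
    scored = prepare_table(config)
    observed_outcome = scored[scored[schema.OUTCOME].notna()]
    descriptives = describe_by_group(
        observed_outcome,
        schema.OUTCOME,
        continuous=schema.DESCRIPTIVE_CONTINUOUS,
        categorical=schema.DESCRIPTIVE_CATEGORICAL,
    )
    results = {"descriptives": descriptives, "table": scored, "variants": {}}
    for variant in config.exposures:
        results["variants"][variant] = run_variant(config, scored, variant)
    results["manifest"] = {
        "package": "dyadlink",
        "version": VERSION,
        "seed": config.seed,
        "m": config.m,
        "cycles": config.cycles,
        "cutoff": config.cutoff,
        "continuous_loneliness": config.continuous_loneliness,
        "complete_case": config.complete_case,
        "exposures": list(config.exposures),
        "config_hash": _config_hash(config),
        "n_pairs": int(len(scored)),
    }
    if config.outdir is not None:
        write_bundle(results, config.outdir)
    return results


def write_bundle(results: dict, outdir) -> None:
    """Serialize a run's outputs: CSV tables + JSON manifest."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    results["descriptives"].to_csv(d / "descriptives.csv", index=False)
    results["table"].to_csv(d / "scored_table.csv", index=False)
    for variant, block in results["variants"].items():
        vd = d / variant
        vd.mkdir(exist_ok=True)
        for name in (
            "mediator_models", "outcome_model", "interactions",
            "decomposition", "evalues",
        ):
            block[name].to_csv(vd / f"{name}.csv", index=False)
        (vd / "summary.json").write_text(
            json.dumps(
                {
                    "n": block["n"],
                    "exposure_column": block["exposure_column"],
                    "tjur_r2": block["tjur_r2"],
                },
                indent=2,
            )
        )
    (d / "manifest.json").write_text(json.dumps(results["manifest"], indent=2))
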