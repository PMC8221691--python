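"""End-to-end wiring: cohort -> costs -> imputation -> adjusted comparisons.

The stages are deliberately thin compositions of the module-level operations
so each remains testable in isolation; this module only fixes their order:

1. classify organizations into care models and attach the label to clients;
2. value resource utilization into per-wave quarterly category costs;
3. impute missing quarterly cost cells (chained-equation PMM, m datasets),
   excluding cells whose value is fixed by the halfway-transition rule;
4. per completed dataset, apply transition rules and the 0.5/1.5
   interpolation to obtain 6-month costs;
5. compare care models on adjusted 6-month costs (OLS + BCa bootstrap,
   pooled by Rubin's rules).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .care_models import classify_organizations
from .costing import (
    aggregate,
    complete_six_month,
    rule_mask,
    wave_cost_columns,
    wave_cost_table,
)
from .data_io import (
    CASE_MIX_COVARIATES,
    ClientWaveRecord,
    PriceTable,
    RunConfig,
)
from .impute import ImputationSpec, mice_pmm
from .inference import AdjustedComparison, compare_models

__all__ = ["AnalysisResult", "attach_models", "impute_wave_costs", "run_analysis"]


@dataclass
class AnalysisResult:
    """Everything the benchmark run produces."""

    completed: list[pd.DataFrame]
    comparisons: list[AdjustedComparison]
    aggregates: pd.DataFrame
    assignments: pd.DataFrame
    config: RunConfig


def attach_models(
    wave_costs: pd.DataFrame,
    assignments: pd.DataFrame,
    include_flagged: bool = False,
) -> pd.DataFrame:
    """Join care-model labels onto the per-client cost table.

    Clients of organizations classified into the residual models (CM5/CM6)
    are excluded unless ``include_flagged`` — those models are too small to
    analyze and have no effect/share configuration.
    """
    cols = assignments[["org_id", "model", "flagged"]]
    merged = wave_costs.merge(cols, on="org_id", how="left", validate="many_to_one")
    if merged["model"].isna().any():
        orphans = sorted(merged.loc[merged["model"].isna(), "org_id"].unique())
        raise ValueError(f"clients from unclassified organizations: {orphans}")
    if not include_flagged:
        merged = merged[~merged["flagged"]].reset_index(drop=True)
    return merged.drop(columns="flagged")


def impute_wave_costs(
    wave_costs: pd.DataFrame,
    config: RunConfig,
    m: int | None = None,
    rng: np.random.Generator | None = None,
    predictors: Sequence[str] | None = None,
) -> list[pd.DataFrame]:
    """Impute missing quarterly cost cells; returns m completed datasets.

    Cells determined by the halfway-transition rule (month-6 costs of
    deceased/institutionalized clients) are masked out of the imputation —
    they are filled by :func:`carebench.costing.complete_six_month`.
    Predictors default to the case-mix covariates plus care-model dummies.
    """
    m = m if m is not None else config.n_imputations
    targets = wave_cost_columns()
    work = wave_costs.copy()
    pred_cols: list[str] = list(predictors) if predictors is not None else []
    if predictors is None:
        pred_cols = list(CASE_MIX_COVARIATES)
        for model in sorted(work["model"].unique())[1:]:
            col = f"_model_{model}"
            work[col] = (work["model"] == model).astype(float)
            pred_cols.append(col)
    mask = ~rule_mask(work)  # imputable = NaN cells outside the rule mask
    spec = ImputationSpec(m=m, predictors=tuple(pred_cols), seed=config.rng_seed)
    completed = mice_pmm(work, targets, spec, mask=mask, rng=rng)
    return [frame.drop(columns=[c for c in frame.columns if c.startswith("_model_")])
            for frame in completed]


def run_analysis(
    records: Sequence[ClientWaveRecord],
    org_frame: pd.DataFrame,
    prices: PriceTable,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> AnalysisResult:
    """Run the full benchmark on a cohort; see the module docstring."""
    config = config or RunConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    assignments = classify_organizations(org_frame)
    wave_costs = attach_models(wave_cost_table(records, prices, config), assignments)
    if wave_costs[wave_cost_columns()].isna().to_numpy().any():
        completed_wave = impute_wave_costs(wave_costs, config, rng=rng)
    else:
        completed_wave = [wave_costs]
    allow = ("informal_care",) if config.perspective == "healthcare" else ()
    completed = [
        complete_six_month(frame, prices, config, allow_missing=allow)
        for frame in completed_wave
    ]
    comparisons = compare_models(completed, config, rng=rng)
    # Unadjusted means: average the per-dataset aggregate tables (identical
    # group sizes across imputations, so this is the pooled mean).
    per_dataset = [aggregate(f, perspective=config.perspective) for f in completed]
    aggregates = per_dataset[0].copy()
    numeric = aggregates.select_dtypes("number").columns
    aggregates[numeric] = sum(t[numeric] for t in per_dataset) / len(per_dataset)
    return AnalysisResult(
        completed=completed,
        comparisons=comparisons,
        aggregates=aggregates,
        assignments=assignments,
        config=config,
    )
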