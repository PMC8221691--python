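"""Benchmark tables and figures.

Renders the run's outputs into the benchmark deliverables: per-model
unadjusted mean costs by category with standard errors, category shares of
the total, the informal-care to home-care cost ratio, and a forest-style
table of adjusted between-model differences with their confidence intervals.
Monetary values are rounded to whole currency units in the human-readable
tables and kept at full precision in the machine-readable output; all numbers
are carried over from the upstream tables, never recomputed, so report totals
equal upstream totals exactly and re-rendering the same inputs is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .data_io import CATEGORIES, RunConfig
from .inference import AdjustedComparison

__all__ = ["BenchmarkReport", "build_report", "render_report", "run_manifest"]


class ManifestMismatchError(ValueError):
    """Inputs come from different runs (seeds or configuration differ)."""


def run_manifest(config: RunConfig, n_per_model: Mapping[str, int]) -> dict:
    """Machine-readable provenance for one run; equality across inputs is
    what :func:`build_report` checks."""
    return {
        "perspective": config.perspective,
        "price_table": config.price_table,
        "rng_seed": config.rng_seed,
        "n_imputations": config.n_imputations,
        "n_bootstrap": config.n_bootstrap,
        "alpha": config.alpha,
        "n_per_model": dict(n_per_model),
    }


@dataclass
class BenchmarkReport:
    model_costs: pd.DataFrame
    contrasts: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def shares_sum_to_100(self, tol: float = 1e-6) -> bool:
        share_cols = [c for c in self.model_costs.columns if c.endswith("_share_pct")]
        sums = self.model_costs[share_cols].sum(axis=1)
        return bool(((sums - 100.0).abs() < tol).all())


def build_report(
    aggregates: pd.DataFrame,
    comparisons: Sequence[AdjustedComparison],
    config: RunConfig,
    manifests: Sequence[Mapping] | None = None,
) -> BenchmarkReport:
    """Assemble the benchmark report from upstream outputs.

    ``manifests``, when given, must all be equal — mixing tables produced
    under different seeds or configurations is an error, not a warning.
    A single-model run yields means but no contrast rows.
    """
    if manifests:
        first = dict(manifests[0])
        for other in manifests[1:]:
            if dict(other) != first:
                raise ManifestMismatchError(
                    "inputs were produced by different runs: "
                    f"{first} != {dict(other)}"
                )
        manifest = first
    else:
        manifest = run_manifest(
            config,
            dict(zip(aggregates["model"], aggregates["n"].astype(int))),
        )
    contrast_rows = [
        {
            "contrast": f"{a} - {b}",
            "estimate": comp.estimate,
            "ci_low": comp.ci_low,
            "ci_high": comp.ci_high,
            "n_bootstrap": comp.n_bootstrap,
            "n_clients": comp.n,
            "covariates": ",".join(comp.covariates),
            "excludes_zero": comp.excludes_zero(),
        }
        for comp in comparisons
        for a, b in [comp.contrast]
    ]
    contrasts = pd.DataFrame(
        contrast_rows,
        columns=[
            "contrast",
            "estimate",
            "ci_low",
            "ci_high",
            "n_bootstrap",
            "n_clients",
            "covariates",
            "excludes_zero",
        ],
    )
    return BenchmarkReport(
        model_costs=aggregates.copy(), contrasts=contrasts, manifest=manifest
    )


def render_report(
    report: BenchmarkReport,
    out_dir: str | Path,
    plot: bool = False,
) -> dict[str, Path]:
    """Write the report tables (and optionally a stacked-cost figure).

    ``model_costs.csv`` / ``contrasts.csv`` keep full precision;
    ``model_costs_rounded.csv`` rounds money to whole units for reading.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["model_costs"] = out_dir / "model_costs.csv"
    report.model_costs.to_csv(paths["model_costs"], index=False)

    rounded = report.model_costs.copy()
    money_cols = [
        c
        for c in rounded.columns
        if c.endswith(("_mean", "_se")) or c in ("total_mean", "total_se")
    ]
    rounded[money_cols] = rounded[money_cols].round(0)
    share_cols = [c for c in rounded.columns if c.endswith("_share_pct")]
    rounded[share_cols] = rounded[share_cols].round(1)
    paths["model_costs_rounded"] = out_dir / "model_costs_rounded.csv"
    rounded.to_csv(paths["model_costs_rounded"], index=False)

    paths["contrasts"] = out_dir / "contrasts.csv"
    report.contrasts.to_csv(paths["contrasts"], index=False)

    paths["manifest"] = out_dir / "manifest.json"
    with open(paths["manifest"], "w", encoding="utf-8") as handle:
        json.dump(report.manifest, handle, indent=2, sort_keys=True)

    if plot:
        paths["figure"] = _stacked_cost_figure(report, out_dir)
    return paths


def _stacked_cost_figure(report: BenchmarkReport, out_dir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = report.model_costs
    cats = [c for c in CATEGORIES if f"{c}_mean" in frame.columns]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    bottom = None
    for cat in cats:
        values = frame[f"{cat}_mean"]
        ax.bar(frame["model"], values, bottom=bottom, label=cat.replace("_", " "))
        bottom = values if bottom is None else bottom + values
    ax.set_ylabel("mean 6-month cost per client")
    ax.set_title("Unadjusted 6-month cost of care per client by care model")
    ax.legend(fontsize=8)
    path = out_dir / "model_costs.png"
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
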