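"""Synthetic multi-country home-care cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes — a
multi-organization, multi-country cohort of home-care clients aged 65+ with
two assessment waves, right-skewed resource use, wave-2 attrition
(death, institutionalization, discharge, loss to follow-up), item-level
missingness, and care-model-level differences in expected 6-month societal
cost confounded by case mix — so every downstream stage is testable without
any external data.

Cost control works through the utilization quantities, not post-hoc on money:
for each client the *expected valued* 6-month societal cost equals

    base_cost + effect[model] + sum_v beta_v * (x_v - center_v),

where the betas (``confounding_strength``) link case-mix scores to expected
utilization.  The model-level expectation is distributed over cost categories
by per-model shares; the client-level case-mix deviation loads on the
home-care and informal-care categories (dependency drives hands-on care),
which is what makes unadjusted between-model comparisons biased and case-mix
adjustment necessary.  Quantities are drawn from Poisson (event counts) and
gamma (minutes and days; shape ``cost_shape`` < 1 gives the heavy right skew
typical of cost data), so expectations are exact and the costing engine is
exercised on realistic inputs.

Deaths and institutionalizations are recorded only as a wave-2 status — the
event time inside the interval is unobserved, exactly as the real instrument
sees it; translating the status into costs (the halfway rule) is the costing
engine's job, not the generator's.

Default parameter values mirror the study conditions: 6/3/9 organizations in
care models 1–3 with ≈1330/310/420 clients, country mixes per model,
case-mix distributions calibrated to the published per-model means,
transition probabilities of 3%/2%/0.7%/2.6%, a wave-2 item missingness rate
implying ≈29% of clients with at least one missing resource item, and
between-model effects of €0/+2230/−321.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .care_models import (
    N_ASP_ITEMS,
    N_MCP_ITEMS,
    N_PCC_ITEMS,
    ORG_ITEM_COLUMNS,
)
from .data_io import (
    ITEM_RECALL,
    ClientWaveRecord,
    PriceTable,
    ResourceUseItem,
    default_price_table,
)

__all__ = [
    "SimulationScenario",
    "ScenarioError",
    "generate_cohort",
    "inject_missingness",
    "expected_model_cost",
]


class ScenarioError(ValueError):
    """The simulation scenario is invalid or infeasible."""


#: Case-mix distributions per care model: age ~ Normal(mean, sd) floored at
#: 65 and rounded; binary traits Bernoulli(p); ordinal scales Binomial(max, p)
#: with p calibrated so the means match the published per-model profiles
#: (e.g. ADLH means 1.9 / 0.6 / 2.2 for CM1–CM3).
DEFAULT_CASE_MIX: Mapping[str, Mapping[str, float]] = {
    "CM1": dict(age_mean=82.7, age_sd=7.5, sex_p=0.66, living_alone_p=0.51,
                cps_p=0.22, drs_p=0.08, adlh_p=1.9 / 6, iadl_p=30.6 / 48,
                chess_p=1.2 / 5, distress_p=0.18),
    "CM2": dict(age_mean=82.4, age_sd=7.2, sex_p=0.67, living_alone_p=0.73,
                cps_p=0.10, drs_p=0.085, adlh_p=0.6 / 6, iadl_p=23.0 / 48,
                chess_p=0.8 / 5, distress_p=0.10),
    "CM3": dict(age_mean=83.5, age_sd=7.7, sex_p=0.71, living_alone_p=0.74,
                cps_p=0.27, drs_p=0.10, adlh_p=2.2 / 6, iadl_p=29.1 / 48,
                chess_p=0.6 / 5, distress_p=0.10),
    "CM4": dict(age_mean=82.2, age_sd=7.3, sex_p=0.69, living_alone_p=0.61,
                cps_p=0.14, drs_p=0.08, adlh_p=2.6 / 6, iadl_p=30.0 / 48,
                chess_p=0.8 / 5, distress_p=0.08),
}

SCALE_MAX = {"cps": 6, "drs": 14, "adlh": 6, "iadl": 48, "chess": 5}

#: Euros of expected 6-month societal cost per unit of each case-mix variable
#: (age is centred at 80 years).  Caregiver distress deliberately carries no
#: weight: it is not among the adjustment covariates, and a cost-linked
#: unadjusted confounder would make the adjusted contrast unrecoverable.
DEFAULT_BETAS: Mapping[str, float] = {
    "age": 30.0,
    "sex": 300.0,
    "living_alone": 500.0,
    "cps": 300.0,
    "drs": 100.0,
    "adlh": 900.0,
    "iadl": 40.0,
    "chess": 600.0,
}

#: Per-model allocation of the expected cost over the six community
#: categories (institutional accrues only via transitions), echoing the
#: published pattern: informal care dominates CM1 (~60%), home care dominates
#: CM3 (~54%).
DEFAULT_SHARES: Mapping[str, Mapping[str, float]] = {
    "CM1": dict(informal_care=0.60, home_care=0.18, hospital=0.11,
                visits=0.04, other_healthcare=0.03, supportive=0.04),
    "CM2": dict(informal_care=0.38, home_care=0.19, hospital=0.12,
                visits=0.11, other_healthcare=0.10, supportive=0.10),
    "CM3": dict(informal_care=0.25, home_care=0.54, hospital=0.06,
                visits=0.06, other_healthcare=0.04, supportive=0.05),
    "CM4": dict(informal_care=0.30, home_care=0.45, hospital=0.11,
                visits=0.05, other_healthcare=0.04, supportive=0.05),
}

#: High/low questionnaire patterns per model, (PCC, ASP, MCP).
MODEL_PATTERNS: Mapping[str, tuple[bool, bool, bool]] = {
    "CM1": (True, True, True),
    "CM2": (True, False, True),
    "CM3": (False, False, True),
    "CM4": (True, True, False),
}


@dataclass
class SimulationScenario:
    """Everything that defines a synthetic cohort; defaults = study conditions."""

    n_orgs_per_model: Mapping[str, int] = field(
        default_factory=lambda: {"CM1": 6, "CM2": 3, "CM3": 9}
    )
    n_clients_per_org: int | Mapping[str, int] = field(
        default_factory=lambda: {"CM1": 222, "CM2": 104, "CM3": 46}
    )
    countries: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "CM1": ("IT", "NL", "IS", "FI"),
            "CM2": ("NL", "FI"),
            "CM3": ("DE",),
            "CM4": ("BE",),
        }
    )
    true_model_effects: Mapping[str, float] = field(
        default_factory=lambda: {"CM1": 0.0, "CM2": 2230.0, "CM3": -321.0,
                                 "CM4": 3644.0}
    )
    base_cost: float = 14100.0
    case_mix_distributions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_CASE_MIX
    )
    confounding_strength: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_BETAS
    )
    category_shares: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_SHARES
    )
    cost_shape: float = 0.8
    transition_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "institutionalized": 0.03,
            "deceased": 0.02,
            "discharged": 0.007,
            "lost": 0.026,
        }
    )
    missingness: Mapping[str, object] = field(
        default_factory=lambda: {"mechanism": "mcar", "rate": 0.037}
    )
    facility: str = "nursing_home"
    prices: PriceTable | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total_p = 0.0
        for key, p in self.transition_probs.items():
            if key not in ("institutionalized", "deceased", "discharged", "lost"):
                raise ScenarioError(f"unknown transition {key!r}")
            if not 0.0 <= p <= 1.0:
                raise ScenarioError(f"transition prob {key} outside [0,1]")
            total_p += p
        if total_p > 1.0 + 1e-12:
            raise ScenarioError("transition probabilities sum to > 1")
        rate = float(self.missingness.get("rate", 0.0))
        if not 0.0 <= rate <= 1.0:
            raise ScenarioError("missingness rate outside [0,1]")
        if self.base_cost <= 0:
            raise ScenarioError("base_cost must be positive")
        if self.cost_shape <= 0:
            raise ScenarioError("cost_shape must be positive")
        for model in self.n_orgs_per_model:
            for table, label in (
                (self.true_model_effects, "true_model_effects"),
                (self.case_mix_distributions, "case_mix_distributions"),
                (self.category_shares, "category_shares"),
                (self.countries, "countries"),
            ):
                if model not in table:
                    raise ScenarioError(f"{label} missing entry for {model!r}")
            shares = self.category_shares[model]
            if any(v < 0 for v in shares.values()):
                raise ScenarioError(f"negative share for {model!r}")
            if not math.isclose(sum(shares.values()), 1.0, abs_tol=1e-9):
                raise ScenarioError(f"shares for {model!r} must sum to 1")

    def clients_for(self, model: str) -> int:
        if isinstance(self.n_clients_per_org, Mapping):
            return int(self.n_clients_per_org[model])
        return int(self.n_clients_per_org)

    def price_table(self) -> PriceTable:
        return self.prices if self.prices is not None else default_price_table()


def _expected_case_mix(params: Mapping[str, float]) -> dict[str, float]:
    return {
        "age": params["age_mean"],
        "sex": params["sex_p"],
        "living_alone": params["living_alone_p"],
        "cps": SCALE_MAX["cps"] * params["cps_p"],
        "drs": SCALE_MAX["drs"] * params["drs_p"],
        "adlh": SCALE_MAX["adlh"] * params["adlh_p"],
        "iadl": SCALE_MAX["iadl"] * params["iadl_p"],
        "chess": SCALE_MAX["chess"] * params["chess_p"],
    }


def _case_mix_contribution(
    betas: Mapping[str, float], values: Mapping[str, float]
) -> float:
    total = 0.0
    for name, beta in betas.items():
        x = values[name]
        if name == "age":
            x = x - 80.0
        total += beta * x
    return total


def expected_model_cost(scenario: SimulationScenario, model: str) -> float:
    """Implied expected 6-month societal cost per client of a care model.

    ``base_cost + effect[model] + case-mix contribution at the model's
    expected scores`` — the quantity the sample mean converges to (before
    transitions remove second-wave community costs).
    """
    params = scenario.case_mix_distributions[model]
    return (
        scenario.base_cost
        + scenario.true_model_effects[model]
        + _case_mix_contribution(
            scenario.confounding_strength, _expected_case_mix(params)
        )
    )


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

_COUNT_ITEMS = ("er_visits", "physician_visits", "supportive_units", "other_hc_units")
_STATUS_ORDER = ("institutionalized", "deceased", "discharged", "lost")


def _draw_case_mix(
    params: Mapping[str, float], k: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    age = np.round(rng.normal(params["age_mean"], params["age_sd"], size=k))
    return {
        "age": np.maximum(65, age).astype(int),
        "sex": rng.binomial(1, params["sex_p"], size=k),
        "living_alone": rng.binomial(1, params["living_alone_p"], size=k),
        "cps": rng.binomial(SCALE_MAX["cps"], params["cps_p"], size=k),
        "drs": rng.binomial(SCALE_MAX["drs"], params["drs_p"], size=k),
        "adlh": rng.binomial(SCALE_MAX["adlh"], params["adlh_p"], size=k),
        "iadl": rng.binomial(SCALE_MAX["iadl"], params["iadl_p"], size=k),
        "chess": rng.binomial(SCALE_MAX["chess"], params["chess_p"], size=k),
        "distress": rng.binomial(1, params["distress_p"], size=k),
    }


def _quarter_item_means(
    scenario: SimulationScenario,
    model: str,
    case_mix: Mapping[str, np.ndarray],
    prices: PriceTable,
    country: str,
) -> dict[str, np.ndarray]:
    """Expected *recall-window* quantity per item for each client.

    Derived by inverting the costing arithmetic: category expected 6-month
    cost -> per-quarter cost (half, waves being exchangeable) -> scaled
    quantity via the unit price -> raw recall-window quantity via
    ``recall / 91``.
    """
    k = len(case_mix["age"])
    betas = scenario.confounding_strength
    exp_cm = _expected_case_mix(scenario.case_mix_distributions[model])
    model_mean = expected_model_cost(scenario, model)
    dev = np.zeros(k)
    for name, beta in betas.items():
        values = case_mix[name].astype(float)
        centre = exp_cm[name]
        dev += beta * (values - centre)

    shares = scenario.category_shares[model]
    care_share = shares["home_care"] + shares["informal_care"]
    if care_share <= 0:
        raise ScenarioError(
            "home_care + informal_care shares must be positive to carry the "
            "case-mix deviation"
        )
    target: dict[str, np.ndarray] = {}
    for cat, share in shares.items():
        t = np.full(k, model_mean * share)
        if cat in ("home_care", "informal_care"):
            t = t + dev * share / care_share
        if (t < -1e-9).any():
            raise ScenarioError(
                f"infeasible scenario: negative expected {cat} cost for model "
                f"{model} (reduce confounding_strength or raise base_cost)"
            )
        target[cat] = np.maximum(t, 0.0) / 2.0  # per-quarter expected cost

    unit = prices.unit_costs
    means: dict[str, np.ndarray] = {}
    means["er_visits"] = target["visits"] * 0.4 / unit["er_visit"] * 90 / 91
    means["physician_visits"] = (
        target["visits"] * 0.6 / unit["physician_visit"] * 90 / 91
    )
    means["supportive_units"] = (
        target["supportive"] / unit["supportive_unit"] * 90 / 91
    )
    means["other_hc_units"] = (
        target["other_healthcare"] / unit["other_hc_unit"] * 90 / 91
    )
    means["home_care_min"] = (
        target["home_care"] * 0.85 / unit["home_care_hour"] * 60 * 7 / 91
    )
    means["therapist_min"] = (
        target["home_care"] * 0.15 / unit["therapist_hour"] * 60 * 7 / 91
    )
    means["informal_care_min"] = (
        target["informal_care"] / prices.informal_care_wage * 60 * 3 / 91
    )
    nights_q = target["hospital"] / unit["hospital_night"]
    if country == prices.recorded_days_country:
        means["hosp_days"] = nights_q * 90 / 91
        means["hosp_events"] = None  # not registered in the recorded-days country
    else:
        if country not in prices.hospital_los:
            raise ScenarioError(f"no LOS entry for country {country!r}")
        means["hosp_events"] = nights_q / prices.hospital_los[country] * 90 / 91
        means["hosp_days"] = None
    return means


def _draw_items(
    means: Mapping[str, np.ndarray | None],
    shape: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray | None]:
    """Poisson draws for event counts, gamma draws for minutes/days."""
    out: dict[str, np.ndarray | None] = {}
    for key, mean in means.items():
        if mean is None:
            out[key] = None
            continue
        if key in _COUNT_ITEMS or key == "hosp_events":
            out[key] = rng.poisson(mean).astype(float)
        else:
            draws = np.zeros_like(mean)
            positive = mean > 0
            draws[positive] = rng.gamma(shape, mean[positive] / shape)
            out[key] = draws
    return out


def _items_for_client(
    quantities: Mapping[str, np.ndarray | None], i: int, informal_assessed: bool
) -> list[ResourceUseItem]:
    items = []
    for key, recall in ITEM_RECALL.items():
        values = quantities.get(key)
        q = None if values is None else float(values[i])
        if key == "informal_care_min" and not informal_assessed:
            q = None
        items.append(ResourceUseItem(key, q, recall))
    return items


def generate_cohort(
    scenario: SimulationScenario,
) -> tuple[list[ClientWaveRecord], pd.DataFrame, dict]:
    """Generate a cohort, its organization table, and the ground truth.

    Returns ``(records, org_frame, truth)`` where ``truth`` stores every
    injected effect (model effects, betas, implied per-model expected costs)
    for parameter-recovery tests.  Identical scenario + seed give an identical
    cohort.  Informal-care time is not assessed in the recorded-days country,
    mirroring the instrument's coverage gap there.
    """
    rng = np.random.default_rng(scenario.seed)
    prices = scenario.price_table()
    records: list[ClientWaveRecord] = []
    org_rows = []
    client_counter = 0
    org_counter = 0
    transition = scenario.transition_probs
    p_levels = [transition.get(s, 0.0) for s in _STATUS_ORDER]

    for model in scenario.n_orgs_per_model:
        n_orgs = scenario.n_orgs_per_model[model]
        pattern = MODEL_PATTERNS.get(model)
        if pattern is None:
            raise ScenarioError(f"no questionnaire pattern for model {model!r}")
        country_cycle = scenario.countries[model]
        for j in range(n_orgs):
            org_counter += 1
            org_id = f"O{org_counter:03d}"
            country = country_cycle[j % len(country_cycle)]
            org_rows.append(
                _org_row(org_id, pattern, rng)
            )
            k = scenario.clients_for(model)
            case_mix = _draw_case_mix(
                scenario.case_mix_distributions[model], k, rng
            )
            means = _quarter_item_means(scenario, model, case_mix, prices, country)
            status_u = rng.random(k)
            informal_assessed = country != prices.recorded_days_country
            wave_draws = {
                wave: _draw_items(means, scenario.cost_shape, rng)
                for wave in ("baseline", "month6")
            }
            for i in range(k):
                client_counter += 1
                client_id = f"C{client_counter:05d}"
                status = "in_care"
                cum = 0.0
                for s, p in zip(_STATUS_ORDER, p_levels):
                    cum += p
                    if status_u[i] < cum:
                        status = s
                        break
                common = dict(
                    client_id=client_id,
                    org_id=org_id,
                    country=country,
                    age=int(case_mix["age"][i]),
                    sex="female" if case_mix["sex"][i] else "male",
                    living_alone=bool(case_mix["living_alone"][i]),
                    cps=int(case_mix["cps"][i]),
                    drs=int(case_mix["drs"][i]),
                    adlh=int(case_mix["adlh"][i]),
                    iadl=int(case_mix["iadl"][i]),
                    chess=int(case_mix["chess"][i]),
                    caregiver_distress=bool(case_mix["distress"][i]),
                )
                records.append(
                    ClientWaveRecord(
                        wave="baseline",
                        status="in_care",
                        resource_items=_items_for_client(
                            wave_draws["baseline"], i, informal_assessed
                        ),
                        **common,
                    )
                )
                if status == "in_care":
                    items = _items_for_client(
                        wave_draws["month6"], i, informal_assessed
                    )
                else:
                    items = [
                        ResourceUseItem(key, None, recall)
                        for key, recall in ITEM_RECALL.items()
                    ]
                records.append(
                    ClientWaveRecord(
                        wave="month6",
                        status=status,
                        resource_items=items,
                        facility_per_diem_key=(
                            scenario.facility
                            if status == "institutionalized"
                            else None
                        ),
                        **common,
                    )
                )

    mechanism = str(scenario.missingness.get("mechanism", "mcar"))
    rate = float(scenario.missingness.get("rate", 0.0))
    if rate > 0:
        records = inject_missingness(
            records,
            mechanism,
            rate,
            rng=rng,
            mar_coef=float(scenario.missingness.get("mar_coef", 0.35)),
        )

    truth = {
        "seed": scenario.seed,
        "base_cost": scenario.base_cost,
        "true_model_effects": dict(scenario.true_model_effects),
        "confounding_strength": dict(scenario.confounding_strength),
        "expected_model_costs": {
            m: expected_model_cost(scenario, m) for m in scenario.n_orgs_per_model
        },
        "category_shares": {
            m: dict(scenario.category_shares[m]) for m in scenario.n_orgs_per_model
        },
    }
    org_frame = pd.DataFrame(org_rows, columns=("org_id",) + ORG_ITEM_COLUMNS)
    return records, org_frame, truth


def _org_row(
    org_id: str, pattern: tuple[bool, bool, bool], rng: np.random.Generator
) -> dict:
    """Questionnaire items consistent with a high/low element pattern (0-4 scale)."""
    row = {"org_id": org_id}
    for prefix, n_items, high in zip(
        ("pcc", "asp", "mcp"), (N_PCC_ITEMS, N_ASP_ITEMS, N_MCP_ITEMS), pattern
    ):
        lo, hi = (3, 5) if high else (0, 2)
        for i in range(1, n_items + 1):
            row[f"{prefix}_{i}"] = int(rng.integers(lo, hi))
    return row


# --------------------------------------------------------------------------
# Missingness injection
# --------------------------------------------------------------------------


def inject_missingness(
    records: Sequence[ClientWaveRecord],
    mechanism: str,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mar_coef: float = 0.35,
    mar_covariate: str = "adlh",
) -> list[ClientWaveRecord]:
    """Delete month-6 resource quantities, MCAR or MAR.

    Eligible cells are the present quantities on month-6 records (baseline is
    assumed complete; the imputation stage targets 6-month costs).  MCAR
    deletes each eligible quantity independently with probability ``rate``.
    MAR makes the deletion probability the logistic function

        p_i = expit(logit(rate) + mar_coef * (x_i - mean(x)))

    of the client's observed case-mix score ``x`` (ADLH by default), centred
    on the cohort mean so the average rate stays ≈ ``rate``.  Deterministic
    under the seed / generator.
    """
    if mechanism not in ("mcar", "mar"):
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0,1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rate == 0.0:
        return list(records)

    eligible = [
        rec for rec in records if rec.wave == "month6" and rec.status == "in_care"
    ]
    if mechanism == "mar" and eligible:
        mean_x = float(
            np.mean([getattr(rec, mar_covariate) for rec in eligible])
        )
    out: list[ClientWaveRecord] = []
    for rec in records:
        if rec.wave != "month6" or rec.status != "in_care":
            out.append(rec)
            continue
        if mechanism == "mcar":
            p = rate
        else:
            if rate >= 1.0:
                p = 1.0
            else:
                x = float(getattr(rec, mar_covariate))
                p = float(expit(logit(rate) + mar_coef * (x - mean_x)))
        new_items = []
        for item in rec.resource_items:
            q = item.quantity
            if q is not None and rng.random() < p:
                q = None
            new_items.append(ResourceUseItem(item.item_key, q, item.recall_days))
        out.append(dataclasses.replace(rec, resource_items=new_items))
    return out
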