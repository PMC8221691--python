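"""Valuation of resource utilization into quarterly and 6-month costs.

Each resource-utilization quantity is observed over an item-specific recall
window (90, 7 or 3 days), scaled to a 91-day quarter
(``quantity * 91 / recall``), and multiplied by its standard unit cost.  Costs
accumulate into seven categories — hospital admissions, emergency/physician
visits, other healthcare services, supportive care services, institutional
care, home care, and informal care — which sum to the total *societal* cost;
the *healthcare* perspective excludes informal care.  Informal-care minutes
are converted to hours and valued at the wage rate of a legally employed
cleaner (proxy-good method).

Hospital use is recorded as admission events; nights are estimated as
``events x country mean length of stay``, except in the one configured
recorded-days country where the registered number of admission days is used
directly.

Six-month totals interpolate the two quarterly assessments with weights
(0.5, 1.5): the first three months are the average of the two assessments,
the second three months are the month-6 assessment alone.

For clients who die or are institutionalized between assessments the event is
assumed to occur halfway through the 182-day window: community costs accrue at
the baseline rate for the first 91 days and, afterwards, nothing (death) or a
facility per-diem (institutionalization).  :func:`apply_transition_rules`
encodes this as an *effective* month-6 quarterly cost, chosen so that the
0.5/1.5 interpolation reproduces the day-by-day accrual total exactly — the
interpolation identity therefore holds for every client, transition or not.
Discharged and lost-to-follow-up clients have genuinely missing month-6 costs,
which are left missing for the imputation stage.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    CATEGORIES,
    ClientWaveRecord,
    PriceTable,
    RunConfig,
)

__all__ = [
    "CostingError",
    "scale_to_quarter",
    "hospital_nights",
    "value_wave",
    "apply_transition_rules",
    "six_month_cost",
    "wave_cost_table",
    "complete_six_month",
    "aggregate",
    "wave_cost_columns",
]

COMMUNITY_CATEGORIES: tuple[str, ...] = tuple(
    c for c in CATEGORIES if c != "institutional"
)


class CostingError(ValueError):
    """A costing precondition is violated (unpriced item, missing LOS, ...)."""


def scale_to_quarter(
    quantity: float | None, recall_days: int, quarter_days: int = 91
) -> float:
    """Scale a recall-window quantity to a quarter: ``q * quarter_days / recall``.

    A missing quantity propagates as NaN; imputation handles it later.
    """
    if quantity is None:
        return float("nan")
    if isinstance(quantity, float) and math.isnan(quantity):
        return float("nan")
    if quantity < 0:
        raise CostingError(f"quantity must be >= 0, got {quantity}")
    return quantity * quarter_days / recall_days


def hospital_nights(
    events: float | None,
    country: str,
    recorded_days: float | None,
    los_table: Mapping[str, float],
    recorded_days_country: str | None = None,
) -> float:
    """Estimate hospital nights from admission events.

    In the recorded-days country the registered number of admission days is
    used directly; elsewhere nights are ``events x mean LOS`` for the country.
    Missing inputs propagate as NaN.
    """
    if country == recorded_days_country:
        if recorded_days is None:
            return float("nan")
        if recorded_days < 0:
            raise CostingError("recorded hospital days must be >= 0")
        return float(recorded_days)
    if recorded_days is not None:
        raise CostingError(
            f"recorded hospital days supplied for {country!r}, which is not the "
            "configured recorded-days country"
        )
    if events is None:
        return float("nan")
    if events < 0:
        raise CostingError("hospital events must be >= 0")
    if country not in los_table:
        raise CostingError(f"no mean length-of-stay entry for country {country!r}")
    return float(events) * los_table[country]


def value_wave(
    record: ClientWaveRecord, prices: PriceTable, quarter_days: int = 91
) -> dict[str, float]:
    """Per-category quarterly cost for one assessment wave.

    Each item's recall-scaled quantity is multiplied by its unit cost and
    accumulated into its category; minute-denominated items are converted to
    hours first.  A missing item quantity makes its whole category NaN (never
    silently zero).  The institutional category is always 0 at the item level;
    it accrues only through the post-institutionalization rule.
    """
    unit = prices.unit_costs
    q = record.quantity

    def scaled(key: str, recall: int) -> float:
        return scale_to_quarter(q(key), recall, quarter_days)

    nights_raw = hospital_nights(
        q("hosp_events"),
        record.country,
        q("hosp_days"),
        prices.hospital_los,
        prices.recorded_days_country,
    )
    nights_q = scale_to_quarter(
        None if math.isnan(nights_raw) else nights_raw, 90, quarter_days
    )
    costs = {
        "hospital": nights_q * unit["hospital_night"],
        "visits": scaled("er_visits", 90) * unit["er_visit"]
        + scaled("physician_visits", 90) * unit["physician_visit"],
        "other_healthcare": scaled("other_hc_units", 90) * unit["other_hc_unit"],
        "supportive": scaled("supportive_units", 90) * unit["supportive_unit"],
        "institutional": 0.0,
        "home_care": scaled("home_care_min", 7) / 60.0 * unit["home_care_hour"]
        + scaled("therapist_min", 7) / 60.0 * unit["therapist_hour"],
        "informal_care": scaled("informal_care_min", 3)
        / 60.0
        * prices.informal_care_wage,
    }
    return costs


def apply_transition_rules(
    wave2_costs: Mapping[str, float],
    status: str,
    facility_per_diem: float | None,
    quarter_days: int = 91,
    weights: tuple[float, float] = (0.5, 1.5),
) -> dict[str, float] | None:
    """Effective month-6 quarterly costs under the halfway-transition rule.

    For deceased and institutionalized clients ``wave2_costs`` is the
    carried-forward *baseline* community quarterly cost (no month-6 assessment
    exists).  The event is placed at the window midpoint (day 91 of 182):
    community costs accrue at the baseline rate before it and zero after;
    institutionalization additionally accrues ``facility_per_diem`` per
    post-midpoint day.  The returned quarterly costs are those for which
    ``w1 * baseline + w2 * returned`` equals the day-by-day accrual total —
    for community categories that is ``carry * (1 - w1) / w2`` (= carry/3 at
    the default weights) and, for the institutional category,
    ``per_diem * quarter_days / w2``.

    ``in_care`` clients pass through unchanged; ``discharged``/``lost``
    clients return ``None`` (month-6 costs are missing, imputation's job).
    """
    if status == "in_care":
        return dict(wave2_costs)
    if status in ("discharged", "lost"):
        return None
    w1, w2 = weights
    if status == "deceased":
        adjusted = {c: wave2_costs.get(c, 0.0) * (1.0 - w1) / w2 for c in CATEGORIES}
        adjusted["institutional"] = 0.0
        return adjusted
    if status == "institutionalized":
        if facility_per_diem is None:
            raise CostingError(
                "institutionalized client without a facility per-diem"
            )
        adjusted = {c: wave2_costs.get(c, 0.0) * (1.0 - w1) / w2 for c in CATEGORIES}
        adjusted["institutional"] = facility_per_diem * quarter_days / w2
        return adjusted
    raise CostingError(f"unknown status {status!r}")


def six_month_cost(
    cost_baseline_quarter: float,
    cost_month6_quarter: float,
    weights: tuple[float, float] = (0.5, 1.5),
) -> float:
    """Interpolated 6-month cost: ``w1 * baseline + w2 * month6``."""
    w1, w2 = weights
    return w1 * cost_baseline_quarter + w2 * cost_month6_quarter


# --------------------------------------------------------------------------
# Cohort-level pipeline
# --------------------------------------------------------------------------

#: Follow-up statuses whose month-6 costs are determined by rule, not data.
RULE_STATUSES = ("deceased", "institutionalized")
#: Statuses whose month-6 costs are genuinely missing.
MISSING_STATUSES = ("discharged", "lost")


def wave_cost_columns() -> list[str]:
    return [f"{cat}_bl" for cat in CATEGORIES] + [f"{cat}_m6" for cat in CATEGORIES]


def wave_cost_table(
    records: Sequence[ClientWaveRecord],
    prices: PriceTable,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """One row per client with quarterly per-category costs at both waves.

    Month-6 cells are NaN where the quantity was not assessed (item
    missingness), where the client dropped out (discharged/lost), or where the
    halfway-transition rule applies (deceased/institutionalized; those cells
    are filled by :func:`complete_six_month`, not by imputation).  Baseline
    covariates, the follow-up status, and the facility key ride along for the
    downstream stages.
    """
    config = config or RunConfig()
    by_client: dict[str, dict[str, ClientWaveRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.client_id not in by_client:
            by_client[rec.client_id] = {}
            order.append(rec.client_id)
        if rec.wave in by_client[rec.client_id]:
            raise CostingError(
                f"client {rec.client_id!r}: duplicate wave {rec.wave!r}"
            )
        by_client[rec.client_id][rec.wave] = rec

    rows = []
    for client_id in order:
        waves = by_client[client_id]
        if "baseline" not in waves:
            raise CostingError(f"client {client_id!r}: no baseline record")
        bl = waves["baseline"]
        m6 = waves.get("month6")
        status = m6.status if m6 is not None else "lost"
        row: dict = {
            "client_id": client_id,
            "org_id": bl.org_id,
            "country": bl.country,
            "status": status,
            "facility_per_diem_key": (
                m6.facility_per_diem_key if m6 is not None else None
            )
            or bl.facility_per_diem_key,
            "age": bl.age,
            "sex": 1 if bl.sex == "female" else 0,
            "living_alone": int(bl.living_alone),
            "cps": bl.cps,
            "drs": bl.drs,
            "adlh": bl.adlh,
            "iadl": bl.iadl,
            "chess": bl.chess,
            "caregiver_distress": int(bl.caregiver_distress),
        }
        bl_costs = value_wave(bl, prices, config.quarter_days)
        for cat in CATEGORIES:
            row[f"{cat}_bl"] = bl_costs[cat]
        if status == "in_care" and m6 is not None:
            m6_costs = value_wave(m6, prices, config.quarter_days)
        else:
            m6_costs = {cat: float("nan") for cat in CATEGORIES}
        for cat in CATEGORIES:
            row[f"{cat}_m6"] = m6_costs[cat]
        rows.append(row)
    return pd.DataFrame(rows)


def rule_mask(frame: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask over wave-cost columns of cells determined by transition rule.

    Those cells are NaN in the wave table but must be excluded from
    imputation: :func:`complete_six_month` fills them from the baseline
    carry-forward and the facility per-diem.
    """
    mask = pd.DataFrame(
        False, index=frame.index, columns=wave_cost_columns()
    )
    is_rule = frame["status"].isin(RULE_STATUSES).to_numpy()
    for cat in CATEGORIES:
        mask.loc[is_rule, f"{cat}_m6"] = True
    return mask


def complete_six_month(
    frame: pd.DataFrame,
    prices: PriceTable,
    config: RunConfig | None = None,
    allow_missing: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Apply transition rules and the 0.5/1.5 interpolation to a completed table.

    Expects all non-rule wave-cost cells to be observed or imputed; a
    remaining NaN in any category outside ``allow_missing`` is an error (it
    means imputation was skipped).  Returns the input columns plus per-category
    6-month costs, ``total_societal_6m`` and ``total_healthcare_6m``.
    """
    config = config or RunConfig()
    w1, w2 = config.interpolation_weights
    out = frame.copy()
    status = out["status"].to_numpy()
    is_rule = np.isin(status, RULE_STATUSES)

    # Fill rule-determined month-6 cells via apply_transition_rules.
    for idx in np.flatnonzero(is_rule):
        row = out.iloc[idx]
        carry = {cat: row[f"{cat}_bl"] for cat in COMMUNITY_CATEGORIES}
        per_diem = None
        key = row["facility_per_diem_key"]
        if isinstance(key, str) and key:
            if key not in prices.facility_per_diem:
                raise CostingError(f"no per-diem configured for facility {key!r}")
            per_diem = prices.facility_per_diem[key]
        adjusted = apply_transition_rules(
            carry,
            row["status"],
            per_diem,
            config.quarter_days,
            config.interpolation_weights,
        )
        for cat in CATEGORIES:
            out.iloc[idx, out.columns.get_loc(f"{cat}_m6")] = adjusted[cat]

    for cat in CATEGORIES:
        bl = out[f"{cat}_bl"].to_numpy(dtype=float)
        m6 = out[f"{cat}_m6"].to_numpy(dtype=float)
        if cat not in allow_missing:
            bad = np.isnan(bl) | np.isnan(m6)
            if bad.any():
                raise CostingError(
                    f"{cat}: {int(bad.sum())} client(s) with missing quarterly "
                    "cost — impute before computing 6-month totals"
                )
        out[f"{cat}_6m"] = w1 * bl + w2 * m6

    # Conservation identities: healthcare = sum of the six non-informal
    # categories (in declared order), societal = healthcare + informal care.
    # Summing healthcare first keeps it computable when informal care was not
    # assessed (healthcare-perspective runs with a recorded-days country).
    non_informal = [c for c in CATEGORIES if c != "informal_care"]
    out["total_healthcare_6m"] = sum(out[f"{c}_6m"] for c in non_informal)
    out["total_societal_6m"] = out["total_healthcare_6m"] + out["informal_care_6m"]
    return out


def aggregate(
    completed: pd.DataFrame,
    perspective: str = "societal",
    group_col: str = "model",
) -> pd.DataFrame:
    """Per-group mean disaggregated 6-month costs, totals, shares and ratio.

    The healthcare perspective excludes the informal-care category from
    totals and shares.  The home-care vs informal-care balance is reported as
    the ratio informal/home-care.  Empty groups cannot occur (groupby drops
    them); groups are returned sorted by name.
    """
    if perspective not in ("societal", "healthcare"):
        raise ValueError(f"unknown perspective {perspective!r}")
    cats = [
        c
        for c in CATEGORIES
        if not (perspective == "healthcare" and c == "informal_care")
    ]
    total_col = (
        "total_societal_6m" if perspective == "societal" else "total_healthcare_6m"
    )
    rows = []
    for group, sub in completed.groupby(group_col, sort=True):
        n = len(sub)
        row: dict = {group_col: group, "n": n}
        total_mean = sub[total_col].mean()
        for cat in cats:
            mean = sub[f"{cat}_6m"].mean()
            row[f"{cat}_mean"] = mean
            row[f"{cat}_se"] = sub[f"{cat}_6m"].std(ddof=1) / math.sqrt(n) if n > 1 else float("nan")
            row[f"{cat}_share_pct"] = (
                100.0 * mean / total_mean if total_mean else float("nan")
            )
        row["total_mean"] = total_mean
        row["total_se"] = (
            sub[total_col].std(ddof=1) / math.sqrt(n) if n > 1 else float("nan")
        )
        home = row.get("home_care_mean", float("nan"))
        informal = (
            row.get("informal_care_mean", float("nan"))
            if perspective == "societal"
            else float("nan")
        )
        row["informal_to_home_care_ratio"] = (
            informal / home if home else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows)
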