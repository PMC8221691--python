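"""Tabular I/O and the validated data model for home-care cost benchmarking.

The analysis consumes three kinds of input:

* a *cohort table* — one row per client per assessment wave, carrying
  demographics, interRAI-HC scale scores, resource-utilization items with
  item-specific recall periods, and a follow-up status flag;
* an *organization table* — questionnaire item scores used to classify each
  home-care organization into a care model (see :mod:`carebench.care_models`);
* a *price table* — standard unit costs per resource item, an informal-care
  wage rate, facility per-diems, and country-level mean hospital lengths of
  stay.

All files are UTF-8 comma-separated text with "." as the decimal separator and
an empty cell denoting a missing value.  Scale scores are ordinal and stored as
integers; non-integer input is rejected rather than rounded.  Currency is a
label only — no exchange-rate conversion is performed, because the whole point
of uniform standard costs is that cost differences between care models reflect
utilization, not national price levels.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CATEGORIES",
    "ITEM_RECALL",
    "ITEM_CATEGORY",
    "CASE_MIX_COVARIATES",
    "ResourceUseItem",
    "ClientWaveRecord",
    "PriceTable",
    "RunConfig",
    "CohortValidationError",
    "PriceTableError",
    "load_cohort",
    "write_cohort",
    "cohort_to_frame",
    "load_price_tables",
    "load_run_config",
    "default_price_table",
]


# --------------------------------------------------------------------------
# Item registry
# --------------------------------------------------------------------------

#: Recall period in days for each resource-utilization item.  Hospitalization,
#: emergency-room and physician items use a 90-day recall; regular home-care
#: and therapist items a 7-day recall; informal care a 3-day recall.
#: Supportive-service and other-healthcare units are event-like and use the
#: 90-day recall.
ITEM_RECALL: Mapping[str, int] = {
    "hosp_events": 90,
    "hosp_days": 90,
    "er_visits": 90,
    "physician_visits": 90,
    "supportive_units": 90,
    "other_hc_units": 90,
    "home_care_min": 7,
    "therapist_min": 7,
    "informal_care_min": 3,
}

#: The seven cost categories.  ``institutional`` accrues only through the
#: post-institutionalization per-diem rule, never through a resource item.
CATEGORIES: tuple[str, ...] = (
    "hospital",
    "visits",
    "other_healthcare",
    "supportive",
    "institutional",
    "home_care",
    "informal_care",
)

#: Cost category each item is valued into.  Therapist minutes are costed
#: within the home-care category (shared 7-day recall); emergency and
#: physician visits are pooled into one visit category.
ITEM_CATEGORY: Mapping[str, str] = {
    "hosp_events": "hospital",
    "hosp_days": "hospital",
    "er_visits": "visits",
    "physician_visits": "visits",
    "supportive_units": "supportive",
    "other_hc_units": "other_healthcare",
    "home_care_min": "home_care",
    "therapist_min": "home_care",
    "informal_care_min": "informal_care",
}

ITEM_KEYS: tuple[str, ...] = tuple(ITEM_RECALL)

#: The eight case-mix adjustment covariates.
CASE_MIX_COVARIATES: tuple[str, ...] = (
    "age",
    "sex",
    "living_alone",
    "cps",
    "drs",
    "adlh",
    "iadl",
    "chess",
)

SCALE_BOUNDS: Mapping[str, tuple[int, int]] = {
    "cps": (0, 6),
    "drs": (0, 14),
    "adlh": (0, 6),
    "iadl": (0, 48),
    "chess": (0, 5),
}

WAVES = ("baseline", "month6")
SEXES = ("female", "male")
STATUSES = ("in_care", "institutionalized", "deceased", "discharged", "lost")


class CohortValidationError(ValueError):
    """A cohort row violates the data model."""


class PriceTableError(ValueError):
    """A price table is incomplete or carries invalid values."""


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------


@dataclass
class ResourceUseItem:
    """One resource-utilization item: a quantity observed over a recall window.

    ``quantity`` is ``None`` when the item was not assessed (missing), which is
    preserved as missing — never coerced to zero — so that imputation can act
    on it downstream.
    """

    item_key: str
    quantity: float | None
    recall_days: int

    def __post_init__(self) -> None:
        if self.item_key not in ITEM_RECALL:
            raise CohortValidationError(f"unknown resource item {self.item_key!r}")
        expected = ITEM_RECALL[self.item_key]
        if self.recall_days != expected:
            raise CohortValidationError(
                f"{self.item_key}: recall_days must be {expected}, got {self.recall_days}"
            )
        if self.quantity is not None and not self.quantity >= 0:
            raise CohortValidationError(
                f"{self.item_key}: quantity must be missing or >= 0, got {self.quantity}"
            )


@dataclass
class ClientWaveRecord:
    """One client at one assessment wave."""

    client_id: str
    org_id: str
    country: str
    wave: str
    age: int
    sex: str
    living_alone: bool
    cps: int
    drs: int
    adlh: int
    iadl: int
    chess: int
    caregiver_distress: bool
    status: str
    resource_items: list[ResourceUseItem] = field(default_factory=list)
    facility_per_diem_key: str | None = None

    def __post_init__(self) -> None:
        if self.wave not in WAVES:
            raise CohortValidationError(f"wave must be one of {WAVES}, got {self.wave!r}")
        if self.sex not in SEXES:
            raise CohortValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.status not in STATUSES:
            raise CohortValidationError(
                f"status must be one of {STATUSES}, got {self.status!r}"
            )
        for name, (lo, hi) in SCALE_BOUNDS.items():
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)):
                raise CohortValidationError(f"{name} must be an integer, got {value!r}")
            if not lo <= value <= hi:
                raise CohortValidationError(f"{name} out of range [{lo},{hi}]: {value}")
        if not self.age >= 65:
            raise CohortValidationError(f"age must be >= 65, got {self.age}")

    def quantity(self, item_key: str) -> float | None:
        for item in self.resource_items:
            if item.item_key == item_key:
                return item.quantity
        return None


# --------------------------------------------------------------------------
# Price table
# --------------------------------------------------------------------------

#: Unit-cost keys every price table must declare.  Hospital nights are priced
#: per night; minute-denominated items are priced per hour.
REQUIRED_PRICE_KEYS: tuple[str, ...] = (
    "hospital_night",
    "er_visit",
    "physician_visit",
    "supportive_unit",
    "other_hc_unit",
    "home_care_hour",
    "therapist_hour",
)


@dataclass(frozen=True)
class PriceTable:
    """Standard unit costs used to value resource utilization.

    ``hospital_los`` maps country code to the mean number of hospital nights
    per admission; the one ``recorded_days_country`` (where the instrument
    registers admission days directly) needs no entry.
    """

    name: str
    unit_costs: Mapping[str, float]
    informal_care_wage: float
    facility_per_diem: Mapping[str, float]
    hospital_los: Mapping[str, float]
    recorded_days_country: str | None = None
    currency: str = "EUR"
    year: int | None = None

    def __post_init__(self) -> None:
        for key in REQUIRED_PRICE_KEYS:
            if key not in self.unit_costs:
                raise PriceTableError(f"price table {self.name!r}: missing price for {key!r}")
        for key, value in self.unit_costs.items():
            if not value >= 0:
                raise PriceTableError(f"price table {self.name!r}: {key} must be >= 0")
        if not self.informal_care_wage >= 0:
            raise PriceTableError(
                f"price table {self.name!r}: informal_care_wage must be >= 0"
            )
        for key, value in self.facility_per_diem.items():
            if not value >= 0:
                raise PriceTableError(
                    f"price table {self.name!r}: per-diem {key!r} must be >= 0"
                )
        for key, value in self.hospital_los.items():
            if not value >= 0:
                raise PriceTableError(f"price table {self.name!r}: LOS {key!r} must be >= 0")

    def scaled(self, k: float, name: str | None = None) -> "PriceTable":
        """Return a copy with every monetary entry multiplied by ``k``."""
        if k < 0:
            raise PriceTableError("scale factor must be >= 0")
        return dataclasses.replace(
            self,
            name=name or f"{self.name}_x{k:g}",
            unit_costs={key: v * k for key, v in self.unit_costs.items()},
            informal_care_wage=self.informal_care_wage * k,
            facility_per_diem={key: v * k for key, v in self.facility_per_diem.items()},
        )


def default_price_table() -> PriceTable:
    """An illustrative reference price set.

    The values are synthetic stand-ins on the scale of published Dutch
    standard-cost manuals; the study's actual unit-cost table is not available
    here, so prices are a configuration input, never hard-coded fact.
    """
    return PriceTable(
        name="reference",
        currency="EUR",
        year=2014,
        unit_costs={
            "hospital_night": 480.0,
            "er_visit": 260.0,
            "physician_visit": 33.0,
            "supportive_unit": 25.0,
            "other_hc_unit": 40.0,
            "home_care_hour": 50.0,
            "therapist_hour": 38.0,
        },
        informal_care_wage=14.0,
        facility_per_diem={
            "nursing_home": 170.0,
            "hospital": 480.0,
            "rehabilitation": 230.0,
        },
        hospital_los={"NL": 6.1, "IT": 7.8, "IS": 5.9, "FI": 7.0, "DE": 9.2},
        recorded_days_country="BE",
    )


def _price_table_from_mapping(doc: Mapping) -> PriceTable:
    try:
        return PriceTable(
            name=str(doc["name"]),
            unit_costs={str(k): float(v) for k, v in dict(doc["unit_costs"]).items()},
            informal_care_wage=float(doc["informal_care_wage"]),
            facility_per_diem={
                str(k): float(v) for k, v in dict(doc.get("facility_per_diem", {})).items()
            },
            hospital_los={
                str(k): float(v) for k, v in dict(doc.get("hospital_los", {})).items()
            },
            recorded_days_country=doc.get("recorded_days_country"),
            currency=str(doc.get("currency", "EUR")),
            year=doc.get("year"),
        )
    except KeyError as exc:
        raise PriceTableError(f"price table: missing required field {exc.args[0]!r}") from exc


def load_price_tables(path) -> dict[str, PriceTable]:
    """Load one or more named price tables from a YAML file.

    The file holds either a single table mapping, a list of them, or a mapping
    with a ``price_tables`` list.  Two named tables (e.g. reference and
    alternate) may coexist for the price-swap sensitivity analysis; they are
    returned as a registry keyed by name.
    """
    with open(path, "r", encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if isinstance(doc, Mapping) and "price_tables" in doc:
        docs = doc["price_tables"]
    elif isinstance(doc, Mapping):
        docs = [doc]
    else:
        docs = list(doc)
    registry: dict[str, PriceTable] = {}
    for entry in docs:
        table = _price_table_from_mapping(entry)
        if table.name in registry:
            raise PriceTableError(f"duplicate price table name {table.name!r}")
        registry[table.name] = table
    return registry


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Analysis constants.

    ``interpolation_weights`` are the (baseline, month-6) multipliers applied
    to quarterly costs when forming the 6-month total; they must sum to 2
    because the window spans two quarters.  ``covariate_priority`` orders the
    case-mix covariates for the collinearity screen: when a pair is flagged,
    the member appearing *later* in this list is dropped.
    """

    perspective: str = "societal"
    n_imputations: int = 10
    n_bootstrap: int = 5000
    alpha: float = 0.05
    collinearity_cutoff: float = 0.4
    quarter_days: int = 91
    interpolation_weights: tuple[float, float] = (0.5, 1.5)
    rng_seed: int = 0
    price_table: str = "reference"
    covariate_priority: tuple[str, ...] = CASE_MIX_COVARIATES

    def __post_init__(self) -> None:
        if self.perspective not in ("societal", "healthcare"):
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        w1, w2 = self.interpolation_weights
        if not math.isclose(w1 + w2, 2.0):
            raise ValueError("interpolation weights must sum to 2 (two quarters)")
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


def load_run_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as handle:
        doc = yaml.safe_load(handle) or {}
    if "interpolation_weights" in doc:
        doc["interpolation_weights"] = tuple(doc["interpolation_weights"])
    if "covariate_priority" in doc:
        doc["covariate_priority"] = tuple(doc["covariate_priority"])
    return RunConfig(**doc)


# --------------------------------------------------------------------------
# Cohort I/O
# --------------------------------------------------------------------------

_BASE_COLUMNS = (
    "client_id",
    "org_id",
    "country",
    "wave",
    "age",
    "sex",
    "living_alone",
    "cps",
    "drs",
    "adlh",
    "iadl",
    "chess",
    "caregiver_distress",
    "status",
    "facility_per_diem_key",
)

COHORT_COLUMNS: tuple[str, ...] = _BASE_COLUMNS + ITEM_KEYS


def _parse_int(value, row: int, name: str) -> int:
    number = float(value)
    if not float(number).is_integer():
        raise CohortValidationError(
            f"row {row}: {name} must be an integer, got {value!r}"
        )
    return int(number)


def _parse_bool(value, row: int, name: str) -> bool:
    text = str(value).strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no"):
        return False
    raise CohortValidationError(f"row {row}: {name} must be boolean, got {value!r}")


def load_cohort(path, config: RunConfig | None = None) -> list[ClientWaveRecord]:
    """Read and validate a cohort table.

    Every input row either yields a record satisfying all data-model
    invariants or a :class:`CohortValidationError` naming the violated
    invariant and the offending row.  Missing quantities (empty cells) are
    preserved as missing, not zero.  A client may have at most one record per
    wave.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortValidationError(f"cohort file missing columns: {missing_cols}")
    records: list[ClientWaveRecord] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(frame.itertuples(index=False)):
        data = dict(zip(frame.columns, row))
        try:
            items = []
            for key in ITEM_KEYS:
                cell = data[key].strip()
                quantity = None if cell == "" else float(cell)
                items.append(ResourceUseItem(key, quantity, ITEM_RECALL[key]))
            facility = data["facility_per_diem_key"].strip() or None
            record = ClientWaveRecord(
                client_id=data["client_id"],
                org_id=data["org_id"],
                country=data["country"],
                wave=data["wave"],
                age=_parse_int(data["age"], idx, "age"),
                sex=data["sex"],
                living_alone=_parse_bool(data["living_alone"], idx, "living_alone"),
                cps=_parse_int(data["cps"], idx, "cps"),
                drs=_parse_int(data["drs"], idx, "drs"),
                adlh=_parse_int(data["adlh"], idx, "adlh"),
                iadl=_parse_int(data["iadl"], idx, "iadl"),
                chess=_parse_int(data["chess"], idx, "chess"),
                caregiver_distress=_parse_bool(
                    data["caregiver_distress"], idx, "caregiver_distress"
                ),
                status=data["status"],
                resource_items=items,
                facility_per_diem_key=facility,
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"row {idx}: {exc}") from None
        except ValueError as exc:
            raise CohortValidationError(f"row {idx}: malformed value ({exc})") from None
        key = (record.client_id, record.wave)
        if key in seen:
            raise CohortValidationError(
                f"row {idx}: duplicate record for client {record.client_id!r} "
                f"wave {record.wave!r}"
            )
        seen.add(key)
        records.append(record)
    return records


def cohort_to_frame(records: Iterable[ClientWaveRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {
            "client_id": rec.client_id,
            "org_id": rec.org_id,
            "country": rec.country,
            "wave": rec.wave,
            "age": rec.age,
            "sex": rec.sex,
            "living_alone": int(rec.living_alone),
            "cps": rec.cps,
            "drs": rec.drs,
            "adlh": rec.adlh,
            "iadl": rec.iadl,
            "chess": rec.chess,
            "caregiver_distress": int(rec.caregiver_distress),
            "status": rec.status,
            "facility_per_diem_key": rec.facility_per_diem_key or "",
        }
        quantities = {item.item_key: item.quantity for item in rec.resource_items}
        for key in ITEM_KEYS:
            value = quantities.get(key)
            row[key] = "" if value is None else repr(float(value))
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(records: Sequence[ClientWaveRecord], path) -> None:
    """Write a cohort table; round-trips through :func:`load_cohort` exactly.

    Quantities are serialized with :func:`repr` so float values survive the
    round trip bit-exactly.
    """
    cohort_to_frame(records).to_csv(path, index=False)
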