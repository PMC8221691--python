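"""Shared fixtures: record factories, price tables, and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from carebench import (
    ClientWaveRecord,
    PriceTable,
    ResourceUseItem,
    RunConfig,
    SimulationScenario,
    default_price_table,
    generate_cohort,
)
from carebench.data_io import ITEM_RECALL


@pytest.fixture
def prices() -> PriceTable:
    return default_price_table()


@pytest.fixture
def config() -> RunConfig:
    return RunConfig(n_bootstrap=200, n_imputations=3, rng_seed=11)


def make_items(**quantities) -> list[ResourceUseItem]:
    """Resource items with the given quantities; everything else zero."""
    items = []
    for key, recall in ITEM_RECALL.items():
        if key in quantities:
            q = quantities[key]
        elif key == "hosp_days":
            q = None  # only the recorded-days country registers days
        else:
            q = 0.0
        items.append(ResourceUseItem(key, q, recall))
    return items


def make_record(
    client_id: str = "C1",
    wave: str = "baseline",
    status: str = "in_care",
    country: str = "NL",
    items: list[ResourceUseItem] | None = None,
    **overrides,
) -> ClientWaveRecord:
    fields = dict(
        client_id=client_id,
        org_id="O1",
        country=country,
        wave=wave,
        age=80,
        sex="female",
        living_alone=True,
        cps=2,
        drs=1,
        adlh=3,
        iadl=20,
        chess=1,
        caregiver_distress=False,
        status=status,
        resource_items=items if items is not None else make_items(),
    )
    fields.update(overrides)
    return ClientWaveRecord(**fields)


@pytest.fixture(scope="session")
def small_scenario() -> SimulationScenario:
    """Two orgs per model, 40 clients each; defaults otherwise."""
    return SimulationScenario(
        n_orgs_per_model={"CM1": 2, "CM2": 2, "CM3": 2},
        n_clients_per_org=40,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    """(records, org_frame, truth) for a 240-client cohort."""
    return generate_cohort(small_scenario)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
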