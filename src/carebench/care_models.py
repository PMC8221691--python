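"""Care-model classification of home-care organizations.

Organizations are scored on three core elements of care delivery — the level
of patient-centred care (PCC, 6 questionnaire items), the availability of
specialized care professionals (ASP, 5 items), and the level of monitoring of
care performance (MCP, 4 items).  Each element score is the arithmetic mean of
its items; higher scores indicate a higher focus on that element.
Dichotomizing each element at a threshold yields a high/low pattern that maps
to one of six care models:

======  ====  ====  ====
model    PCC   ASP   MCP
======  ====  ====  ====
CM1      H     H     H
CM2      H     L     H
CM3      L     L     H
CM4      H     H     L
CM5      L     H     any   (residual rule)
CM6      L/H   L     L     (residual rule: remaining patterns)
======  ====  ====  ====

The four patterns CM1–CM4 are fixed by the model definitions; the residual
patterns (low PCC with high ASP, and the remaining low-MCP patterns) are
assigned to CM5/CM6 by the documented rule above and flagged, mirroring the
exclusion of those models from analysis.  The exact item wording and the
original classification rule live in the instrument-development literature;
the midpoint threshold used here is a declared, configurable stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "N_PCC_ITEMS",
    "N_ASP_ITEMS",
    "N_MCP_ITEMS",
    "OrganizationProfile",
    "ElementScores",
    "CareModelAssignment",
    "score_elements",
    "classify",
    "classify_organizations",
    "organizations_from_frame",
]

N_PCC_ITEMS = 6
N_ASP_ITEMS = 5
N_MCP_ITEMS = 4

ELEMENTS = ("pcc", "asp", "mcp")

#: (PCC, ASP, MCP) high/low pattern -> care model.  True = high.
PATTERN_TO_MODEL: Mapping[tuple[bool, bool, bool], str] = {
    (True, True, True): "CM1",
    (True, False, True): "CM2",
    (False, False, True): "CM3",
    (True, True, False): "CM4",
    (False, True, True): "CM5",
    (False, True, False): "CM5",
    (False, False, False): "CM6",
    (True, False, False): "CM6",
}

#: Models outside the four analyzable patterns; assignments are flagged.
RESIDUAL_MODELS = frozenset({"CM5", "CM6"})


@dataclass(frozen=True)
class OrganizationProfile:
    """Questionnaire item scores for one organization.

    Items are ordinal 0..``scale_max``.  Exactly 6 PCC, 5 ASP, and 4 MCP item
    slots must be filled; a missing item is an error — there is no implicit
    imputation policy for partial profiles.
    """

    org_id: str
    pcc_items: tuple[float, ...]
    asp_items: tuple[float, ...]
    mcp_items: tuple[float, ...]
    scale_max: float = 4.0

    def __post_init__(self) -> None:
        for name, items, expected in (
            ("pcc_items", self.pcc_items, N_PCC_ITEMS),
            ("asp_items", self.asp_items, N_ASP_ITEMS),
            ("mcp_items", self.mcp_items, N_MCP_ITEMS),
        ):
            if len(items) != expected:
                raise ValueError(
                    f"org {self.org_id!r}: {name} must have {expected} items, "
                    f"got {len(items)}"
                )
            for value in items:
                if value is None:
                    raise ValueError(
                        f"org {self.org_id!r}: missing item score in {name} "
                        "(no imputation policy for partial profiles)"
                    )
                if not 0 <= value <= self.scale_max:
                    raise ValueError(
                        f"org {self.org_id!r}: {name} score {value} outside "
                        f"[0, {self.scale_max}]"
                    )


@dataclass(frozen=True)
class ElementScores:
    """Mean item scores on the three core elements for one organization."""

    org_id: str
    pcc: float
    asp: float
    mcp: float
    scale_max: float = 4.0


@dataclass(frozen=True)
class CareModelAssignment:
    org_id: str
    model: str
    element_levels: Mapping[str, str]
    #: True for the residual CM5/CM6 patterns excluded from analysis.
    flagged: bool = False


def score_elements(profile: OrganizationProfile) -> ElementScores:
    """Arithmetic mean of the item scores within each element."""
    return ElementScores(
        org_id=profile.org_id,
        pcc=sum(profile.pcc_items) / N_PCC_ITEMS,
        asp=sum(profile.asp_items) / N_ASP_ITEMS,
        mcp=sum(profile.mcp_items) / N_MCP_ITEMS,
        scale_max=profile.scale_max,
    )


def classify(
    scores: ElementScores,
    thresholds: Mapping[str, float] | None = None,
) -> CareModelAssignment:
    """Assign a care model from the element-score high/low pattern.

    Each element is "high" when its score is at or above the threshold (ties
    count as high — a fixed, documented tie-break).  By default every
    threshold is the scale midpoint ``scale_max / 2``; the original
    dichotomization rule is not available, so the cutoffs are configurable per
    element.  The function is total and deterministic: the four in-analysis
    patterns always map to CM1–CM4 regardless of thresholds, and the residual
    patterns map to CM5/CM6 and are flagged.
    """
    midpoint = scores.scale_max / 2.0
    cuts = {e: midpoint for e in ELEMENTS}
    if thresholds:
        for element, value in thresholds.items():
            if element not in ELEMENTS:
                raise ValueError(f"unknown element {element!r}")
            if not 0 <= value <= scores.scale_max:
                raise ValueError(
                    f"threshold for {element} must lie within [0, {scores.scale_max}]"
                )
            cuts[element] = value
    pattern = tuple(getattr(scores, e) >= cuts[e] for e in ELEMENTS)
    model = PATTERN_TO_MODEL[pattern]
    levels = {e: ("high" if high else "low") for e, high in zip(ELEMENTS, pattern)}
    return CareModelAssignment(
        org_id=scores.org_id,
        model=model,
        element_levels=levels,
        flagged=model in RESIDUAL_MODELS,
    )


# --------------------------------------------------------------------------
# Table-level helpers
# --------------------------------------------------------------------------

ORG_ITEM_COLUMNS: tuple[str, ...] = tuple(
    [f"pcc_{i}" for i in range(1, N_PCC_ITEMS + 1)]
    + [f"asp_{i}" for i in range(1, N_ASP_ITEMS + 1)]
    + [f"mcp_{i}" for i in range(1, N_MCP_ITEMS + 1)]
)


def organizations_from_frame(
    frame: pd.DataFrame, scale_max: float = 4.0
) -> list[OrganizationProfile]:
    missing = [c for c in ("org_id",) + ORG_ITEM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"organization table missing columns: {missing}")
    profiles = []
    for _, row in frame.iterrows():
        profiles.append(
            OrganizationProfile(
                org_id=str(row["org_id"]),
                pcc_items=tuple(
                    float(row[f"pcc_{i}"]) for i in range(1, N_PCC_ITEMS + 1)
                ),
                asp_items=tuple(
                    float(row[f"asp_{i}"]) for i in range(1, N_ASP_ITEMS + 1)
                ),
                mcp_items=tuple(
                    float(row[f"mcp_{i}"]) for i in range(1, N_MCP_ITEMS + 1)
                ),
                scale_max=scale_max,
            )
        )
    return profiles


def classify_organizations(
    org_frame: pd.DataFrame,
    scale_max: float = 4.0,
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Classify every organization in a table; returns an assignment table."""
    rows = []
    for profile in organizations_from_frame(org_frame, scale_max=scale_max):
        scores = score_elements(profile)
        assignment = classify(scores, thresholds=thresholds)
        rows.append(
            {
                "org_id": assignment.org_id,
                "pcc": scores.pcc,
                "asp": scores.asp,
                "mcp": scores.mcp,
                "pcc_level": assignment.element_levels["pcc"],
                "asp_level": assignment.element_levels["asp"],
                "mcp_level": assignment.element_levels["mcp"],
                "model": assignment.model,
                "flagged": assignment.flagged,
            }
        )
    return pd.DataFrame(rows)
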