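"""Crop codes, crop groups and agricultural land-cover classes.

Emissions are modelled independently within six agricultural land-cover
classes.  Crop extents are reported against EUROSTAT-style crop codes;
for modelling, related crops are pooled into a single area predictor
(a *crop group*) under the assumption that an active substance is applied
at a similar dose to every crop in the group.  The default inventory below
pools 44 crop codes into 16 groups, each group belonging to exactly one
land-cover class.
"""

from __future__ import annotations

from typing import Iterable, Mapping

ARABLE = "arable land"
FRUIT_TREE = "fruit tree"
GRASSLAND = "grassland"
OLIVE = "olive groves"
VINEYARD = "vineyards"
RICE = "rice fields"

#: The six agricultural land-cover classes within which use is modelled.
LAND_COVER_CLASSES: tuple[str, ...] = (
    ARABLE,
    FRUIT_TREE,
    GRASSLAND,
    OLIVE,
    VINEYARD,
    RICE,
)

#: Crop group -> land-cover class.  Ten groups fall on arable land, two on
#: fruit-tree plantations and one each on the remaining four classes.
GROUP_TO_CLASS: dict[str, str] = {
    "C0000": ARABLE,      # cereal grain
    "G0000": ARABLE,      # plants harvested green
    "I0000": ARABLE,      # industrial crops
    "P0000": ARABLE,      # dry pulses and protein crops
    "Q0000": ARABLE,      # fallow land
    "R0000": ARABLE,      # root crops
    "V_S0000": ARABLE,    # fresh vegetables and strawberries
    "E0000": ARABLE,      # seeds and seedlings
    "L0000": ARABLE,      # nurseries
    "OTHER_ARA": ARABLE,  # ornamental plants and kitchen gardens
    "F0000": FRUIT_TREE,  # fruits, berries and nuts
    "T0000": FRUIT_TREE,  # citrus fruits
    "J0000": GRASSLAND,   # permanent grassland
    "O1000": OLIVE,       # olives
    "W1000": VINEYARD,    # grapes
    "C2000": RICE,        # rice
}

#: The sixteen default crop-group predictors, in a stable order.
CROP_GROUPS: tuple[str, ...] = tuple(GROUP_TO_CLASS)

#: Default crop code -> crop group mapping (44 codes -> 16 groups).
DEFAULT_CROP_GROUPING: dict[str, str] = {
    # cereal grain
    "C1110": "C0000", "C1120": "C0000", "C1300": "C0000", "C1400": "C0000",
    "C1500": "C0000", "C1600": "C0000", "C1700": "C0000",
    # plants harvested green
    "G1000": "G0000", "G2000": "G0000", "G3000": "G0000",
    # industrial crops
    "I1100": "I0000", "I1200": "I0000", "I1300": "I0000", "I1400": "I0000",
    "I5000": "I0000",
    # dry pulses and protein crops
    "P1000": "P0000", "P2000": "P0000",
    # fallow land
    "Q1000": "Q0000",
    # root crops
    "R1000": "R0000", "R2000": "R0000", "R9000": "R0000",
    # fresh vegetables and strawberries
    "V1000": "V_S0000", "V2000": "V_S0000", "V3000": "V_S0000",
    "S0000": "V_S0000",
    # seeds and seedlings
    "E1000": "E0000",
    # nurseries
    "L1000": "L0000",
    # ornamental plants and kitchen gardens
    "N0000": "OTHER_ARA", "K0000": "OTHER_ARA",
    # fruits, berries and nuts
    "F1100": "F0000", "F1200": "F0000", "F2000": "F0000", "F3000": "F0000",
    "F4000": "F0000", "F5000": "F0000",
    # citrus fruits
    "T1000": "T0000", "T2000": "T0000",
    # permanent grassland
    "J1000": "J0000", "J2000": "J0000",
    # olives
    "O1100": "O1000", "O1900": "O1000",
    # grapes
    "W1100": "W1000", "W1900": "W1000",
    # rice
    "C2100": "C2000",
}

#: All 44 default crop codes, in a stable order.
DEFAULT_CROP_CODES: tuple[str, ...] = tuple(DEFAULT_CROP_GROUPING)


def class_of_group(group: str, group_to_class: Mapping[str, str] | None = None) -> str:
    """Land-cover class of a crop group."""
    mapping = GROUP_TO_CLASS if group_to_class is None else group_to_class
    try:
        return mapping[group]
    except KeyError:
        raise KeyError(f"crop group {group!r} has no land-cover class") from None


def class_of_crop(
    crop: str,
    grouping: Mapping[str, str] | None = None,
    group_to_class: Mapping[str, str] | None = None,
) -> str:
    """Land-cover class of a crop code, via its group."""
    g = DEFAULT_CROP_GROUPING if grouping is None else grouping
    try:
        group = g[crop]
    except KeyError:
        raise KeyError(f"crop code {crop!r} is not in the grouping") from None
    return class_of_group(group, group_to_class)


def groups_of_crops(
    crops: Iterable[str], grouping: Mapping[str, str] | None = None
) -> tuple[str, ...]:
    """Distinct crop groups covering *crops*, in first-appearance order."""
    g = DEFAULT_CROP_GROUPING if grouping is None else grouping
    seen: dict[str, None] = {}
    for c in crops:
        seen.setdefault(g[c], None)
    return tuple(seen)
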