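"""Apportionment of reported use to regions and land-cover classes.

A reported amount at country or province scope is split across the regions
of that scope proportionally to the *weighted applicable crop area* of each
region: the sum over the crops the report covers of the substance's
relative dose weight for the crop's group times the crop's area.  The
regional amount is then split across the six land-cover classes with the
same dose-weighted-area logic.  Every step conserves mass exactly.

Calibration uses the reported-coverage crop areas; extrapolation later
uses total areas — the ``area_variant`` switch selects between the two
crop-extent datasets.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import landcover
from .datatypes import RegionTable, SubstanceProfile

logger = logging.getLogger(__name__)


def _covered_crops(
    profile: SubstanceProfile, crops: Iterable[str] | None
) -> list[str]:
    if crops is None:
        return list(profile.crops)
    crop_set = set(crops)
    return [c for c in profile.crops if c in crop_set]


def applicable_weight(
    areas: pd.Series,
    profile: SubstanceProfile,
    grouping: Mapping[str, str] | None = None,
    crops: Iterable[str] | None = None,
) -> float:
    """Dose-weighted applicable hectares of one region.

    ``areas`` maps crop code -> hectares for the region.  With uniform dose
    weights this reduces to the plain applicable area.  ``crops``
    optionally restricts to the crop codes a report covers.
    """
    grouping = landcover.DEFAULT_CROP_GROUPING if grouping is None else grouping
    total = 0.0
    for crop in _covered_crops(profile, crops):
        if crop in areas.index:
            total += profile.weight_of_group(grouping[crop]) * float(areas[crop])
    return total


def _weights_by_region(
    area_table: pd.DataFrame,
    profile: SubstanceProfile,
    grouping: Mapping[str, str],
    crops: Iterable[str] | None,
) -> pd.Series:
    cols = [c for c in _covered_crops(profile, crops) if c in area_table.columns]
    if not cols:
        return pd.Series(0.0, index=area_table.index)
    w = np.array([profile.weight_of_group(grouping[c]) for c in cols])
    return pd.Series(area_table[cols].to_numpy(dtype=float) @ w, index=area_table.index)


def disaggregate(
    report: Mapping,
    regions: RegionTable,
    profile: SubstanceProfile,
    grouping: Mapping[str, str] | None = None,
    *,
    area_variant: str = "reported",
) -> pd.Series:
    """Apportion one reported amount to the regions of its scope.

    ``report`` needs keys ``scope``, ``kg`` and optionally ``crops`` (a
    ';'-joined restriction of covered crop codes).  Returns kg per region;
    the regional amounts sum to the reported amount exactly.  If every
    region in scope has zero applicable weight the amount is spread
    uniformly and a warning is emitted (the amount is kept, for audit).
    """
    grouping = landcover.DEFAULT_CROP_GROUPING if grouping is None else grouping
    scope = report["scope"]
    ids = regions.regions_of(scope)
    if len(ids) == 0:
        raise ValueError(f"scope {scope!r} resolves to no region")
    crops_field = report.get("crops", "") if hasattr(report, "get") else report["crops"]
    crops = [c for c in str(crops_field or "").split(";") if c] or None

    areas = regions.areas(area_variant).loc[ids]
    w = _weights_by_region(areas, profile, grouping, crops)
    amount = float(report["kg"])
    total = float(w.sum())
    if total <= 0:
        warnings.warn(
            f"all-zero applicable weights for substance "
            f"{profile.substance_id!r} in scope {scope!r}; spreading uniformly",
            stacklevel=2,
        )
        return pd.Series(amount / len(ids), index=ids, name="kg")
    return pd.Series(amount * w.to_numpy() / total, index=ids, name="kg")


def split_by_landcover(
    kg: float,
    areas: pd.Series,
    profile: SubstanceProfile,
    grouping: Mapping[str, str] | None = None,
    group_to_class: Mapping[str, str] | None = None,
    crops: Iterable[str] | None = None,
) -> dict[str, float]:
    """Split a regional amount across the six land-cover classes.

    Class shares are proportional to the dose-weighted applicable area of
    the crops falling in each class; shares sum to one, and a substance
    applicable to a single class maps 100% to it.  If the region grows no
    applicable crop at all, the amount is spread uniformly over the
    substance's declared classes (the degenerate counterpart of the uniform
    regional spread).
    """
    grouping = landcover.DEFAULT_CROP_GROUPING if grouping is None else grouping
    group_to_class = (
        landcover.GROUP_TO_CLASS if group_to_class is None else group_to_class
    )
    weights: dict[str, float] = {}
    for crop in _covered_crops(profile, crops):
        if crop not in areas.index:
            continue
        cls = group_to_class[grouping[crop]]
        weights[cls] = weights.get(cls, 0.0) + profile.weight_of_group(
            grouping[crop]
        ) * float(areas[crop])
    total = sum(weights.values())
    if total <= 0:
        classes = profile.classes or tuple(
            dict.fromkeys(group_to_class[grouping[c]] for c in profile.crops)
        )
        return {cls: kg / len(classes) for cls in classes}
    return {cls: kg * w / total for cls, w in weights.items() if w > 0}


def build_calibration_table(
    reports: pd.DataFrame,
    regions: RegionTable,
    catalog: Mapping[str, SubstanceProfile],
    grouping: Mapping[str, str] | None = None,
    group_to_class: Mapping[str, str] | None = None,
    *,
    area_variant: str = "reported",
) -> pd.DataFrame:
    """Disaggregate every report and split it by land-cover class.

    Returns the calibration table consumed by the modelling stage: one row
    per (region, substance, class) with columns ``region_id, country,
    substance_id, lcc, kg``.
    """
    grouping = landcover.DEFAULT_CROP_GROUPING if grouping is None else grouping
    group_to_class = (
        landcover.GROUP_TO_CLASS if group_to_class is None else group_to_class
    )
    areas = regions.areas(area_variant)
    rows: dict[tuple[str, str, str], float] = {}
    for _, rep in reports.iterrows():
        sid = rep["substance_id"]
        if sid not in catalog:
            raise KeyError(f"substance {sid!r} not in catalog")
        profile = catalog[sid]
        crops = [c for c in str(rep.get("crops", "") or "").split(";") if c] or None
        regional = disaggregate(
            rep, regions, profile, grouping, area_variant=area_variant
        )
        for region_id, kg in regional.items():
            per_class = split_by_landcover(
                float(kg), areas.loc[region_id], profile, grouping,
                group_to_class, crops,
            )
            for cls, amount in per_class.items():
                key = (region_id, sid, cls)
                rows[key] = rows.get(key, 0.0) + amount
    out = pd.DataFrame(
        [
            {"region_id": r, "substance_id": s, "lcc": c, "kg": v}
            for (r, s, c), v in rows.items()
        ]
    )
    if len(out) == 0:
        return pd.DataFrame(
            columns=["region_id", "country", "substance_id", "lcc", "kg"]
        )
    out["country"] = out["region_id"].map(regions.info["country"])
    return out[["region_id", "country", "substance_id", "lcc", "kg"]]
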