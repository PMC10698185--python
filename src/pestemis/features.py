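"""Predictor construction: climate summaries, collinearity pruning, crop groups.

Per-region climate cells are condensed to five summary statistics per
monthly variable (min, max, median, mean, sample sd); with the default
24-variable monthly inventory this gives 120 candidate climate features.
Highly collinear features are then removed by iterative pairwise
correlation pruning, and crop-code areas are pooled into group predictors.
The design matrix for one substance x land-cover class combines the
applicable crop-group areas with the retained climate features.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import landcover
from .datatypes import DesignMatrix, RegionTable, SubstanceProfile

logger = logging.getLogger(__name__)

CLIMATE_STATS = ("min", "max", "median", "mean", "sd")


def summarize_climate(cells: pd.DataFrame) -> pd.DataFrame:
    """Five summary statistics per climate variable per region.

    ``cells`` is the long table (region_id, variable, cell, value).  Returns
    a wide table indexed by region with one column ``<variable>_<stat>`` per
    variable and statistic; the sample (n-1) standard deviation is reported
    as 0 for single-cell regions.  Permutation-invariant in cell order.
    """
    if len(cells) == 0:
        raise ValueError("no climate cells supplied")
    counts = cells.groupby(["region_id", "variable"])["value"].size()
    if (counts < 1).any():  # pragma: no cover - groupby cannot yield 0
        raise ValueError("region with zero cells")
    g = cells.groupby(["region_id", "variable"])["value"]
    stats = pd.DataFrame(
        {
            "min": g.min(),
            "max": g.max(),
            "median": g.median(),
            "mean": g.mean(),
            "sd": g.std(ddof=1).fillna(0.0),
        }
    )
    wide = stats.unstack("variable")
    # column order: variables in first-appearance order, stats in fixed order
    var_order = list(dict.fromkeys(cells["variable"]))
    cols = [(stat, var) for var in var_order for stat in CLIMATE_STATS]
    wide = wide[cols]
    wide.columns = [f"{var}_{stat}" for stat, var in cols]
    wide.index.name = "region_id"
    return wide


def prune_correlated(
    features: pd.DataFrame, threshold: float = 0.9
) -> list[str]:
    """Iteratively remove one member of each highly correlated feature pair.

    While any pair of remaining features has |Pearson r| above the
    threshold, the currently worst pair is examined and the member with the
    larger mean absolute correlation to all remaining features is dropped
    (ties drop the later column).  Constant columns, whose correlation is
    undefined, are dropped first with a warning.  The result is
    deterministic given column order, and no retained pair exceeds the
    threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if len(features) < 2:
        raise ValueError("need at least two rows to estimate correlations")
    cols = list(features.columns)
    constant = [c for c in cols if float(features[c].std(ddof=0)) == 0.0]
    if constant:
        warnings.warn(
            f"dropping constant feature(s) with undefined correlation: {constant}",
            stacklevel=2,
        )
        cols = [c for c in cols if c not in constant]

    corr = features[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    active = list(range(len(cols)))
    while len(active) > 1:
        sub = corr[np.ix_(active, active)]
        flat = int(np.argmax(sub))
        i, j = divmod(flat, len(active))
        if sub[i, j] <= threshold:
            break
        mean_i = sub[i].sum() / (len(active) - 1)
        mean_j = sub[j].sum() / (len(active) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)  # tie: drop the later column
        del active[drop]
    return [cols[i] for i in active]


def group_crops(
    areas: pd.DataFrame,
    grouping: Mapping[str, str] | Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pool per-crop areas into crop-group predictor columns.

    ``grouping`` maps crop code -> group (a mapping, or (code, group) pairs
    — a code appearing under two groups is a configuration error).  Group
    area is the sum of member areas; crop codes absent from the grouping are
    dropped and logged.  Column order follows first appearance of each
    group in the grouping.
    """
    if grouping is None:
        gmap: dict[str, str] = dict(landcover.DEFAULT_CROP_GROUPING)
    elif isinstance(grouping, Mapping):
        gmap = dict(grouping)
    else:
        gmap = {}
        for code, group in grouping:
            if code in gmap and gmap[code] != group:
                raise ValueError(
                    f"crop code {code!r} mapped to two groups "
                    f"({gmap[code]!r} and {group!r})"
                )
            gmap[code] = group

    dropped = [c for c in areas.columns if c not in gmap]
    if dropped:
        logger.info("dropping %d ungrouped crop code(s): %s", len(dropped), dropped)
    order = list(dict.fromkeys(gmap.values()))
    out = pd.DataFrame(0.0, index=areas.index, columns=order)
    for code in areas.columns:
        if code in gmap:
            out[gmap[code]] += areas[code].astype(float)
    return out


def assemble_design(
    calibration: pd.DataFrame,
    substance_id: str,
    lcc: str,
    profile: SubstanceProfile,
    regions: RegionTable,
    grouped_areas: pd.DataFrame,
    climate_features: pd.DataFrame | None = None,
    retained_climate: Sequence[str] = (),
    group_to_class: Mapping[str, str] | None = None,
) -> DesignMatrix | None:
    """Build the calibration design matrix for one substance x class.

    Rows are all regions of the countries contributing calibration data
    for this substance (regions without an allocation get an explicit
    zero response).  Crop predictors are the substance's dosed groups
    belonging to this land-cover class; climate predictors are the
    retained features.  Returns ``None`` when the combination is
    unmodellable (no calibration rows or no applicable predictor).
    """
    group_to_class = (
        landcover.GROUP_TO_CLASS if group_to_class is None else group_to_class
    )
    rows = calibration[
        (calibration["substance_id"] == substance_id) & (calibration["lcc"] == lcc)
    ]
    if len(rows) == 0:
        logger.info("unmodellable: no calibration data for %s / %s", substance_id, lcc)
        return None
    countries = sorted(rows["country"].unique())
    idx = regions.info.index[regions.info["country"].isin(countries)]

    applicable_groups = (
        set(profile.dose_weights)
        if profile.dose_weights
        else set(landcover.groups_of_crops(profile.crops))
    )
    crop_cols = [
        g
        for g in grouped_areas.columns
        if g in applicable_groups and group_to_class.get(g) == lcc
    ]
    if not crop_cols:
        logger.info(
            "unmodellable: no applicable crop predictor for %s / %s",
            substance_id, lcc,
        )
        return None

    X = grouped_areas.loc[idx, crop_cols].copy()
    climate_cols: list[str] = []
    if retained_climate:
        if climate_features is None:
            raise ValueError("retained_climate given but no climate feature table")
        climate_cols = list(retained_climate)
        X = pd.concat([X, climate_features.loc[idx, climate_cols]], axis=1)

    y = (
        rows.set_index("region_id")["kg"].reindex(idx).fillna(0.0).rename("kg")
    )
    country = regions.info.loc[idx, "country"]
    return DesignMatrix(
        substance_id=substance_id,
        lcc=lcc,
        X=X,
        y=y,
        country=country,
        crop_columns=crop_cols,
        climate_columns=climate_cols,
    )
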