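"""Extrapolation to all regions, authorization masking, and the output table.

The selected model of each substance x land-cover class is applied to
every region using the *total* crop extents (not just the reported-
coverage extents used in calibration).  Predictions are clipped at zero,
masked to zero where the substance is not authorized in the region's
country, and assembled into the published one-row-per-(region, substance)
CSV schema with the total kilograms in ``KG_TOT``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .datatypes import AuthorizationMatrix, FittedModel, RegionTable, SubstanceProfile

logger = logging.getLogger(__name__)

#: Column order of the published dataset.
OUTPUT_COLUMNS = [
    "Country",
    "NUTS3",
    "Categories of products",
    "Chemical Class Substance",
    "ID_EUPDB",
    "CAS",
    "CIPAC",
    "Substances common names",
    "KG_TOT",
]


def extrapolate(model: FittedModel, predictors: pd.DataFrame) -> pd.Series:
    """Predict per-region use (kg) from a fitted model.

    ``predictors`` must contain every feature the model selected, built
    from total crop extents (plus climate features).  Country-augmented
    (M3) models are refused: their per-country shifts cannot be
    extrapolated.  Negative predictions are clipped to zero and counted in
    the log.
    """
    if not model.extrapolable:
        raise ValueError(
            f"model {model.model_id} is diagnostic-only and cannot be used "
            f"for extrapolation"
        )
    pred = model.predict(predictors)
    negative = int((pred < 0).sum())
    if negative:
        logger.info(
            "%s: clipped %d negative prediction(s) to zero", model.model_id, negative
        )
    return pred.clip(lower=0.0)


def apply_authorization(
    predictions: pd.DataFrame, auth: AuthorizationMatrix
) -> pd.DataFrame:
    """Zero predictions of (country, substance) pairs that are not authorized.

    ``predictions`` is the long table (region_id, country, substance_id,
    lcc, kg).  Authorized pairs pass through unchanged; masked cells become
    exactly 0 and the mask count is logged.
    """
    out = predictions.copy()
    pairs = out[["country", "substance_id"]].drop_duplicates()
    masked_pairs = [
        (c, s)
        for c, s in pairs.itertuples(index=False)
        if not auth.is_authorized(c, s)
    ]
    if masked_pairs:
        mask = pd.Series(False, index=out.index)
        for c, s in masked_pairs:
            mask |= (out["country"] == c) & (out["substance_id"] == s)
        out.loc[mask, "kg"] = 0.0
        logger.info(
            "authorization masking: %d pair(s), %d row(s) set to zero",
            len(masked_pairs), int(mask.sum()),
        )
    return out


def assemble_dataset(
    predictions: pd.DataFrame,
    catalog: Mapping[str, SubstanceProfile],
    regions: RegionTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the published table and its per-class companion.

    Returns ``(primary, detailed)``: the primary table has exactly the
    published columns with ``KG_TOT`` the sum over the six land-cover
    classes; the detailed table keeps one kg column per class.  Regions
    with zero predicted use for an authorized substance are retained as
    explicit zeros.
    """
    unknown = sorted(set(predictions["substance_id"]) - set(catalog))
    if unknown:
        raise KeyError(f"substance(s) not in catalog: {unknown}")

    detailed = predictions.pivot_table(
        index=["region_id", "substance_id"],
        columns="lcc",
        values="kg",
        aggfunc="sum",
        fill_value=0.0,
    )
    detailed["KG_TOT"] = detailed.sum(axis=1)
    detailed = detailed.reset_index()
    detailed["Country"] = detailed["region_id"].map(regions.info["country"])

    rows = []
    for _, r in detailed.iterrows():
        p = catalog[r["substance_id"]]
        rows.append(
            {
                "Country": r["Country"],
                "NUTS3": r["region_id"],
                "Categories of products": p.category,
                "Chemical Class Substance": p.chemical_class,
                "ID_EUPDB": p.id_eupdb,
                "CAS": p.cas,
                "CIPAC": p.cipac,
                "Substances common names": p.name,
                "KG_TOT": float(r["KG_TOT"]),
            }
        )
    primary = pd.DataFrame(rows, columns=OUTPUT_COLUMNS)
    return primary, detailed


def write_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write an emissions table as UTF-8 CSV with full float precision."""
    table.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def read_emissions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in OUTPUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df
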