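"""Reading, harmonizing and validating the tabular inputs.

All files are UTF-8, comma-separated CSV with a header row and "." as the
decimal mark.  Sales and use are treated as equivalent, and all amounts
are kilograms.  Loaders validate and *reject* bad rows with an error that
names the offending row and column; they never coerce.

Schemas
-------
reported use : country, scope, substance_id, year, kg, crops
               (``crops`` is a ';'-joined list of crop codes, may be empty;
               ``year`` is an integer or the literal ``multi``)
regions      : region_id, country, province, total:<code>..., reported:<code>...
catalog      : substance_id, name, category, chemical_class, cas, cipac,
               id_eupdb, crops, dose_weights, classes
               (``dose_weights`` as 'GROUP:value;GROUP:value')
authorizations: country, substance_id, authorized
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .datatypes import AuthorizationMatrix, RegionTable, SubstanceProfile

logger = logging.getLogger(__name__)

REPORTED_USE_COLUMNS = ["country", "scope", "substance_id", "year", "kg", "crops"]


class LoadError(ValueError):
    """Raised when an input file violates its documented schema."""


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def convert_products_to_as(
    product_records: pd.DataFrame,
    composition: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert commercial-product amounts to active-substance amounts.

    ``product_records`` has columns (country, scope, year, product, kg);
    ``composition`` has columns (product, substance_id, fraction) with the
    mass fraction of each active substance in the product.  Returns
    ``(records, rejects)``: one record per (country, scope, year,
    substance), kg_AS = sum over products of kg_product x fraction, and the
    product rows whose product has no composition entry (reported, never
    silently dropped).
    """
    comp = composition.copy()
    bad = comp[(comp["fraction"] < 0) | (comp["fraction"] > 1)]
    if len(bad):
        raise LoadError(
            f"composition fractions outside [0, 1] for products "
            f"{sorted(bad['product'].unique())}"
        )
    known = set(comp["product"])
    rejects = product_records[~product_records["product"].isin(known)].copy()
    if len(rejects):
        logger.warning(
            "%d product record(s) lack a composition entry and were rejected: %s",
            len(rejects),
            sorted(rejects["product"].unique()),
        )
    ok = product_records[product_records["product"].isin(known)]
    merged = ok.merge(comp, on="product", how="left")
    merged["kg"] = merged["kg"] * merged["fraction"]
    out = (
        merged.groupby(["country", "scope", "year", "substance_id"], as_index=False)[
            "kg"
        ]
        .sum()
    )
    out["crops"] = ""
    return out[REPORTED_USE_COLUMNS], rejects


def average_over_years(records: pd.DataFrame) -> pd.DataFrame:
    """Average reported amounts over the available years.

    Returns one record per (country, scope, substance_id, crops) with the
    arithmetic mean of the per-year kilograms and ``year`` set to
    ``"multi"``.  A single-year input passes through unchanged except for
    the year marker (averaging is idempotent).
    """
    if len(records) == 0:
        return records.assign(year="multi")
    keys = ["country", "scope", "substance_id", "crops"]
    out = records.groupby(keys, as_index=False, dropna=False)["kg"].mean()
    out["year"] = "multi"
    return out[REPORTED_USE_COLUMNS]


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")


def write_reported_use(records: pd.DataFrame, path: str | Path) -> None:
    records[REPORTED_USE_COLUMNS].to_csv(path, index=False)


def load_reported_use(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[""], dtype={"crops": str})
    _require_columns(df, REPORTED_USE_COLUMNS, path)
    df["crops"] = df["crops"].fillna("")
    neg = df.index[df["kg"] < 0]
    if len(neg):
        raise LoadError(f"{path}: negative kg at row(s) {list(neg + 2)} (column 'kg')")
    if df["kg"].isna().any():
        row = int(df.index[df["kg"].isna()][0]) + 2
        raise LoadError(f"{path}: missing kg at row {row} (column 'kg')")
    dup = df.duplicated(subset=["country", "scope", "substance_id", "year"], keep=False)
    if dup.any():
        rows = list(df.index[dup] + 2)
        raise LoadError(
            f"{path}: duplicate (country, scope, substance_id, year) at row(s) {rows}"
        )
    return df[REPORTED_USE_COLUMNS]


def write_regions(regions: RegionTable, path: str | Path) -> None:
    wide = regions.info.copy()
    for c in regions.area_total.columns:
        wide[f"total:{c}"] = regions.area_total[c]
    for c in regions.area_reported.columns:
        wide[f"reported:{c}"] = regions.area_reported[c]
    wide.to_csv(path, index=True, index_label="region_id")


def load_regions(path: str | Path) -> RegionTable:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["region_id", "country", "province"], path)
    if df["region_id"].duplicated().any():
        dups = sorted(df["region_id"][df["region_id"].duplicated()])
        raise LoadError(f"{path}: duplicate region_id(s) {dups}")
    df = df.set_index("region_id")
    total_cols = [c for c in df.columns if c.startswith("total:")]
    rep_cols = [c for c in df.columns if c.startswith("reported:")]
    crops_t = [c.split(":", 1)[1] for c in total_cols]
    crops_r = [c.split(":", 1)[1] for c in rep_cols]
    if crops_t != crops_r:
        raise LoadError(f"{path}: total/reported crop columns do not match")
    area_total = df[total_cols].astype(float)
    area_total.columns = crops_t
    area_reported = df[rep_cols].astype(float)
    area_reported.columns = crops_r
    for name, tbl in (("total", area_total), ("reported", area_reported)):
        if tbl.isna().any().any():
            col = tbl.columns[tbl.isna().any()][0]
            raise LoadError(f"{path}: missing {name} area in column {col!r}")
        if (tbl.to_numpy() < 0).any():
            col = tbl.columns[(tbl < 0).any()][0]
            raise LoadError(f"{path}: negative {name} area in column {col!r}")
    try:
        return RegionTable(df[["country", "province"]], area_total, area_reported)
    except ValueError as exc:
        raise LoadError(f"{path}: {exc}") from exc


_CATALOG_COLUMNS = [
    "substance_id", "name", "category", "chemical_class", "cas", "cipac",
    "id_eupdb", "crops", "dose_weights", "classes",
]


def write_catalog(catalog: Mapping[str, SubstanceProfile], path: str | Path) -> None:
    rows = []
    for s in sorted(catalog):
        p = catalog[s]
        rows.append(
            {
                "substance_id": p.substance_id,
                "name": p.name,
                "category": p.category,
                "chemical_class": p.chemical_class,
                "cas": p.cas,
                "cipac": p.cipac,
                "id_eupdb": p.id_eupdb,
                "crops": ";".join(p.crops),
                "dose_weights": ";".join(
                    f"{g}:{w!r}" for g, w in sorted(p.dose_weights.items())
                ),
                "classes": ";".join(p.classes),
            }
        )
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, index=False)


def load_catalog(path: str | Path) -> dict[str, SubstanceProfile]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _CATALOG_COLUMNS, path)
    if df["substance_id"].duplicated().any():
        dups = sorted(df["substance_id"][df["substance_id"].duplicated()])
        raise LoadError(f"{path}: duplicate substance_id(s) {dups}")
    catalog: dict[str, SubstanceProfile] = {}
    for i, row in df.iterrows():
        crops = tuple(c for c in row["crops"].split(";") if c)
        if not crops:
            raise LoadError(
                f"{path}: row {i + 2}: substance {row['substance_id']!r} has no "
                f"applicable crop (column 'crops')"
            )
        weights: dict[str, float] = {}
        for item in row["dose_weights"].split(";"):
            if not item:
                continue
            try:
                g, w = item.split(":")
                weights[g] = float(w)
            except ValueError:
                raise LoadError(
                    f"{path}: row {i + 2}: malformed dose_weights entry {item!r}"
                ) from None
        try:
            catalog[row["substance_id"]] = SubstanceProfile(
                substance_id=row["substance_id"],
                name=row["name"],
                category=row["category"],
                chemical_class=row["chemical_class"],
                cas=row["cas"],
                cipac=row["cipac"],
                id_eupdb=row["id_eupdb"],
                crops=crops,
                dose_weights=weights,
                classes=tuple(c for c in row["classes"].split(";") if c),
            )
        except ValueError as exc:
            raise LoadError(f"{path}: row {i + 2}: {exc}") from exc
    return catalog


def write_authorizations(auth: AuthorizationMatrix, path: str | Path) -> None:
    long = (
        auth.table.rename_axis("country")
        .reset_index()
        .melt(id_vars="country", var_name="substance_id", value_name="authorized")
    )
    long.to_csv(path, index=False)


def load_authorizations(path: str | Path, default: bool = True) -> AuthorizationMatrix:
    """Load the country x substance authorization table.

    Pairs absent from the file take the permissive default (authorized);
    only known non-authorizations are masked.  The fallback policy is
    recorded on the returned matrix and fallback lookups are counted.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["country", "substance_id", "authorized"], path)
    dup = df.duplicated(subset=["country", "substance_id"], keep=False)
    if dup.any():
        raise LoadError(
            f"{path}: duplicate (country, substance_id) at row(s) "
            f"{list(df.index[dup] + 2)}"
        )
    table = df.pivot(index="country", columns="substance_id", values="authorized")
    if table.isna().any().any():
        n = int(table.isna().to_numpy().sum())
        logger.info(
            "authorization table: %d absent pair(s) take the default (%s)",
            n, "authorized" if default else "not authorized",
        )
        table = table.fillna(default)
    return AuthorizationMatrix(table, default=default)
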