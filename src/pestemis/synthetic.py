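"""Synthetic landscapes, climate, use processes and reporting schemes.

Real inputs to the pipeline are national use/sales reports, crop-area
tables and gridded climate summaries.  This module generates statistically
similar stand-ins with a known ground truth so that every downstream stage
(disaggregation, feature building, the regression cascade, extrapolation)
can be exercised and checked end to end:

* crop areas are log-normal (heavy-tailed, like agricultural statistics);
* climate cells follow smooth cross-region gradients plus cell noise;
* true use is dose x area per crop group, optionally modulated by a
  multiplicative climate term and log-normal noise;
* reporting aggregates true use to each country's resolution (country,
  province or region level), with optional unreported crops and
  non-reporting countries.

Everything is driven by explicit integer seeds: the same seed and
parameters reproduce every table exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import landcover
from .datatypes import (
    AuthorizationMatrix,
    RegionTable,
    ReportingScheme,
    SubstanceProfile,
    SyntheticTruth,
)

#: Monthly climate variable inventory: 12 monthly mean temperatures (degC)
#: and 12 monthly mean precipitations (mm/month).
CLIMATE_VARIABLES: tuple[str, ...] = tuple(
    f"tmean_{m:02d}" for m in range(1, 13)
) + tuple(f"prec_{m:02d}" for m in range(1, 13))

_CATEGORIES = (
    "Herbicide",
    "Fungicide",
    "Insecticide",
    "Plant growth regulator",
    "Molluscicide",
    "Other",
)


def country_codes(n: int) -> list[str]:
    """Deterministic ISO-3-style synthetic country codes: AAA, AAB, ..."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    codes = []
    for combo in itertools.product(letters, repeat=3):
        codes.append("".join(combo))
        if len(codes) == n:
            return codes
    raise ValueError("too many countries requested")


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def generate_landscape(
    n_countries: int,
    regions_per_country: int,
    crop_codes: Sequence[str] | None = None,
    seed: int = 0,
    *,
    median_area_ha: float = 500.0,
    log_sd: float = 1.0,
    coverage_fraction: float | tuple[float, float] = 1.0,
    regions_per_province: int = 2,
) -> RegionTable:
    """Generate a synthetic landscape of regions with crop-area tables.

    Each (region, crop) total area is drawn log-normal with the given median
    and log-scale sd.  The reported-coverage area is ``coverage_fraction``
    times the total (a scalar, or a ``(low, high)`` range sampled uniformly
    per cell), so reported <= total always holds.  Regions are grouped into
    provinces of ``regions_per_province`` consecutive regions.
    """
    if n_countries < 1 or regions_per_country < 1:
        raise ValueError("counts must be >= 1")
    codes = list(landcover.DEFAULT_CROP_CODES if crop_codes is None else crop_codes)
    if len(set(codes)) != len(codes):
        raise ValueError("crop codes must be unique")

    rng = np.random.default_rng(seed)
    countries = country_codes(n_countries)
    rows, region_ids = [], []
    for c in countries:
        for i in range(regions_per_country):
            region_ids.append(f"{c}-R{i + 1:02d}")
            rows.append(
                {"country": c, "province": f"{c}-P{i // regions_per_province + 1:02d}"}
            )
    info = pd.DataFrame(rows, index=pd.Index(region_ids, name="region_id"))

    n = len(region_ids)
    total = np.exp(
        rng.normal(np.log(median_area_ha), log_sd, size=(n, len(codes)))
    )
    if isinstance(coverage_fraction, tuple):
        lo, hi = coverage_fraction
        if not (0 <= lo <= hi <= 1):
            raise ValueError("coverage_fraction range must lie in [0, 1]")
        frac = rng.uniform(lo, hi, size=total.shape)
    else:
        if not 0 <= coverage_fraction <= 1:
            raise ValueError("coverage_fraction must lie in [0, 1]")
        frac = float(coverage_fraction)
    area_total = pd.DataFrame(total, index=info.index, columns=codes)
    area_reported = pd.DataFrame(total * frac, index=info.index, columns=codes)
    return RegionTable(info, area_total, area_reported)


def apply_reporting_scheme(regions: RegionTable, scheme: ReportingScheme) -> RegionTable:
    """Zero the reported-coverage areas that a scheme declares uncovered.

    Crops a country does not report on, and all crops of non-reporting
    countries, get zero reported-coverage area: the calibration dataset only
    contains extents for which use was actually reported.
    """
    scheme.validate_against(regions)
    reported = regions.area_reported.copy()
    for ctry, crops in scheme.unreported_crops.items():
        mask = regions.info["country"] == ctry
        cols = [c for c in reported.columns if c in crops]
        reported.loc[mask, cols] = 0.0
    if scheme.nonreporting:
        mask = regions.info["country"].isin(scheme.nonreporting)
        reported.loc[mask, :] = 0.0
    return RegionTable(regions.info, regions.area_total, reported)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def generate_climate(
    regions: RegionTable,
    cells_per_region: int = 100,
    seed: int = 0,
    *,
    gradient_scale: float = 1.0,
    noise_scale: float = 1.0,
    temp_gradient: float = 5.0,
    prec_gradient: float = 30.0,
    temp_cell_sd: float = 1.0,
    prec_cell_sd: float = 5.0,
    sd_gradient: float = 0.6,
) -> pd.DataFrame:
    """Sample per-region climate cells for the monthly variable inventory.

    Each region yields ``cells_per_region`` samples of the 24 monthly
    variables (12 mean temperatures, 12 mean precipitations).  The regional
    level of month *m* follows a smooth sinusoidal gradient across the
    region sequence, shared between the temperature and precipitation of
    that month; the within-region cell spread also scales with the same
    gradient.  The default geometry therefore carries twelve independent
    latent gradients, one per calendar month.

    Returns a long table with columns ``region_id, variable, cell, value``;
    precipitation is clipped at zero.
    """
    if len(regions.region_ids) == 0:
        raise ValueError("empty region table")
    if cells_per_region < 1:
        raise ValueError("cells_per_region must be >= 1")

    rng = np.random.default_rng(seed)
    n = len(regions.region_ids)
    x = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    phases = rng.uniform(0, 1, size=12)
    latents = {
        m: np.sin(2 * np.pi * ((m + 1) * x + phases[m])) for m in range(12)
    }

    frames = []
    for var in CLIMATE_VARIABLES:
        kind, month = var.split("_")
        m = int(month) - 1
        g = latents[m] * gradient_scale
        if kind == "tmean":
            base = 10.0 + 8.0 * np.cos(2 * np.pi * (m + 1 - 7) / 12.0)
            mu, amp, s0 = base, temp_gradient, temp_cell_sd
        else:
            mu, amp, s0 = 80.0, prec_gradient, prec_cell_sd
        level = mu + amp * g
        spread = noise_scale * s0 * np.clip(1.0 + sd_gradient * g, 0.05, None)
        vals = rng.normal(
            level[:, None], spread[:, None], size=(n, cells_per_region)
        )
        if kind == "prec":
            vals = np.clip(vals, 0.0, None)
        frames.append(
            pd.DataFrame(
                {
                    "region_id": np.repeat(regions.region_ids.to_numpy(), cells_per_region),
                    "variable": var,
                    "cell": np.tile(np.arange(cells_per_region), n),
                    "value": vals.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_correlated_blocks(
    n_rows: int,
    n_blocks: int,
    per_block: int,
    seed: int = 0,
    *,
    within_noise: float = 0.05,
) -> pd.DataFrame:
    """Feature table in correlated blocks, for collinearity-pruning tests.

    Columns within a block are one latent standard normal plus small
    independent noise (within-block |r| close to 1); latents of different
    blocks are independent (cross-block |r| small).  Column ``b{i}_f{j}``
    belongs to block *i*.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for b in range(n_blocks):
        latent = rng.normal(size=n_rows)
        for j in range(per_block):
            cols[f"b{b}_f{j}"] = latent + within_noise * rng.normal(size=n_rows)
    return pd.DataFrame(cols, index=pd.RangeIndex(n_rows, name="row"))


# ---------------------------------------------------------------------------
# true use and reporting
# ---------------------------------------------------------------------------

def simulate_true_use(
    truth: SyntheticTruth,
    regions: RegionTable,
    climate_features: pd.DataFrame | None = None,
    grouping: Mapping[str, str] | None = None,
    group_to_class: Mapping[str, str] | None = None,
    *,
    area_variant: str = "total",
) -> pd.DataFrame:
    """Simulate true use of every substance on every crop in every region.

    kg(region, substance, crop) =
        dose(group of crop) x area(crop) x country multiplier
        x exp(sum_f climate_coef_f x z_f(region)) x exp(eps),

    with ``z_f`` the climate feature standardized across regions and
    ``eps ~ N(0, noise_sd^2)`` drawn per (substance, crop, region).  Noise
    draws depend only on ``truth.seed`` and the sorted key order, so the
    "total" and "reported" variants of the same scenario share the same
    noise realization.

    Returns a long table: region_id, country, substance_id, crop, group,
    lcc, kg.
    """
    grouping = landcover.DEFAULT_CROP_GROUPING if grouping is None else dict(grouping)
    group_to_class = (
        landcover.GROUP_TO_CLASS if group_to_class is None else dict(group_to_class)
    )
    areas = regions.areas(area_variant)
    groups_present = {grouping[c] for c in areas.columns if c in grouping}
    for (_s, g) in truth.dose_per_group:
        if g not in groups_present:
            raise ValueError(
                f"dose references crop group {g!r} with no crop present in the landscape"
            )

    if truth.climate_coefs:
        if climate_features is None:
            raise ValueError("climate_coefs set but no climate features supplied")
        z = climate_features.loc[regions.region_ids]
        sd = z.std(ddof=1).replace(0.0, 1.0)
        z = (z - z.mean()) / sd

    rng = np.random.default_rng(truth.seed)
    n = len(regions.region_ids)
    country = regions.info["country"]
    frames = []
    for s in truth.substances:
        doses = truth.doses_of(s)
        mult = country.map(
            lambda c: truth.country_dose_multiplier.get((c, s), 1.0)
        ).to_numpy(dtype=float)
        clim = np.zeros(n)
        for (sub, feat), coef in sorted(truth.climate_coefs.items()):
            if sub == s:
                clim = clim + coef * z[feat].to_numpy(dtype=float)
        clim = np.exp(clim)
        for g in sorted(doses):
            dose = doses[g]
            crops = sorted(c for c in areas.columns if grouping.get(c) == g)
            for crop in crops:
                # one noise vector per (substance, crop), fixed draw order
                eps = (
                    rng.normal(0.0, truth.noise_sd, size=n)
                    if truth.noise_sd > 0
                    else np.zeros(n)
                )
                kg = dose * areas[crop].to_numpy(dtype=float) * mult * clim * np.exp(eps)
                frames.append(
                    pd.DataFrame(
                        {
                            "region_id": regions.region_ids,
                            "country": country.to_numpy(),
                            "substance_id": s,
                            "crop": crop,
                            "group": g,
                            "lcc": group_to_class[g],
                            "kg": kg,
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True)
    return out


def aggregate_true_use(
    true_use: pd.DataFrame, by: Sequence[str] = ("region_id", "substance_id", "lcc")
) -> pd.DataFrame:
    """Sum the per-crop simulation output over the given keys."""
    return true_use.groupby(list(by), as_index=False)["kg"].sum()


def simulate_reporting(
    true_use: pd.DataFrame,
    scheme: ReportingScheme,
    regions: RegionTable,
    *,
    years: Sequence[int] = (2015,),
    year_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Aggregate simulated true use into country reports.

    Each reporting country's records sum true use over the scope implied by
    its resolution (whole country, provinces, or single regions), after
    removing the contributions of its unreported crops.  Non-reporting
    countries are absent.  With several years, each record is replicated
    per year with independent multiplicative log-normal noise.

    ``true_use`` should normally be the *reported-coverage* variant of
    :func:`simulate_true_use`, so that reported kilograms match the crop
    extents the calibration stage will see.
    """
    overlap = set(scheme.resolution) & set(scheme.nonreporting)
    if overlap:
        raise ValueError(f"countries both reporting and non-reporting: {sorted(overlap)}")
    scheme.validate_against(regions)

    rng = np.random.default_rng(seed)
    records = []
    for ctry in scheme.reporting_countries:
        level = scheme.resolution[ctry]
        excluded = set(scheme.unreported_crops.get(ctry, ()))
        sub = true_use[true_use["country"] == ctry]
        sub = sub[~sub["crop"].isin(excluded)]
        if level == "country":
            sub = sub.assign(scope=ctry)
        elif level == "province":
            sub = sub.assign(
                scope=sub["region_id"].map(regions.info["province"])
            )
        else:
            sub = sub.assign(scope=sub["region_id"])
        agg = sub.groupby(["scope", "substance_id"], as_index=False)["kg"].sum()
        crops_by_substance = (
            sub.groupby("substance_id")["crop"]
            .apply(lambda s: ";".join(sorted(set(s))))
            .to_dict()
        )
        for _, row in agg.iterrows():
            for year in years:
                kg = float(row["kg"])
                if year_noise_sd > 0 and len(years) > 1:
                    kg *= float(np.exp(rng.normal(0.0, year_noise_sd)))
                records.append(
                    {
                        "country": ctry,
                        "scope": row["scope"],
                        "substance_id": row["substance_id"],
                        "year": year,
                        "kg": kg,
                        "crops": crops_by_substance.get(row["substance_id"], ""),
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["country", "scope", "substance_id", "year", "kg", "crops"]
    )


# ---------------------------------------------------------------------------
# catalogs and authorizations
# ---------------------------------------------------------------------------

def make_catalog(
    truth: SyntheticTruth,
    grouping: Mapping[str, str] | None = None,
    group_to_class: Mapping[str, str] | None = None,
    categories: Mapping[str, str] | None = None,
) -> dict[str, SubstanceProfile]:
    """Derive a substance catalog from a synthetic ground truth.

    Applicable crops are the members of every group the substance has a
    positive dose for; dose weights are the (relative) true doses, which is
    what a perfectly informed label/recommendation table would contain.
    """
    grouping = landcover.DEFAULT_CROP_GROUPING if grouping is None else dict(grouping)
    group_to_class = (
        landcover.GROUP_TO_CLASS if group_to_class is None else dict(group_to_class)
    )
    crops_of_group: dict[str, list[str]] = {}
    for crop, g in grouping.items():
        crops_of_group.setdefault(g, []).append(crop)

    catalog: dict[str, SubstanceProfile] = {}
    for i, s in enumerate(truth.substances):
        doses = {g: d for g, d in truth.doses_of(s).items() if d > 0}
        crops = tuple(
            sorted(itertools.chain.from_iterable(crops_of_group[g] for g in doses))
        )
        classes = tuple(
            dict.fromkeys(group_to_class[g] for g in sorted(doses))
        )
        category = (
            categories[s]
            if categories is not None
            else _CATEGORIES[i % len(_CATEGORIES)]
        )
        catalog[s] = SubstanceProfile(
            substance_id=s,
            name=f"substance-{s.lower()}",
            category=category,
            chemical_class=f"synthetic class {i % 4 + 1}",
            cas=f"{10000 + i}-{i % 100:02d}-{i % 10}",
            cipac=str(100 + i),
            id_eupdb=str(1000 + i),
            crops=crops,
            dose_weights=doses,
            classes=classes,
        )
    return catalog


def make_authorizations(
    countries: Iterable[str],
    substances: Iterable[str],
    unauthorized: Iterable[tuple[str, str]] = (),
    default: bool = True,
) -> AuthorizationMatrix:
    """Full country x substance authorization table, all True except listed pairs."""
    countries = list(countries)
    substances = list(substances)
    table = pd.DataFrame(True, index=pd.Index(countries, name="country"),
                         columns=pd.Index(substances, name="substance_id"))
    for ctry, s in unauthorized:
        table.loc[ctry, s] = False
    return AuthorizationMatrix(table, default=default)


# ---------------------------------------------------------------------------
# reference fixture
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A complete synthetic study: landscape, climate, truth and reports."""

    regions: RegionTable
    climate_cells: pd.DataFrame
    truth: SyntheticTruth
    catalog: dict[str, SubstanceProfile]
    grouping: dict[str, str]
    group_to_class: dict[str, str]
    scheme: ReportingScheme
    auth: AuthorizationMatrix
    reports: pd.DataFrame          # simulated ReportedUse records
    true_use_total: pd.DataFrame   # per-crop true use on total extents

    @property
    def reporting_countries(self) -> tuple[str, ...]:
        return self.scheme.reporting_countries


#: Doses (kg/ha) of the twelve reference substances per crop group.  Four
#: substances act on arable groups, two on fruit trees, two on grassland,
#: one each on olives and rice, two on vineyards: all six land-cover
#: classes are exercised.
_REFERENCE_DOSES: dict[tuple[str, str], float] = {
    ("S01", "C0000"): 2.0, ("S01", "G0000"): 1.5, ("S01", "I0000"): 1.0,
    ("S01", "Q0000"): 0.5,
    ("S02", "C0000"): 0.8, ("S02", "R0000"): 1.2, ("S02", "P0000"): 0.6,
    ("S03", "C0000"): 0.4, ("S03", "V_S0000"): 2.5,
    ("S04", "C0000"): 0.3, ("S04", "I0000"): 0.7,
    ("S05", "F0000"): 3.0, ("S05", "T0000"): 2.0,
    ("S06", "F0000"): 1.1,
    ("S07", "J0000"): 0.9,
    ("S08", "J0000"): 0.35,
    ("S09", "O1000"): 2.2,
    ("S10", "W1000"): 2.8,
    ("S11", "W1000"): 0.5,
    ("S12", "C2000"): 1.4,
}

_REFERENCE_CATEGORIES = {
    "S01": "Herbicide", "S02": "Herbicide", "S07": "Herbicide",
    "S12": "Herbicide",
    "S03": "Fungicide", "S05": "Fungicide", "S09": "Fungicide",
    "S10": "Fungicide",
    "S04": "Insecticide", "S06": "Insecticide", "S11": "Insecticide",
    "S08": "Plant growth regulator",
}


def reference_fixture(
    seed: int = 42,
    *,
    noise_sd: float = 0.0,
    coverage_fraction: float | tuple[float, float] = (0.7, 1.0),
    climate_coefs: Mapping[tuple[str, str], float] | None = None,
    cells_per_region: int = 100,
    regions_per_country: int = 10,
    unauthorized: Iterable[tuple[str, str]] = (),
) -> Scenario:
    """The default test scenario.

    Twelve countries of ``regions_per_country`` regions each; the first
    eight report (four at country level, three at province level, one at
    region level) and four do not.  Twelve substances with fixed doses span
    all six land-cover classes; substance S12 is applied in only two of the
    reporting countries, so it fails the eligibility filter.  One reporting
    country does not report on the plants-harvested-green crops.  Defaults
    are noise-free and climate-free so that the ground truth is exactly
    recoverable.
    """
    countries = country_codes(12)
    reporting = countries[:8]
    scheme = ReportingScheme(
        resolution={
            reporting[0]: "country", reporting[1]: "country",
            reporting[2]: "country", reporting[3]: "country",
            reporting[4]: "province", reporting[5]: "province",
            reporting[6]: "province", reporting[7]: "region",
        },
        unreported_crops={reporting[1]: frozenset({"G1000", "G2000", "G3000"})},
        nonreporting=frozenset(countries[8:]),
    )
    # S12 used only in the first two reporting countries
    multipliers = {
        (c, "S12"): 0.0 for c in countries if c not in reporting[:2]
    }
    truth = SyntheticTruth(
        dose_per_group=dict(_REFERENCE_DOSES),
        climate_coefs=dict(climate_coefs or {}),
        noise_sd=noise_sd,
        seed=seed + 1,
        country_dose_multiplier=multipliers,
    )

    landscape = generate_landscape(
        12, regions_per_country, landcover.DEFAULT_CROP_CODES, seed,
        coverage_fraction=coverage_fraction,
    )
    regions = apply_reporting_scheme(landscape, scheme)
    climate_cells = generate_climate(regions, cells_per_region, seed + 2)

    climate_features = None
    if truth.climate_coefs:
        from . import features

        climate_features = features.summarize_climate(climate_cells)

    true_total = simulate_true_use(
        truth, regions, climate_features, area_variant="total"
    )
    true_reported = simulate_true_use(
        truth, regions, climate_features, area_variant="reported"
    )
    reports = simulate_reporting(true_reported, scheme, regions, seed=seed + 3)

    catalog = make_catalog(truth, categories=_REFERENCE_CATEGORIES)
    auth = make_authorizations(countries, truth.substances, unauthorized=unauthorized)
    return Scenario(
        regions=regions,
        climate_cells=climate_cells,
        truth=truth,
        catalog=catalog,
        grouping=dict(landcover.DEFAULT_CROP_GROUPING),
        group_to_class=dict(landcover.GROUP_TO_CLASS),
        scheme=scheme,
        auth=auth,
        reports=reports,
        true_use_total=true_total,
    )
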