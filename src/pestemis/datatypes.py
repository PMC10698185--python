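"""Shared in-memory containers used across the pipeline stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

RESOLUTIONS = ("country", "province", "region")


@dataclass(frozen=True)
class SubstanceProfile:
    """Identity and applicability of one active substance.

    ``dose_weights`` are relative recommended doses per crop group
    (dimensionless, >= 0); an empty mapping means uniform weights over the
    applicable groups.  ``classes`` are the land-cover classes the substance
    can be applied in, derived from its applicable crops.
    """

    substance_id: str
    name: str
    category: str
    chemical_class: str
    cas: str
    cipac: str
    id_eupdb: str
    crops: tuple[str, ...]
    dose_weights: Mapping[str, float] = field(default_factory=dict)
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.crops) == 0:
            raise ValueError(
                f"substance {self.substance_id!r} has no applicable crop"
            )
        if any(w < 0 for w in self.dose_weights.values()):
            raise ValueError(
                f"substance {self.substance_id!r} has a negative dose weight"
            )

    def weight_of_group(self, group: str) -> float:
        """Relative dose weight of a crop group (1.0 when weights are uniform)."""
        if not self.dose_weights:
            return 1.0
        return float(self.dose_weights.get(group, 0.0))


@dataclass
class RegionTable:
    """Small regions with country/province membership and two crop-area tables.

    ``area_total`` holds the full crop extents used for prediction;
    ``area_reported`` the (smaller or equal) extents for which use was
    actually reported, used for calibration.  Both are indexed by region id
    with one column per crop code, in hectares.
    """

    info: pd.DataFrame        # index region_id; columns: country, province
    area_total: pd.DataFrame  # index region_id; columns: crop codes
    area_reported: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.info.index.is_unique:
            raise ValueError("region ids are not unique")
        for name, tbl in (("total", self.area_total), ("reported", self.area_reported)):
            if not tbl.index.equals(self.info.index):
                raise ValueError(f"area_{name} index does not match region info")
            if (tbl.to_numpy() < 0).any():
                raise ValueError(f"negative {name} crop area")
        if (self.area_reported.to_numpy() - self.area_total.to_numpy() > 1e-9).any():
            raise ValueError("reported-coverage area exceeds total area")

    @property
    def region_ids(self) -> pd.Index:
        return self.info.index

    @property
    def crop_codes(self) -> list[str]:
        return list(self.area_total.columns)

    def countries(self) -> list[str]:
        return sorted(self.info["country"].unique())

    def regions_of(self, scope: str) -> pd.Index:
        """Region ids covered by a scope (country code, province id or region id)."""
        if scope in self.info.index:
            return pd.Index([scope])
        mask = (self.info["country"] == scope) | (self.info["province"] == scope)
        return self.info.index[mask]

    def areas(self, variant: str) -> pd.DataFrame:
        if variant == "total":
            return self.area_total
        if variant == "reported":
            return self.area_reported
        raise ValueError(f"unknown area variant {variant!r}")


@dataclass(frozen=True)
class ReportingScheme:
    """How each country reports use: spatial resolution, crop gaps, absences."""

    resolution: Mapping[str, str]                     # country -> level
    unreported_crops: Mapping[str, frozenset] = field(default_factory=dict)
    nonreporting: frozenset = frozenset()

    def __post_init__(self) -> None:
        bad = {r for r in self.resolution.values() if r not in RESOLUTIONS}
        if bad:
            raise ValueError(f"unknown resolution level(s): {sorted(bad)}")

    @property
    def reporting_countries(self) -> tuple[str, ...]:
        return tuple(sorted(self.resolution))

    def validate_against(self, regions: RegionTable) -> None:
        known = set(regions.countries())
        unknown = set(self.resolution) - known
        if unknown:
            raise ValueError(f"reporting countries not in landscape: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth use process behind a synthetic scenario.

    Regional use of a substance is dose x area per crop group, optionally
    modulated by a multiplicative climate term and log-normal noise.
    """

    dose_per_group: Mapping[tuple[str, str], float]   # (substance, group) -> kg/ha
    climate_coefs: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    country_dose_multiplier: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )  # (country, substance) -> factor, default 1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(d < 0 for d in self.dose_per_group.values()):
            raise ValueError("doses must be non-negative")
        by_substance: dict[str, float] = {}
        for (s, _g), d in self.dose_per_group.items():
            by_substance[s] = by_substance.get(s, 0.0) + d
        lifeless = [s for s, tot in by_substance.items() if tot <= 0]
        if lifeless:
            raise ValueError(f"substances with no positive dose: {sorted(lifeless)}")

    @property
    def substances(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.dose_per_group}))

    def doses_of(self, substance: str) -> dict[str, float]:
        return {
            g: d for (s, g), d in self.dose_per_group.items() if s == substance
        }


class AuthorizationMatrix:
    """Country x substance authorization flags with an explicit default.

    Pairs absent from the table fall back to ``default`` (authorized, by
    default -- only known non-authorizations are masked); fallbacks are
    counted for audit.
    """

    def __init__(self, table: pd.DataFrame, default: bool = True) -> None:
        if table.isna().any().any():
            raise ValueError("authorization table contains missing values")
        self.table = table.astype(bool)
        self.default = bool(default)
        self.fallback_count = 0

    def is_authorized(self, country: str, substance_id: str) -> bool:
        if country in self.table.index and substance_id in self.table.columns:
            return bool(self.table.loc[country, substance_id])
        self.fallback_count += 1
        return self.default

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AuthorizationMatrix)
            and self.default == other.default
            and self.table.sort_index(axis=0)
            .sort_index(axis=1)
            .equals(other.table.sort_index(axis=0).sort_index(axis=1))
        )


@dataclass
class DesignMatrix:
    """Calibration design for one substance x land-cover class.

    Rows are calibration regions; ``X`` stacks crop-group area predictors
    (ha) and retained climate features; ``y`` is the disaggregated use (kg).
    """

    substance_id: str
    lcc: str
    X: pd.DataFrame
    y: pd.Series
    country: pd.Series
    crop_columns: list[str]
    climate_columns: list[str]

    def __post_init__(self) -> None:
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("design matrix contains missing values")
        if self.X.shape[1] == 0:
            raise ValueError("design matrix has no predictors")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate predictor names")
        if not (self.X.index.equals(self.y.index) and self.X.index.equals(self.country.index)):
            raise ValueError("misaligned design components")

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, rows: pd.Index) -> "DesignMatrix":
        return DesignMatrix(
            self.substance_id,
            self.lcc,
            self.X.loc[rows],
            self.y.loc[rows],
            self.country.loc[rows],
            self.crop_columns,
            self.climate_columns,
        )


@dataclass
class FittedModel:
    """One fitted regression of the M1-M6 cascade for a substance x class."""

    model_id: str
    intercept: float
    coef: pd.Series                 # indexed by predictor name
    aic: float
    resid_sd: float
    n_obs: int
    extrapolable: bool = True
    country_specific: bool | None = None
    country_effects: Mapping[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.coef.index)

    @property
    def has_negative_coef(self) -> bool:
        return bool((self.coef < 0).any())

    def predict(self, X: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.coef.index if c not in X.columns]
        if missing:
            raise ValueError(f"predictor columns missing from input: {missing}")
        vals = X[list(self.coef.index)].to_numpy(dtype=float) @ self.coef.to_numpy()
        return pd.Series(vals + self.intercept, index=X.index, name="predicted_kg")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coef"] = {k: float(v) for k, v in self.coef.items()}
        d["country_effects"] = dict(self.country_effects)
        d.pop("diagnostics")
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedModel":
        d = dict(d)
        d["coef"] = pd.Series(d["coef"], dtype=float)
        return cls(**d)


REASON_CODES = (
    "ineligible",
    "country_specific_only",
    "cv_fail",
    "negative_coefs->M6",
    "outliers->M5",
    "accepted_M4",
    "accepted_base",
)


@dataclass(frozen=True)
class CascadeDecision:
    """Outcome of the model-selection cascade for one substance x class."""

    substance_id: str
    lcc: str
    model_id: str          # "M1".."M6" or "excluded"
    reason: str
    cv_nse: float | None = None
    country_specific: bool | None = None

    def __post_init__(self) -> None:
        if self.reason not in REASON_CODES:
            raise ValueError(f"unknown reason code {self.reason!r}")

    @property
    def excluded(self) -> bool:
        return self.model_id == "excluded"


@dataclass
class CVReport:
    """Cross-validation record for one substance x class x model.

    ``fold_metrics`` has one row per (repetition, fold) with the five
    goodness-of-fit metrics; ``predictions`` holds the held-out prediction of
    every observation in every repetition, so each observation is validated
    exactly ``repetitions`` times.
    """

    substance_id: str
    lcc: str
    model_id: str
    k: int
    repetitions: int
    seed: int | None
    fold_metrics: pd.DataFrame
    predictions: pd.DataFrame       # index: observation id, columns: repetition
    observed: pd.Series
    normalizer: str = "mean"        # denominator convention for NRMSE / NMAE

    def pooled_metrics(self) -> pd.DataFrame:
        """Metrics of pooled held-out predictions, one row per repetition."""
        from . import evaluation

        rows = {}
        for rep in self.predictions.columns:
            rows[rep] = evaluation.compute_metrics(
                self.observed, self.predictions[rep]
            )
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(self) -> dict[str, float]:
        """Mean over repetitions of the pooled held-out metrics."""
        pooled = self.pooled_metrics()
        return {k: float(np.nanmean(pooled[k].to_numpy(dtype=float))) for k in pooled}
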