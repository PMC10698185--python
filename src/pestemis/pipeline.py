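"""End-to-end orchestration: calibrate the cascade and extrapolate.

This is the glue the CLI and the acceptance checks drive: harmonized
reports in, emission estimates out, with every intermediate artefact
(calibration table, designs, decisions, fitted models, audit) kept for
inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

from . import disaggregation, evaluation, features, ingestion, models, prediction
from .datatypes import (
    AuthorizationMatrix,
    CascadeDecision,
    DesignMatrix,
    FittedModel,
    RegionTable,
    SubstanceProfile,
)


@dataclass
class PipelineResult:
    """Everything one calibration + extrapolation run produces."""

    calibration: pd.DataFrame
    retained_climate: list[str]
    designs: dict[tuple[str, str], DesignMatrix]
    decisions: list[CascadeDecision]
    final_models: dict[tuple[str, str], FittedModel]
    audit: dict[tuple[str, str], dict]
    predictions: pd.DataFrame          # long: region_id, country, substance_id, lcc, kg
    emissions: pd.DataFrame            # published schema
    emissions_detailed: pd.DataFrame   # per-class companion
    eligible: list[str] = field(default_factory=list)

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "substance_id": d.substance_id,
                    "lcc": d.lcc,
                    "model_id": d.model_id,
                    "reason": d.reason,
                    "cv_nse": d.cv_nse,
                    "country_specific": d.country_specific,
                }
                for d in self.decisions
            ]
        )


def run_pipeline(
    regions: RegionTable,
    climate_cells: pd.DataFrame,
    reports: pd.DataFrame,
    catalog: Mapping[str, SubstanceProfile],
    auth: AuthorizationMatrix,
    grouping: Mapping[str, str] | None = None,
    group_to_class: Mapping[str, str] | None = None,
    *,
    policy: models.CascadePolicy | None = None,
    correlation_threshold: float = 0.9,
) -> PipelineResult:
    """Calibrate the cascade on reported use and extrapolate to all regions.

    Steps: average reports over years, filter eligible substances,
    disaggregate reports to (region, substance, class) on reported-coverage
    extents, build climate features and prune collinear ones, assemble one
    design per substance x class, run the decision cascade, extrapolate the
    accepted models on total extents, mask non-authorized pairs and
    assemble the output table.
    """
    policy = policy or models.CascadePolicy()
    reports = ingestion.average_over_years(reports)
    eligible = models.eligibility_filter(
        reports, substances=catalog, min_countries=policy.min_countries
    )
    _log_category_shares(reports, catalog)

    calibration = disaggregation.build_calibration_table(
        reports, regions, catalog, grouping, group_to_class, area_variant="reported"
    )

    climate_features = features.summarize_climate(climate_cells)
    retained = features.prune_correlated(
        climate_features, threshold=correlation_threshold
    )
    grouped_reported = features.group_crops(regions.area_reported, grouping)
    grouped_total = features.group_crops(regions.area_total, grouping)

    designs: dict[tuple[str, str], DesignMatrix] = {}
    decisions: list[CascadeDecision] = []
    final_models: dict[tuple[str, str], FittedModel] = {}
    audit: dict[tuple[str, str], dict] = {}
    for sid in eligible:
        profile = catalog[sid]
        for lcc in profile.classes:
            design = features.assemble_design(
                calibration, sid, lcc, profile, regions, grouped_reported,
                climate_features, retained, group_to_class,
            )
            if design is None:
                continue
            decision, final, a = models.run_cascade(design, policy)
            designs[(sid, lcc)] = design
            decisions.append(decision)
            audit[(sid, lcc)] = a
            if final is not None:
                final_models[(sid, lcc)] = final

    predictors = pd.concat([grouped_total, climate_features], axis=1)
    pred_rows = []
    for (sid, lcc), model in final_models.items():
        yhat = prediction.extrapolate(model, predictors)
        pred_rows.append(
            pd.DataFrame(
                {
                    "region_id": yhat.index,
                    "country": regions.info["country"].to_numpy(),
                    "substance_id": sid,
                    "lcc": lcc,
                    "kg": yhat.to_numpy(),
                }
            )
        )
    if pred_rows:
        predictions = pd.concat(pred_rows, ignore_index=True)
        predictions = prediction.apply_authorization(predictions, auth)
        emissions, detailed = prediction.assemble_dataset(
            predictions, catalog, regions
        )
    else:
        predictions = pd.DataFrame(
            columns=["region_id", "country", "substance_id", "lcc", "kg"]
        )
        emissions = pd.DataFrame(columns=prediction.OUTPUT_COLUMNS)
        detailed = pd.DataFrame()

    return PipelineResult(
        calibration=calibration,
        retained_climate=retained,
        designs=designs,
        decisions=decisions,
        final_models=final_models,
        audit=audit,
        predictions=predictions,
        emissions=emissions,
        emissions_detailed=detailed,
        eligible=eligible,
    )


def _log_category_shares(
    reports: pd.DataFrame, catalog: Mapping[str, SubstanceProfile]
) -> None:
    """Log which substances exceed 1% by weight of their product category.

    Commonly used substances dominate their category's total; the share is
    informative for interpreting model quality but does not influence the
    selection policy.
    """
    known = reports[reports["substance_id"].isin(catalog)]
    if len(known) == 0:
        return
    totals = known.groupby("substance_id")["kg"].sum()
    cat = pd.Series({s: catalog[s].category for s in totals.index})
    cat_totals = totals.groupby(cat).sum()
    for s, kg in totals.items():
        denom = cat_totals[cat[s]]
        share = kg / denom if denom > 0 else 0.0
        if share > 0.01:
            logger.info(
                "substance %s: %.1f%% by weight of category %r",
                s, 100 * share, cat[s],
            )


def evaluate_result(
    result: PipelineResult,
    *,
    k: int = 10,
    repetitions: int = 100,
    seed: int = 0,
    policy: models.CascadePolicy | None = None,
) -> pd.DataFrame:
    """Repeated k-fold and country-wise CV of every final model.

    Returns a summary with one row per substance x class x scheme; the
    NRMSE/NMAE normalizer (mean of observed) is recorded in every row.
    """
    policy = policy or models.CascadePolicy()
    rows = []
    for (sid, lcc), model in result.final_models.items():
        design = result.designs[(sid, lcc)]
        recipe = models.model_recipe(model.model_id, model.feature_names, policy)
        kk = min(k, design.n)
        rep = evaluation.repeated_kfold(
            design, recipe, k=kk, repetitions=repetitions, seed=seed
        )
        rows.append(
            {"substance_id": sid, "lcc": lcc, "model_id": model.model_id,
             "scheme": f"{kk}-fold x {repetitions}", "normalizer": "mean(observed)"}
            | rep.summary()
        )
        if design.country.nunique() >= 2:
            loco = evaluation.leave_one_country_out(design, recipe)
            rows.append(
                {"substance_id": sid, "lcc": lcc, "model_id": model.model_id,
                 "scheme": "leave-one-country-out",
                 "normalizer": "mean(observed)"}
                | loco.summary()
            )
    return pd.DataFrame(rows)
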