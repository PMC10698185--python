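"""Goodness-of-fit metrics and cross-validation.

Five normalized metrics are used throughout, so that substances with very
different absolute use levels are comparable:

* SMAPE — symmetric mean absolute error, ``mean(2|yhat - y| / (|y| + |yhat|))``
  on the [0, 2] scale, with 0/0 terms counted as 0;
* NSE — Nash-Sutcliffe efficiency, ``1 - sum((y - yhat)^2) / sum((y - ybar)^2)``;
  positive values mean the model beats predicting the observed mean;
* NRMSE — root mean squared error divided by mean(observed);
* NMAE — mean absolute error divided by mean(observed);
* R2 — squared Pearson correlation of observed and predicted.

Model quality is assessed by repeated k-fold cross-validation (every
observation held out exactly ``repetitions`` times) and by
leave-one-country-out cross-validation, which probes whether a country's
use pattern can be predicted from the other countries' data alone.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .datatypes import CVReport, DesignMatrix, FittedModel

METRIC_NAMES = ("smape", "nse", "nrmse", "r2", "nmae")


def compute_metrics(observed, predicted) -> dict[str, float]:
    """The five goodness-of-fit metrics for one observed/predicted pair.

    Metrics whose denominator is degenerate (NSE with constant
    observations, R2 with a constant vector, NRMSE/NMAE with zero mean
    observed) are reported as NaN ("missing") rather than raising.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need 1-d vectors of length >= 2")

    denom = np.abs(y) + np.abs(yhat)
    terms = np.where(denom > 0, 2.0 * np.abs(yhat - y) / np.where(denom > 0, denom, 1.0), 0.0)
    smape = float(np.mean(terms))

    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    nse = 1.0 - sse / sst if sst > 0 else float("nan")

    mean_y = float(y.mean())
    rmse = float(np.sqrt(sse / len(y)))
    mae = float(np.mean(np.abs(y - yhat)))
    nrmse = rmse / mean_y if mean_y != 0 else float("nan")
    nmae = mae / mean_y if mean_y != 0 else float("nan")

    if y.std() > 0 and yhat.std() > 0:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return {"smape": smape, "nse": nse, "nrmse": nrmse, "r2": r2, "nmae": nmae}


def repeated_kfold(
    design: DesignMatrix,
    recipe: Callable[[DesignMatrix], FittedModel],
    k: int = 10,
    repetitions: int = 100,
    seed: int = 0,
) -> CVReport:
    """Repeated k-fold cross-validation of a model recipe.

    Within each repetition the folds partition the rows (disjoint,
    exhaustive, sizes differing by at most one); the model is refit on the
    k-1 training folds and evaluated on the held-out fold.  Every
    observation is therefore validated exactly ``repetitions`` times.  Fold
    shuffling is seeded: identical seeds give identical assignments,
    predictions and metrics.
    """
    n = design.n
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    if k < 2:
        raise ValueError("k must be >= 2")

    fold_rows = []
    preds = pd.DataFrame(
        np.nan, index=design.X.index, columns=pd.RangeIndex(repetitions, name="repetition")
    )
    for rep in range(repetitions):
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(design.X)):
            train = design.subset(design.X.index[train_idx])
            test_rows = design.X.index[test_idx]
            model = recipe(train)
            p = model.predict(design.X.loc[test_rows])
            preds.loc[test_rows, rep] = p.to_numpy()
            row = {"repetition": rep, "fold": fold, "n": len(test_rows)}
            if len(test_rows) >= 2:  # single-row folds (k = n) have no fold metric
                row.update(compute_metrics(design.y.loc[test_rows], p))
            fold_rows.append(row)
    model_id = recipe(design).model_id
    return CVReport(
        substance_id=design.substance_id,
        lcc=design.lcc,
        model_id=model_id,
        k=k,
        repetitions=repetitions,
        seed=seed,
        fold_metrics=pd.DataFrame(fold_rows),
        predictions=preds,
        observed=design.y.copy(),
    )


def leave_one_country_out(
    design: DesignMatrix,
    recipe: Callable[[DesignMatrix], FittedModel],
) -> CVReport:
    """Country-wise cross-validation: one fold per country.

    Predictions for a country's regions are made by a model fitted without
    any row of that country; the per-country metric block shows whether a
    country's use pattern departs from the rest.
    """
    countries = sorted(design.country.unique())
    if len(countries) < 2:
        raise ValueError("leave-one-country-out needs at least two countries")
    preds = pd.DataFrame(
        np.nan, index=design.X.index, columns=pd.RangeIndex(1, name="repetition")
    )
    fold_rows = []
    for fold, ctry in enumerate(countries):
        held = design.X.index[design.country == ctry]
        train = design.subset(design.X.index[design.country != ctry])
        model = recipe(train)
        p = model.predict(design.X.loc[held])
        preds.loc[held, 0] = p.to_numpy()
        row = {"repetition": 0, "fold": fold, "country": ctry, "n": len(held)}
        if len(held) >= 2:
            row.update(compute_metrics(design.y.loc[held], p))
        fold_rows.append(row)
    model_id = recipe(design).model_id
    return CVReport(
        substance_id=design.substance_id,
        lcc=design.lcc,
        model_id=model_id,
        k=len(countries),
        repetitions=1,
        seed=None,
        fold_metrics=pd.DataFrame(fold_rows),
        predictions=preds,
        observed=design.y.copy(),
    )


def compare_external(
    estimates: pd.DataFrame,
    reference: pd.DataFrame,
    group_keys: Sequence[str],
    *,
    estimate_col: str = "kg",
    reference_col: str = "kg",
) -> pd.DataFrame:
    """Compare modelled estimates with an external reference table.

    Both inputs are joined on ``group_keys`` plus their shared finer keys
    (whatever identifies an entry).  Per group the report contains the
    summed modelled and reported kilograms, their ratio (a ratio of 2 means
    the model predicts twice the reported amount), the median and median
    absolute deviation of ``log10(modelled + 1) - log10(reported + 1)``
    across entries, and the fraction of entries within one order of
    magnitude (|log10 difference| <= 1, boundary inclusive).
    """
    join_keys = [c for c in estimates.columns if c in reference.columns
                 and c not in (estimate_col, reference_col)]
    if not join_keys:
        raise ValueError("no shared key columns to join on")
    est = estimates.rename(columns={estimate_col: "modeled"})
    ref = reference.rename(columns={reference_col: "reported"})
    merged = est.merge(ref, on=join_keys, how="inner")
    if len(merged) == 0:
        raise ValueError("no overlapping keys between estimates and reference")
    missing = [k for k in group_keys if k not in merged.columns]
    if missing:
        raise ValueError(f"group key(s) not present after join: {missing}")

    merged["log_dev"] = np.log10(merged["modeled"] + 1.0) - np.log10(
        merged["reported"] + 1.0
    )
    out_rows = []
    for keys, grp in merged.groupby(list(group_keys)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        modeled = float(grp["modeled"].sum())
        reported = float(grp["reported"].sum())
        dev = grp["log_dev"].to_numpy()
        med = float(np.median(dev))
        out_rows.append(
            dict(zip(group_keys, keys))
            | {
                "modeled": modeled,
                "reported": reported,
                "ratio": modeled / reported if reported > 0 else float("nan"),
                "median_log_dev": med,
                "mad_log_dev": float(np.median(np.abs(dev - med))),
                "frac_within_oom": float(np.mean(np.abs(dev) <= 1.0)),
                "n": len(grp),
            }
        )
    return pd.DataFrame(out_rows)
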