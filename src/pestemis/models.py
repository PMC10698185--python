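"""The M1-M6 regression cascade and the model-selection policy.

For each eligible substance x land-cover class, use (kg) is regressed on
crop-group areas and retained climate features with a cascade of linear
model variants:

* M1 — ordinary least squares on the applicable crop-area predictors;
* M2 — M1 after stepwise AIC reduction of the crop predictors (only
  worthwhile on arable land, where up to ten crop groups compete);
* M3 — the M2/M1 predictor set plus a categorical country effect; used
  only to diagnose country-specific use patterns, never to extrapolate;
* M4 — stepwise AIC addition of climate features on top of the crop terms
  (crop terms protected, at most four climate terms by default);
* M5 — Huber robust regression (IRLS, tuning constant 1.345, MAD scale),
  to damp the influence of outlying regions;
* M6 — non-negative least squares through the origin: coefficients may
  not be negative and the intercept is suppressed, since applying a
  substance on zero agricultural area is not physically meaningful.

A deterministic decision policy walks this cascade and returns exactly one
decision (a chosen model, or an exclusion with a reason code) per
substance x class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import statsmodels.api as sm

from . import landcover
from .datatypes import CascadeDecision, DesignMatrix, FittedModel

_AIC_RSS_FLOOR = 1e-30


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge."""


def aic_from_rss(n: int, rss: float, n_params: int, floor: float | None = None) -> float:
    """AIC on the least-squares log-likelihood scale: n ln(RSS/n) + 2(k+1).

    ``n_params`` counts every fitted mean parameter (intercept included);
    the +1 accounts for the residual variance.  RSS is floored (by default
    at ``floor``, a scale-aware tiny value) to keep the criterion finite
    and meaningful on numerically interpolating fits: two fits that both
    interpolate differ only by the parameter-count penalty.
    """
    floor = _AIC_RSS_FLOOR if floor is None else max(floor, _AIC_RSS_FLOOR)
    return n * np.log(max(rss, floor) / n) + 2 * (n_params + 1)


def _rss_floor(y: pd.Series | np.ndarray) -> float:
    yy = float(np.asarray(y, dtype=float) @ np.asarray(y, dtype=float))
    return 1e-16 * yy


def _independent_columns(X: pd.DataFrame) -> list[str]:
    """Maximal linearly independent column subset (QR with pivoting)."""
    mat = X.to_numpy(dtype=float)
    if mat.shape[1] == 0:
        return []
    _, r, piv = scipy.linalg.qr(mat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r)) if r.ndim == 2 else np.abs(r[:1])
    tol = max(mat.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 0.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    return [X.columns[i] for i in keep]


def _prepare(X: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    Xs = X[list(features)]
    kept = _independent_columns(Xs)
    if len(kept) < len(features):
        dropped = [c for c in features if c not in kept]
        warnings.warn(f"dropping aliased predictor column(s): {dropped}", stacklevel=3)
        Xs = Xs[kept]
    return Xs


def _ols_fit(
    X: pd.DataFrame,
    y: pd.Series,
    features: Sequence[str],
    model_id: str,
    *,
    intercept: bool = True,
) -> FittedModel:
    Xs = _prepare(X, features)
    exog = sm.add_constant(Xs.to_numpy(dtype=float), has_constant="add") if intercept \
        else Xs.to_numpy(dtype=float)
    res = sm.OLS(y.to_numpy(dtype=float), exog).fit()
    params = res.params
    if intercept:
        beta0, beta = float(params[0]), params[1:]
    else:
        beta0, beta = 0.0, params
    n, p = len(y), len(params)
    rss = float(res.ssr)
    resid_sd = float(np.sqrt(rss / max(n - p, 1)))
    return FittedModel(
        model_id=model_id,
        intercept=beta0,
        coef=pd.Series(beta, index=Xs.columns, dtype=float),
        aic=aic_from_rss(n, rss, p, floor=_rss_floor(y)),
        resid_sd=resid_sd,
        n_obs=n,
        diagnostics={"rss": rss, "sm_results": res, "exog_columns": list(Xs.columns)},
    )


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def eligibility_filter(
    reports: pd.DataFrame, substances: Iterable[str] | None = None,
    min_countries: int = 4,
) -> list[str]:
    """Substances with strictly positive reported use in enough countries.

    A substance is eligible when at least ``min_countries`` distinct
    reporting countries report a positive amount for it (explicit zero
    reports do not count).
    """
    pos = reports[reports["kg"] > 0]
    counts = pos.groupby("substance_id")["country"].nunique()
    pool = set(substances) if substances is not None else set(reports["substance_id"])
    return sorted(s for s in pool if counts.get(s, 0) >= min_countries)


# ---------------------------------------------------------------------------
# M1 / M2 (stepwise AIC)
# ---------------------------------------------------------------------------

def fit_m1(design: DesignMatrix) -> FittedModel:
    """OLS of use on the applicable crop-area predictors."""
    return _ols_fit(design.X, design.y, design.crop_columns, "M1")


def stepwise_aic(
    X: pd.DataFrame,
    y: pd.Series,
    candidates: Sequence[str],
    forced: Sequence[str] = (),
    *,
    start: str = "full",
    max_candidates: int | None = None,
    model_id: str = "M2",
) -> FittedModel:
    """Bidirectional stepwise selection minimizing AIC.

    ``forced`` terms are always kept; ``candidates`` may be added or
    removed.  ``start`` is "full" (all candidates in) or "forced"
    (candidates out).  ``max_candidates`` caps how many candidates the
    model may contain at once.  Every accepted step strictly decreases the
    AIC, so the result's AIC never exceeds the starting model's.
    """
    forced = [c for c in forced if c in X.columns]
    candidates = [c for c in candidates if c in X.columns and c not in forced]
    current = list(candidates) if start == "full" else []

    def fit(feats: list[str]) -> FittedModel:
        return _ols_fit(X, y, list(forced) + feats, model_id)

    best = fit(current)
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, list[str], FittedModel]] = []
        for c in current:  # removals
            feats = [f for f in current if f != c]
            m = fit(feats)
            moves.append((m.aic, feats, m))
        if max_candidates is None or len(current) < max_candidates:
            for c in candidates:  # additions
                if c in current:
                    continue
                feats = current + [c]
                m = fit(feats)
                moves.append((m.aic, feats, m))
        if moves:
            aic, feats, m = min(moves, key=lambda t: t[0])
            if aic < best.aic - 1e-10:
                best, current, improved = m, feats, True
    return best


def fit_m2(design: DesignMatrix) -> FittedModel:
    """Stepwise-AIC reduction of the crop predictor set."""
    return stepwise_aic(design.X, design.y, design.crop_columns, model_id="M2")


def select_stepaic(design: DesignMatrix, scope: str = "crop") -> FittedModel:
    """Stepwise AIC over the crop or climate predictors of a design."""
    if scope == "crop":
        return fit_m2(design)
    if scope == "climate":
        return stepwise_aic(
            design.X, design.y, design.climate_columns,
            forced=design.crop_columns, start="forced", model_id="M4",
        )
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# M3: country effect (diagnostic only)
# ---------------------------------------------------------------------------

def fit_m3(
    design: DesignMatrix,
    base: FittedModel,
    delta_aic: float = 2.0,
) -> FittedModel:
    """Base predictors plus a categorical country block.

    The country-specificity verdict is positive when the country-augmented
    model improves the base AIC by more than ``delta_aic``.  The fitted
    model is flagged non-extrapolable: per-country intercept shifts have no
    meaning in countries with no data.
    """
    if design.country.nunique() < 2:
        raise ValueError("country-effect model needs data from at least two countries")
    dummies = pd.get_dummies(design.country, prefix="country", drop_first=True,
                             dtype=float)
    Xc = pd.concat([design.X, dummies], axis=1)
    feats = base.feature_names + list(dummies.columns)
    m = _ols_fit(Xc, design.y, feats, "M3")
    effects = {c: float(m.coef[c]) for c in dummies.columns if c in m.coef.index}
    coef = m.coef.drop(labels=[c for c in dummies.columns if c in m.coef.index])
    return FittedModel(
        model_id="M3",
        intercept=m.intercept,
        coef=coef,
        aic=m.aic,
        resid_sd=m.resid_sd,
        n_obs=m.n_obs,
        extrapolable=False,
        country_specific=bool(m.aic < base.aic - delta_aic),
        country_effects=effects,
        diagnostics=m.diagnostics,
    )


# ---------------------------------------------------------------------------
# M4: climate augmentation
# ---------------------------------------------------------------------------

def fit_m4(
    design: DesignMatrix,
    base: FittedModel | None = None,
    climate_cap: int = 4,
) -> FittedModel:
    """Stepwise climate augmentation with the crop terms protected.

    Starts from the (selected) crop terms and lets stepwise AIC add at most
    ``climate_cap`` climate features.  With no climate candidates this
    degenerates to the base crop model.
    """
    crop_feats = (
        [f for f in base.feature_names if f in design.crop_columns]
        if base is not None
        else design.crop_columns
    )
    return stepwise_aic(
        design.X, design.y, design.climate_columns, forced=crop_feats,
        start="forced", max_candidates=climate_cap, model_id="M4",
    )


# ---------------------------------------------------------------------------
# M5: robust (Huber) regression
# ---------------------------------------------------------------------------

def fit_m5(
    design: DesignMatrix,
    features: Sequence[str] | None = None,
    *,
    huber_t: float = 1.345,
    maxiter: int = 200,
    tol: float = 1e-8,
) -> FittedModel:
    """Huber M-estimation via IRLS with MAD scale.

    Raises :class:`ConvergenceError` when the coefficient iteration does
    not converge within ``maxiter`` iterations.
    """
    feats = list(features) if features is not None else design.crop_columns
    Xs = _prepare(design.X, feats)
    exog = sm.add_constant(Xs.to_numpy(dtype=float), has_constant="add")
    rlm = sm.RLM(design.y.to_numpy(dtype=float), exog,
                 M=sm.robust.norms.HuberT(t=huber_t))
    res = rlm.fit(maxiter=maxiter, tol=tol, conv="coefs", scale_est="mad")
    iterations = int(res.fit_history.get("iteration", 0))
    if iterations >= maxiter:
        raise ConvergenceError(
            f"Huber IRLS did not converge in {maxiter} iterations "
            f"(last coefficient sets: {res.fit_history['params'][-3:]})"
        )
    params = res.params
    resid = design.y.to_numpy(dtype=float) - exog @ params
    rss = float(resid @ resid)
    n, p = len(design.y), len(params)
    return FittedModel(
        model_id="M5",
        intercept=float(params[0]),
        coef=pd.Series(params[1:], index=Xs.columns, dtype=float),
        aic=aic_from_rss(n, rss, p, floor=_rss_floor(design.y)),
        resid_sd=float(np.sqrt(rss / max(n - p, 1))),
        n_obs=n,
        diagnostics={
            "rss": rss,
            "weights": pd.Series(res.weights, index=design.X.index),
            "iterations": iterations,
        },
    )


# ---------------------------------------------------------------------------
# M6: non-negative least squares through the origin
# ---------------------------------------------------------------------------

def fit_m6(
    design: DesignMatrix,
    features: Sequence[str] | None = None,
    *,
    intercept_mode: str = "zero",
) -> FittedModel:
    """Least squares with non-negative coefficients and suppressed intercept.

    The default fixes the intercept at zero (zero agricultural area implies
    zero application); ``intercept_mode="nonneg"`` instead includes a free
    intercept constrained to be non-negative.
    """
    feats = list(features) if features is not None else design.crop_columns
    Xs = _prepare(design.X, feats)
    cols = list(Xs.columns)
    mat = Xs.to_numpy(dtype=float)
    if intercept_mode == "nonneg":
        mat = np.column_stack([np.ones(len(Xs)), mat])
    elif intercept_mode != "zero":
        raise ValueError(f"unknown intercept_mode {intercept_mode!r}")
    yv = design.y.to_numpy(dtype=float)
    beta, _ = scipy.optimize.nnls(mat, yv)
    if intercept_mode == "nonneg":
        beta0, coefs = float(beta[0]), beta[1:]
    else:
        beta0, coefs = 0.0, beta
    resid = yv - mat @ beta
    rss = float(resid @ resid)
    n, p = len(yv), len(beta)
    return FittedModel(
        model_id="M6",
        intercept=beta0,
        coef=pd.Series(coefs, index=cols, dtype=float),
        aic=aic_from_rss(n, rss, p, floor=_rss_floor(design.y)),
        resid_sd=float(np.sqrt(rss / max(n - p, 1))),
        n_obs=n,
        diagnostics={"rss": rss},
    )


def kkt_max_violation(
    X: pd.DataFrame, y: pd.Series, model: FittedModel
) -> float:
    """Largest KKT violation of a non-negativity-constrained fit.

    For active coefficients (beta_j > 0) the gradient component of the RSS
    must vanish; for coefficients at the bound it must be non-negative.
    Returns the largest violation magnitude (0 for an exact KKT point).
    """
    Xs = X[model.feature_names].to_numpy(dtype=float)
    resid = y.to_numpy(dtype=float) - Xs @ model.coef.to_numpy() - model.intercept
    grad = -2.0 * Xs.T @ resid
    beta = model.coef.to_numpy()
    scale = max(1.0, float(np.abs(Xs.T @ y.to_numpy(dtype=float)).max()))
    viol = np.where(beta > 0, np.abs(grad), np.maximum(0.0, -grad))
    return float(viol.max() / scale) if len(viol) else 0.0


# ---------------------------------------------------------------------------
# outlier diagnosis
# ---------------------------------------------------------------------------

def detect_outliers(
    design: DesignMatrix,
    m4: FittedModel,
    m5: FittedModel,
    *,
    cooks_factor: float = 4.0,
    band_sds: float = 1.0,
) -> list[str]:
    """Regions whose observations dominate the fit.

    A region is flagged when its Cook's distance under the (OLS) M4 fit
    exceeds ``cooks_factor / n`` (the usual screening threshold for
    influential points) *and* the M4 and M5 predictions for it differ by
    more than ``band_sds`` robust residual sds of M4 (MAD-based, so a
    gross outlier cannot inflate its own detection band).  The screening
    step alone would flag a few percent of perfectly clean observations;
    requiring the robust/least-squares disagreement confirms that the
    point actually distorts the fit.  Flags are reported; rows are never
    deleted.
    """
    scale = float(np.abs(design.y).mean()) + 1e-12
    if m4.resid_sd <= 1e-10 * scale:
        # numerically interpolating fit: no observation can be influential
        return []
    res = m4.diagnostics.get("sm_results")
    if res is None:
        refit = _ols_fit(design.X, design.y, m4.feature_names, m4.model_id)
        res = refit.diagnostics["sm_results"]
    cooks = res.get_influence().cooks_distance[0]
    n = design.n
    pred4 = m4.predict(design.X).to_numpy()
    pred5 = m5.predict(design.X).to_numpy()
    resid4 = design.y.to_numpy() - pred4
    robust_sd = 1.4826 * float(np.median(np.abs(resid4 - np.median(resid4))))
    band = band_sds * max(robust_sd, 1e-8 * scale)
    flagged = (cooks > cooks_factor / n) & (np.abs(pred4 - pred5) > band)
    return [str(r) for r in design.X.index[flagged]]


# ---------------------------------------------------------------------------
# cascade policy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CascadePolicy:
    """Thresholds of the deterministic model-selection policy."""

    min_countries: int = 4        # eligibility: countries with positive use
    delta_aic: float = 2.0        # evidence margin for a country effect
    climate_cap: int = 4          # max climate terms in M4
    cooks_factor: float = 4.0     # Cook's distance screening threshold = factor / n
    nse_gate: float = 0.0         # exclude models at or below this CV NSE
    intercept_tol_frac: float = 0.1  # |intercept| tolerance, fraction of mean |y|
    huber_t: float = 1.345
    cv_k: int = 10
    cv_repetitions: int = 5
    cv_seed: int = 1


ModelRecipe = Callable[[DesignMatrix], FittedModel]


def model_recipe(
    model_id: str, features: Sequence[str], policy: CascadePolicy | None = None
) -> ModelRecipe:
    """A refit closure for cross-validation: same model family and features."""
    policy = policy or CascadePolicy()
    feats = list(features)

    def refit(d: DesignMatrix) -> FittedModel:
        if model_id == "M5":
            return fit_m5(d, feats, huber_t=policy.huber_t)
        if model_id == "M6":
            return fit_m6(d, feats)
        return _ols_fit(d.X, d.y, feats, model_id)

    return refit


def _cv_nse(design: DesignMatrix, recipe: ModelRecipe, policy: CascadePolicy) -> float:
    from . import evaluation

    k = min(policy.cv_k, design.n)
    report = evaluation.repeated_kfold(
        design, recipe, k=k, repetitions=policy.cv_repetitions,
        seed=policy.cv_seed,
    )
    return report.summary().get("nse", float("nan"))


def run_cascade(
    design: DesignMatrix,
    policy: CascadePolicy | None = None,
) -> tuple[CascadeDecision, FittedModel | None, dict]:
    """Walk the model cascade for one substance x class.

    Returns the decision, the final model (``None`` when excluded) and an
    audit dictionary with the intermediate fits, flagged outlier regions
    and cross-validated NSE values.  The policy is total: every call
    terminates with exactly one decision carrying a reason code.
    """
    policy = policy or CascadePolicy()
    audit: dict = {"models": {}, "outliers": [], "cv_nse": {}}
    arable = design.lcc == landcover.ARABLE

    base = fit_m2(design) if arable and len(design.crop_columns) > 1 else fit_m1(design)
    audit["models"][base.model_id] = base

    country_specific = None
    if design.country.nunique() >= 2:
        m3 = fit_m3(design, base, delta_aic=policy.delta_aic)
        country_specific = m3.country_specific
        audit["models"]["M3"] = m3

    if design.climate_columns:
        m4 = fit_m4(design, base, climate_cap=policy.climate_cap)
    else:
        m4 = None
    if m4 is not None and set(m4.feature_names) - set(base.feature_names):
        candidate, reason_ok = m4, "accepted_M4"
        audit["models"]["M4"] = m4
    else:
        candidate, reason_ok = base, "accepted_base"

    mean_abs_y = float(np.abs(design.y).mean()) + 1e-12
    intercept_tol = policy.intercept_tol_frac * mean_abs_y

    def clean(m: FittedModel) -> bool:
        return not m.has_negative_coef and abs(m.intercept) <= intercept_tol

    final: FittedModel | None = None
    reason = reason_ok
    if not arable:
        nse = _cv_nse(
            design, model_recipe(candidate.model_id, candidate.feature_names, policy),
            policy,
        )
        audit["cv_nse"][candidate.model_id] = nse
        if nse > policy.nse_gate and clean(candidate):
            final = candidate

    if final is None:
        m5 = fit_m5(design, candidate.feature_names, huber_t=policy.huber_t)
        audit["models"]["M5"] = m5
        reference = m4 if m4 is not None else base
        outliers = detect_outliers(
            design, reference, m5, cooks_factor=policy.cooks_factor
        )
        audit["outliers"] = outliers
        if outliers:
            final, reason = m5, "outliers->M5"
        else:
            final, reason = candidate, reason_ok
        if not clean(final):
            final = fit_m6(design, final.feature_names)
            audit["models"]["M6"] = final
            reason = "negative_coefs->M6"

    nse_final = audit["cv_nse"].get(final.model_id)
    if nse_final is None:
        nse_final = _cv_nse(
            design, model_recipe(final.model_id, final.feature_names, policy), policy
        )
        audit["cv_nse"][final.model_id] = nse_final

    if not (nse_final > policy.nse_gate):
        reason = "country_specific_only" if country_specific else "cv_fail"
        decision = CascadeDecision(
            design.substance_id, design.lcc, "excluded", reason,
            cv_nse=nse_final, country_specific=country_specific,
        )
        return decision, None, audit

    decision = CascadeDecision(
        design.substance_id, design.lcc, final.model_id, reason,
        cv_nse=nse_final, country_specific=country_specific,
    )
    final.country_specific = country_specific
    return decision, final, audit
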