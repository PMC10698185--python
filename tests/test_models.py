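"""The regression cascade: fits, oracles, diagnostics and the policy."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pestemis import landcover, models
from conftest import make_design


def _random_design(rng, n=60, p=3, beta=None, sd=1.0, intercept=0.0, lcc="vineyards"):
    X = pd.DataFrame(
        rng.lognormal(mean=3.0, sigma=0.8, size=(n, p)),
        columns=[f"x{i}" for i in range(p)],
        index=[f"R{i:03d}" for i in range(n)],
    )
    beta = np.ones(p) if beta is None else np.asarray(beta, dtype=float)
    y = intercept + X.to_numpy() @ beta + rng.normal(0, sd, size=n)
    return make_design(X, y, lcc=lcc)


class TestEligibility:
    @pytest.mark.parametrize("n_countries,eligible", [(3, False), (4, True), (8, True)])
    def test_retention_boundary_at_four_countries(self, n_countries, eligible):
        reports = pd.DataFrame(
            {
                "country": [f"C{i}" for i in range(8)],
                "substance_id": "S",
                "kg": [1.0] * n_countries + [0.0] * (8 - n_countries),
            }
        )
        out = models.eligibility_filter(reports, ["S"], min_countries=4)
        assert (out == ["S"]) is eligible

    def test_explicit_zero_reports_do_not_count(self):
        reports = pd.DataFrame(
            {"country": ["A", "B", "C", "D"], "substance_id": "S",
             "kg": [1.0, 1.0, 1.0, 0.0]}
        )
        assert models.eligibility_filter(reports, ["S"]) == []


class TestM1:
    def test_exact_recovery_without_noise(self, rng):
        d = _random_design(rng, n=30, p=1, beta=[2.0], sd=0.0)
        m = models.fit_m1(d)
        assert m.coef["x0"] == pytest.approx(2.0, abs=1e-8)
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_normal_equations_hold(self, rng):
        d = _random_design(rng, n=50, p=3, sd=2.0)
        m = models.fit_m1(d)
        resid = d.y.to_numpy() - m.predict(d.X).to_numpy()
        Xc = np.column_stack([np.ones(d.n), d.X.to_numpy()])
        assert np.abs(Xc.T @ resid).max() / d.n < 1e-8 * max(1.0, np.abs(d.y).max())

    def test_matches_pseudo_inverse_oracle_on_small_design(self):
        X = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0, 5.0], "b": [2.0, 1.0, 4.0, 3.0, 6.0]},
            index=list("vwxyz"),
        )
        y = [3.1, 4.0, 9.8, 10.2, 16.0]
        d = make_design(X, y)
        m = models.fit_m1(d)
        Xc = np.column_stack([np.ones(5), X.to_numpy()])
        oracle = np.linalg.pinv(Xc) @ np.asarray(y)
        assert m.intercept == pytest.approx(oracle[0], abs=1e-8)
        assert m.coef.to_numpy() == pytest.approx(oracle[1:], abs=1e-8)

    def test_independent_response_gives_null_coefficients(self, rng):
        d = _random_design(rng, n=200, p=2, beta=[0.0, 0.0], sd=1.0, intercept=5.0)
        m = models.fit_m1(d)
        assert np.abs(m.coef.to_numpy()).max() < 0.05

    def test_aliased_column_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        X["c"] = X["a"] + X["b"]
        d = make_design(X, X["a"] * 2.0)
        with pytest.warns(UserWarning, match="aliased"):
            m = models.fit_m1(d)
        assert len(m.coef) == 2


class TestStepAIC:
    def test_true_predictor_survives_among_noise(self, rng):
        n = 200
        X = pd.DataFrame(
            rng.normal(size=(n, 6)), columns=[f"x{i}" for i in range(6)]
        )
        y = 3.0 * X["x0"] + rng.normal(0, 1.0, size=n)
        d = make_design(X, y)
        m = models.fit_m2(d)
        assert "x0" in m.feature_names
        # exhaustive best-subset oracle by the same AIC
        best_aic, best_set = np.inf, None
        for k in range(7):
            for combo in itertools.combinations(X.columns, k):
                mm = models._ols_fit(X, d.y, list(combo), "M?")
                if mm.aic < best_aic:
                    best_aic, best_set = mm.aic, set(combo)
        assert set(m.feature_names) == best_set
        assert m.aic == pytest.approx(best_aic)

    def test_never_worse_than_full_model(self, rng):
        for trial in range(5):
            n = 50
            X = pd.DataFrame(
                rng.normal(size=(n, 5)), columns=[f"x{i}" for i in range(5)]
            )
            y = rng.normal(size=n)  # pure noise
            d = make_design(X, y)
            full = models._ols_fit(X, d.y, list(X.columns), "full")
            m = models.fit_m2(d)
            assert m.aic <= full.aic + 1e-9

    def test_all_noise_collapses_to_few_terms(self, rng):
        n = 100
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"x{i}" for i in range(5)])
        d = make_design(X, rng.normal(size=n))
        m = models.fit_m2(d)
        assert len(m.feature_names) <= 2


class TestM3:
    def _country_design(self, rng, shifts):
        n_per = 30
        frames, ys, countries = [], [], []
        for ctry, shift in shifts.items():
            X = pd.DataFrame(
                {"area": rng.lognormal(3, 0.7, size=n_per)},
                index=[f"{ctry}{i}" for i in range(n_per)],
            )
            y = 2.0 * X["area"] + shift + rng.normal(0, 1.0, size=n_per)
            frames.append(X)
            ys.append(y)
            countries += [ctry] * n_per
        X = pd.concat(frames)
        return make_design(X, np.concatenate(ys), country=countries)

    def test_detects_injected_country_shifts(self, rng):
        d = self._country_design(rng, {"AAA": 0.0, "BBB": 40.0, "CCC": -35.0})
        base = models.fit_m1(d)
        m3 = models.fit_m3(d, base)
        assert m3.country_specific is True
        assert not m3.extrapolable

    def test_no_country_effect_when_process_is_shared(self, rng):
        d = self._country_design(rng, {"AAA": 0.0, "BBB": 0.0, "CCC": 0.0})
        m3 = models.fit_m3(d, models.fit_m1(d))
        assert m3.country_specific is False

    def test_single_country_design_rejected(self, rng):
        d = _random_design(rng, n=20, p=1)
        with pytest.raises(ValueError, match="two countries"):
            models.fit_m3(d, models.fit_m1(d))


class TestM4:
    def _climate_design(self, rng, effect=0.0, n=120):
        X = pd.DataFrame(
            {
                "area": rng.lognormal(3, 0.7, size=n),
                "clim_a": rng.normal(size=n),
                "clim_b": rng.normal(size=n),
                "clim_c": rng.normal(size=n),
            },
            index=[f"R{i}" for i in range(n)],
        )
        y = 2.0 * X["area"] + effect * X["clim_a"] + rng.normal(0, 1.0, size=n)
        return make_design(
            X, y, crop_columns=["area"],
            climate_columns=["clim_a", "clim_b", "clim_c"],
        )

    def test_simulated_climate_effect_is_retained(self, rng):
        d = self._climate_design(rng, effect=5.0)
        m = models.fit_m4(d, models.fit_m1(d))
        assert "clim_a" in m.feature_names
        assert "area" in m.feature_names  # crop term protected

    def test_climate_cap_enforced(self, rng):
        n = 80
        X = pd.DataFrame(
            rng.normal(size=(n, 7)),
            columns=["area"] + [f"clim_{i}" for i in range(6)],
        )
        clim_cols = [f"clim_{i}" for i in range(6)]
        y = X["area"] + X[clim_cols].sum(axis=1) * 3.0 + rng.normal(0, 0.2, size=n)
        d = make_design(X, y, crop_columns=["area"], climate_columns=clim_cols)
        m = models.fit_m4(d, models.fit_m1(d), climate_cap=4)
        n_climate = len([f for f in m.feature_names if f.startswith("clim")])
        assert n_climate == 4  # all six reduce AIC but the cap binds

    def test_zero_effect_keeps_model_lean(self, rng):
        d = self._climate_design(rng, effect=0.0)
        m = models.fit_m4(d, models.fit_m1(d), climate_cap=4)
        n_climate = len([f for f in m.feature_names if f.startswith("clim")])
        assert n_climate <= 4


class TestM5:
    def test_agrees_with_ols_on_clean_data(self, rng):
        d = _random_design(rng, n=80, p=2, beta=[2.0, 3.0], sd=0.0)
        m1 = models.fit_m1(d)
        m5 = models.fit_m5(d)
        assert m5.coef.to_numpy() == pytest.approx(m1.coef.to_numpy(), abs=1e-6)

    def test_resists_gross_outlier_better_than_ols(self, rng):
        d = _random_design(rng, n=60, p=1, beta=[2.0], sd=0.5)
        y = d.y.copy()
        y.iloc[7] *= 100.0
        d_out = make_design(d.X, y)
        m1 = models.fit_m1(d_out)
        m5 = models.fit_m5(d_out)
        assert abs(m5.coef["x0"] - 2.0) < abs(m1.coef["x0"] - 2.0)

    def test_huber_weights_in_unit_interval_and_downweight_outlier(self, rng):
        d = _random_design(rng, n=60, p=1, beta=[2.0], sd=0.5)
        y = d.y.copy()
        y.iloc[7] *= 100.0
        m5 = models.fit_m5(make_design(d.X, y))
        w = m5.diagnostics["weights"]
        assert (w > 0).all() and (w <= 1).all()
        assert w.iloc[7] < 1.0


class TestM6:
    def test_interior_solution_is_exact(self, rng):
        d = _random_design(rng, n=40, p=1, beta=[2.0], sd=0.0)
        m = models.fit_m6(d)
        assert m.coef["x0"] == pytest.approx(2.0, abs=1e-8)
        assert m.intercept == 0.0

    def test_negative_relationship_pinned_at_zero(self, rng):
        n = 80
        X = pd.DataFrame(
            {"a": rng.lognormal(2, 0.5, size=n), "b": rng.lognormal(2, 0.5, size=n)}
        )
        y = 2.0 * X["a"] - 1.0 * X["b"] + rng.normal(0, 0.1, size=n)
        m = models.fit_m6(make_design(X, y))
        assert m.coef["b"] == 0.0
        assert m.coef["a"] > 0

    def test_matches_active_set_oracle_on_small_design(self, rng):
        # brute-force oracle: best feasible support-restricted LS solution
        X = pd.DataFrame(
            rng.normal(size=(6, 3)) + 2.0, columns=["a", "b", "c"]
        )
        y = X.to_numpy() @ np.array([1.0, 0.0, -2.0]) + rng.normal(0, 0.3, size=6)
        d = make_design(X, y)
        m = models.fit_m6(d)

        yv = d.y.to_numpy()
        best_rss, best_beta = np.inf, np.zeros(3)
        for k in range(4):
            for combo in itertools.combinations(range(3), k):
                sub = X.to_numpy()[:, list(combo)]
                beta_s, *_ = np.linalg.lstsq(sub, yv, rcond=None)
                if (beta_s < 0).any():
                    continue
                full = np.zeros(3)
                full[list(combo)] = beta_s
                rss = float(((yv - X.to_numpy() @ full) ** 2).sum())
                if rss < best_rss:
                    best_rss, best_beta = rss, full
        assert m.coef.to_numpy() == pytest.approx(best_beta, abs=1e-6)

    def test_kkt_conditions_hold(self, rng):
        for trial in range(5):
            n, p = 40, 4
            X = pd.DataFrame(
                rng.normal(size=(n, p)) + 1.0, columns=[f"x{i}" for i in range(p)]
            )
            beta = np.array([2.0, -1.0, 0.5, -0.2])
            y = X.to_numpy() @ beta + rng.normal(0, 0.2, size=n)
            d = make_design(X, y)
            m = models.fit_m6(d)
            assert (m.coef >= 0).all()
            assert models.kkt_max_violation(d.X, d.y, m) < 1e-6

    def test_residual_never_below_unconstrained(self, rng):
        d = _random_design(rng, n=50, p=3, beta=[1.0, -2.0, 0.5], sd=0.3)
        m1 = models.fit_m1(d)
        m6 = models.fit_m6(d)
        assert m6.diagnostics["rss"] >= m1.diagnostics["rss"] - 1e-9

    def test_nonneg_intercept_variant(self, rng):
        d = _random_design(rng, n=50, p=1, beta=[2.0], sd=0.1, intercept=5.0)
        m = models.fit_m6(d, intercept_mode="nonneg")
        assert m.intercept >= 0.0


class TestOutlierDetection:
    def test_clean_data_has_no_flags(self, rng):
        d = _random_design(rng, n=100, p=1, beta=[2.0], sd=0.5)
        m4 = models.fit_m4(d, models.fit_m1(d))
        m5 = models.fit_m5(d, m4.feature_names)
        flags = models.detect_outliers(d, m4, m5)
        assert flags == []

    def test_injected_outlier_is_flagged(self, rng):
        d = _random_design(rng, n=100, p=1, beta=[2.0], sd=0.5)
        y = d.y.copy()
        y.iloc[13] *= 100.0
        d_out = make_design(d.X, y)
        m4 = models.fit_m4(d_out, models.fit_m1(d_out))
        m5 = models.fit_m5(d_out, m4.feature_names)
        flags = models.detect_outliers(d_out, m4, m5)
        assert d.X.index[13] in flags

    def test_flags_are_subset_of_rows(self, rng):
        d = _random_design(rng, n=50, p=2, sd=3.0)
        m4 = models.fit_m4(d, models.fit_m1(d))
        m5 = models.fit_m5(d, m4.feature_names)
        flags = models.detect_outliers(d, m4, m5)
        assert set(flags) <= set(d.X.index)


class TestParameterRecovery:
    """All extrapolable models recover true doses on noise-free data."""

    def test_noise_free_recovery_to_1e6(self, scenario, pipeline_result):
        doses = scenario.truth.dose_per_group
        for (sid, lcc), design in pipeline_result.designs.items():
            fits = [
                models.fit_m1(design),
                models.fit_m2(design),
                models.fit_m4(design, models.fit_m1(design)),
                models.fit_m5(design),
                models.fit_m6(design),
            ]
            for m in fits:
                for g in design.crop_columns:
                    true = doses.get((sid, g))
                    if true is None or g not in m.coef.index:
                        continue
                    assert m.coef[g] == pytest.approx(true, rel=1e-6), (
                        sid, lcc, m.model_id, g,
                    )


class TestCascade:
    def test_clean_nonarable_accepts_base_or_m4(self, pipeline_result):
        for d in pipeline_result.decisions:
            if d.lcc != landcover.ARABLE:
                assert d.reason in ("accepted_base", "accepted_M4")
                assert d.model_id in ("M1", "M4")

    def test_every_design_gets_exactly_one_decision(self, pipeline_result):
        keys = [(d.substance_id, d.lcc) for d in pipeline_result.decisions]
        assert len(keys) == len(set(keys))
        assert set(keys) == set(pipeline_result.designs)

    def test_arable_outliers_prefer_m5(self, pipeline_result):
        design = pipeline_result.designs[("S01", landcover.ARABLE)]
        y = design.y.copy()
        big = y[y > 0].index[3]
        y.loc[big] *= 10.0
        noisy = make_design(
            design.X, y, country=design.country,
            crop_columns=design.crop_columns,
            climate_columns=design.climate_columns,
            lcc=landcover.ARABLE,
        )
        decision, final, audit = models.run_cascade(noisy)
        assert big in audit["outliers"]
        assert decision.reason in ("outliers->M5", "negative_coefs->M6")
        assert decision.model_id in ("M5", "M6")

    def test_negative_slope_falls_through_to_m6(self, rng):
        n = 90
        X = pd.DataFrame(
            {
                "a": rng.lognormal(3, 0.6, size=n),
                "b": rng.lognormal(3, 0.6, size=n),
            },
            index=[f"C{i % 4}R{i}" for i in range(n)],
        )
        y = 3.0 * X["a"] - 0.6 * X["b"] + rng.normal(0, 1.0, size=n)
        d = make_design(
            X, y, country=[f"C{i % 4}" for i in range(n)], lcc="vineyards"
        )
        decision, final, _ = models.run_cascade(d)
        assert decision.reason == "negative_coefs->M6"
        assert final.model_id == "M6"
        assert (final.coef >= 0).all()

    def test_unpredictable_response_is_excluded(self, rng):
        n = 60
        X = pd.DataFrame({"a": rng.lognormal(3, 0.6, size=n)})
        d = make_design(
            X, rng.normal(50, 30, size=n).clip(0), lcc="vineyards",
            country=[f"C{i % 4}" for i in range(n)],
        )
        decision, final, _ = models.run_cascade(d)
        assert decision.excluded
        assert final is None
        assert decision.reason in ("cv_fail", "country_specific_only")

    def test_m3_never_selected_as_final(self, pipeline_result):
        for d in pipeline_result.decisions:
            assert d.model_id != "M3"
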