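"""Generator behaviour: structure, determinism, conservation, noise law."""

import numpy as np
import pandas as pd
import pytest

from pestemis import landcover, synthetic
from pestemis.datatypes import ReportingScheme, SyntheticTruth


class TestLandscape:
    def test_structure_and_nonnegativity(self):
        t = synthetic.generate_landscape(2, 3, ["C1110", "W1100"], seed=42)
        assert len(t.region_ids) == 6
        assert t.region_ids.is_unique
        # region ids carry their country prefix
        for rid, ctry in t.info["country"].items():
            assert rid.startswith(ctry)
        assert (t.area_total.to_numpy() >= 0).all()
        assert (t.area_reported.to_numpy() <= t.area_total.to_numpy() + 1e-12).all()

    def test_seed_determinism(self):
        a = synthetic.generate_landscape(2, 3, ["C1110", "W1100"], seed=42)
        b = synthetic.generate_landscape(2, 3, ["C1110", "W1100"], seed=42)
        pd.testing.assert_frame_equal(a.area_total, b.area_total)
        pd.testing.assert_frame_equal(a.area_reported, b.area_reported)
        pd.testing.assert_frame_equal(a.info, b.info)

    def test_full_coverage_means_equal_areas(self):
        t = synthetic.generate_landscape(
            2, 3, ["C1110"], seed=1, coverage_fraction=1.0
        )
        pd.testing.assert_frame_equal(t.area_total, t.area_reported)

    @pytest.mark.parametrize("n_countries,n_regions", [(0, 3), (2, 0)])
    def test_nonpositive_counts_rejected(self, n_countries, n_regions):
        with pytest.raises(ValueError):
            synthetic.generate_landscape(n_countries, n_regions, ["C1110"], seed=0)

    def test_duplicate_crop_codes_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_landscape(1, 1, ["C1110", "C1110"], seed=0)

    def test_lognormal_median_roughly_at_default(self):
        t = synthetic.generate_landscape(4, 50, ["C1110"], seed=3)
        med = float(np.median(t.area_total["C1110"]))
        assert 350 < med < 700  # log-sd 1 around median 500


class TestClimate:
    def test_variable_inventory_per_region(self):
        t = synthetic.generate_landscape(1, 1, ["C1110"], seed=0)
        cells = synthetic.generate_climate(t, cells_per_region=1, seed=0)
        assert set(cells["variable"]) == set(synthetic.CLIMATE_VARIABLES)
        assert len(synthetic.CLIMATE_VARIABLES) == 24
        assert len(cells) == 24  # one cell per variable for the single region

    def test_degenerate_settings_make_regions_identical(self):
        t = synthetic.generate_landscape(2, 3, ["C1110"], seed=0)
        cells = synthetic.generate_climate(
            t, cells_per_region=4, seed=0, gradient_scale=0.0, noise_scale=0.0
        )
        by_region = cells.pivot_table(
            index="variable", columns="region_id", values="value", aggfunc="mean"
        )
        assert np.allclose(by_region.to_numpy(), by_region.iloc[:, [0]].to_numpy())

    def test_precipitation_nonnegative_and_deterministic(self):
        t = synthetic.generate_landscape(2, 5, ["C1110"], seed=0)
        a = synthetic.generate_climate(t, 10, seed=7)
        b = synthetic.generate_climate(t, 10, seed=7)
        pd.testing.assert_frame_equal(a, b)
        prec = a[a["variable"].str.startswith("prec")]
        assert (prec["value"] >= 0).all()

    def test_empty_region_table_rejected(self):
        t = synthetic.generate_landscape(1, 1, ["C1110"], seed=0)
        empty = t.info.iloc[:0]
        bad = type(t)(empty, t.area_total.iloc[:0], t.area_reported.iloc[:0])
        with pytest.raises(ValueError):
            synthetic.generate_climate(bad, 1, seed=0)


class TestTrueUse:
    def _one_region(self, area=10.0):
        t = synthetic.generate_landscape(1, 1, ["C1110"], seed=0)
        t.area_total.loc[:, "C1110"] = area
        t.area_reported.loc[:, "C1110"] = area
        return t

    def test_forced_arithmetic_dose_times_area(self):
        regions = self._one_region(10.0)
        truth = SyntheticTruth(dose_per_group={("S", "C0000"): 2.0})
        use = synthetic.simulate_true_use(truth, regions)
        assert use["kg"].sum() == pytest.approx(20.0, abs=1e-12)

    def test_zero_area_gives_zero_use(self):
        regions = self._one_region(0.0)
        truth = SyntheticTruth(dose_per_group={("S", "C0000"): 2.0})
        use = synthetic.simulate_true_use(truth, regions)
        assert (use["kg"] == 0).all()

    def test_unknown_group_is_configuration_error(self):
        regions = self._one_region()
        truth = SyntheticTruth(dose_per_group={("S", "XXXX"): 1.0})
        with pytest.raises(ValueError, match="XXXX"):
            synthetic.simulate_true_use(truth, regions)

    def test_lognormal_noise_mean_identity(self):
        # E[exp(eps)] = exp(sd^2/2): Monte-Carlo over 1000 regions
        sd = 0.3
        regions = synthetic.generate_landscape(1, 1000, ["C1110"], seed=5)
        regions.area_total.loc[:, "C1110"] = 1.0
        regions.area_reported.loc[:, "C1110"] = 1.0
        truth = SyntheticTruth(
            dose_per_group={("S", "C0000"): 2.0}, noise_sd=sd, seed=99
        )
        use = synthetic.simulate_true_use(truth, regions)
        expected = 2.0 * np.exp(sd**2 / 2)
        # s.e. of the mean of 2*exp(eps)
        se = 2.0 * np.sqrt((np.exp(sd**2) - 1) * np.exp(sd**2)) / np.sqrt(1000)
        assert abs(use["kg"].mean() - expected) < 3 * se

    def test_noise_free_climate_free_is_exact(self):
        scen = synthetic.reference_fixture(7, regions_per_country=2,
                                           cells_per_region=2)
        grouped_dose = scen.true_use_total.groupby(
            ["region_id", "substance_id", "group"], as_index=False
        )["kg"].sum()
        areas = scen.regions.area_total
        for _, row in grouped_dose.head(50).iterrows():
            crops = [c for c, g in scen.grouping.items() if g == row["group"]]
            area = float(areas.loc[row["region_id"], crops].sum())
            dose = scen.truth.dose_per_group.get(
                (row["substance_id"], row["group"]), 0.0
            )
            mult = scen.truth.country_dose_multiplier.get(
                (row["region_id"][:3], row["substance_id"]), 1.0
            )
            assert row["kg"] == pytest.approx(dose * area * mult, rel=1e-12)


@pytest.fixture(scope="module")
def small():
    return synthetic.reference_fixture(11, regions_per_country=4,
                                       cells_per_region=2)


class TestReporting:
    def test_country_level_conservation(self, small):
        scen = small
        true_rep = synthetic.simulate_true_use(
            scen.truth, scen.regions, area_variant="reported"
        )
        ctry = scen.scheme.reporting_countries[0]  # country-level, full crops
        recs = scen.reports[scen.reports["country"] == ctry]
        truth_sum = true_rep[true_rep["country"] == ctry].groupby("substance_id")[
            "kg"
        ].sum()
        for _, r in recs.iterrows():
            assert r["kg"] == pytest.approx(truth_sum[r["substance_id"]], rel=1e-12)

    def test_unreported_crops_excluded(self, small):
        scen = small
        ctry = scen.scheme.reporting_countries[1]
        dropped = scen.scheme.unreported_crops[ctry]
        crops_listed = set()
        for v in scen.reports.loc[scen.reports["country"] == ctry, "crops"]:
            crops_listed |= set(v.split(";"))
        assert not (crops_listed & set(dropped))

    def test_nonreporting_countries_absent(self, small):
        scen = small
        assert not set(scen.reports["country"]) & set(scen.scheme.nonreporting)

    def test_year_replicates_no_noise_identical(self, small):
        scen = small
        true_rep = synthetic.simulate_true_use(
            scen.truth, scen.regions, area_variant="reported"
        )
        recs = synthetic.simulate_reporting(
            true_rep, scen.scheme, scen.regions, years=(2011, 2012, 2013)
        )
        spread = recs.groupby(["country", "scope", "substance_id"])["kg"].agg(
            lambda s: s.max() - s.min()
        )
        assert (spread == 0).all()

    def test_determinism(self, small):
        scen = small
        true_rep = synthetic.simulate_true_use(
            scen.truth, scen.regions, area_variant="reported"
        )
        a = synthetic.simulate_reporting(true_rep, scen.scheme, scen.regions, seed=3)
        b = synthetic.simulate_reporting(true_rep, scen.scheme, scen.regions, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_scheme_validation(self, small):
        with pytest.raises(ValueError):
            ReportingScheme(resolution={"AAA": "continent"})
        scheme = ReportingScheme(resolution={"ZZZ": "country"})
        with pytest.raises(ValueError, match="ZZZ"):
            scheme.validate_against(small.regions)


class TestTruthInvariants:
    def test_doses_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            SyntheticTruth(dose_per_group={("S", "C0000"): -1.0})

    def test_substance_needs_positive_dose(self):
        with pytest.raises(ValueError, match="S"):
            SyntheticTruth(dose_per_group={("S", "C0000"): 0.0})

    def test_fixture_determinism_end_to_end(self):
        a = synthetic.reference_fixture(5, regions_per_country=2, cells_per_region=2)
        b = synthetic.reference_fixture(5, regions_per_country=2, cells_per_region=2)
        pd.testing.assert_frame_equal(a.reports, b.reports)
        pd.testing.assert_frame_equal(a.true_use_total, b.true_use_total)
        pd.testing.assert_frame_equal(a.climate_cells, b.climate_cells)


def test_correlated_block_fixture_structure():
    df = synthetic.generate_correlated_blocks(200, 3, 4, seed=0)
    corr = df.corr().abs()
    for c1 in df.columns:
        for c2 in df.columns:
            if c1 >= c2:
                continue
            r = corr.loc[c1, c2]
            if c1.split("_")[0] == c2.split("_")[0]:
                assert r > 0.95
            else:
                assert r < 0.5


def test_default_grouping_is_44_codes_16_groups():
    assert len(landcover.DEFAULT_CROP_CODES) == 44
    assert len(set(landcover.DEFAULT_CROP_GROUPING.values())) == 16
    assert set(landcover.GROUP_TO_CLASS.values()) == set(landcover.LAND_COVER_CLASSES)
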