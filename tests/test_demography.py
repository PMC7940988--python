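"""Rosters, age/sex classification, and covariate construction."""

import datetime as dt
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cofeed.demography import (
    COVARIATE_NAMES,
    Demography,
    DemographyTable,
    SchemaError,
    ValidationError,
    build_covariates,
    census_date,
    classify,
    load_demography,
    roster_at,
    write_demography,
)
from .conftest import make_individual


class TestLoading:
    def test_loads_and_preserves_rows(self, demography_csv):
        dem = load_demography(demography_csv)
        assert dem.group_ids == ("g1",)
        assert len(dem["g1"]) == 3
        assert dem["g1"].individuals[1].mother_id == "mom"

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,group,sex,birth_date,mother_id,entry_date\nx,g,female,2000-01-01,,2001-01-01\n")
        with pytest.raises(SchemaError, match="exit_date"):
            load_demography(path)

    def test_header_only_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,group,sex,birth_date,mother_id,entry_date,exit_date\n")
        dem = load_demography(path)
        assert dem.group_ids == ()

    def test_unknown_columns_ignored(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text(
            "id,group,sex,birth_date,mother_id,entry_date,exit_date,notes\n"
            "a,g1,male,2000-01-01,,2001-01-01,2010-01-01,hello\n"
        )
        assert len(load_demography(path)["g1"]) == 1

    def test_duplicate_ids_rejected(self):
        a = make_individual("dup")
        b = make_individual("dup", sex="male")
        with pytest.raises(ValidationError, match="dup"):
            DemographyTable("g1", (a, b))

    def test_exit_before_entry_rejected(self):
        with pytest.raises(ValidationError, match="exit_date"):
            make_individual(entry=dt.date(2010, 1, 1), exit=dt.date(2009, 1, 1))

    def test_mother_not_on_roster_rejected(self):
        kid = make_individual("kid", mother="ghost")
        with pytest.raises(ValidationError, match="ghost"):
            DemographyTable("g1", (kid,))

    def test_round_trip_preserves_required_columns(self, demography_csv, tmp_path):
        dem = load_demography(demography_csv)
        out = tmp_path / "rt.csv"
        write_demography(dem, out)
        again = load_demography(out)
        assert dem.to_frame().equals(again.to_frame())


class TestRoster:
    def test_date_before_all_entries_is_empty(self, small_table):
        assert roster_at(small_table, dt.date(1990, 1, 1)) == ()

    def test_date_inside_all_windows_returns_everyone(self, small_table):
        assert len(roster_at(small_table, dt.date(2015, 6, 1))) == 3

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_staggered_windows_match_interval_scan(self, data):
        """Membership equals an independent per-row interval check."""
        base = dt.date(2010, 1, 1)
        inds = []
        for i in range(data.draw(st.integers(1, 8))):
            start = data.draw(st.integers(0, 2000))
            length = data.draw(st.integers(0, 2000))
            inds.append(
                make_individual(
                    f"i{i}",
                    birth=dt.date(2000, 1, 1),
                    entry=base + dt.timedelta(days=start),
                    exit=base + dt.timedelta(days=start + length),
                )
            )
        table = DemographyTable("g", tuple(inds))
        query = base + dt.timedelta(days=data.draw(st.integers(0, 4000)))
        got = {ind.id for ind in roster_at(table, query)}
        want = {ind.id for ind in inds if ind.entry_date <= query <= ind.exit_date}
        assert got == want


class TestClassify:
    @pytest.mark.parametrize(
        "birth, query, expected",
        [
            (dt.date(2012, 8, 1), dt.date(2015, 6, 1), "infant_lt3"),   # age 2
            (dt.date(2012, 6, 1), dt.date(2015, 6, 1), "young_3_4"),    # exactly 3
            (dt.date(2002, 7, 1), dt.date(2015, 6, 30), "adolescent_9_12"),  # age 12
            (dt.date(2002, 6, 30), dt.date(2015, 6, 30), "adult_13plus"),    # exactly 13
            (dt.date(2010, 1, 1), dt.date(2015, 6, 1), "juvenile_5_8"),
        ],
    )
    def test_left_closed_bins(self, birth, query, expected):
        ind = make_individual(birth=birth, sex="female")
        cls = classify(ind, query)
        assert cls.age_class == expected
        assert cls.sex == "female"

    def test_query_before_birth_is_domain_error(self):
        ind = make_individual(birth=dt.date(2010, 1, 1))
        with pytest.raises(ValidationError, match="precedes birth"):
            classify(ind, dt.date(2009, 12, 31))

    @given(st.integers(0, 60))
    @settings(max_examples=61, deadline=None)
    def test_bins_partition_all_ages(self, age):
        ind = make_individual(birth=dt.date(2015 - age, 1, 1))
        assert classify(ind, dt.date(2015, 6, 1)).age_class in {
            "infant_lt3", "young_3_4", "juvenile_5_8", "adolescent_9_12", "adult_13plus"
        }


class TestCovariates:
    def test_fractions_in_unit_interval_and_z_standardized(self, small_demography):
        cov = build_covariates(small_demography, [2015, 2016])
        for name in COVARIATE_NAMES:
            if name != "group_size":
                assert cov[name].between(0, 1).all()
        # z-columns: mean 0, SD 1 over all cells (population SD)
        for name in COVARIATE_NAMES:
            z = cov[name + "_z"].to_numpy()
            if np.ptp(z) > 0:
                assert abs(z.mean()) < 1e-10
                assert abs(z.std() - 1) < 1e-10

    def test_no_coresident_kin_gives_zero_fraction(self):
        a = make_individual("a", "female", dt.date(1990, 1, 1))
        b = make_individual("b", "male", dt.date(1991, 1, 1))
        dem = Demography({"g": DemographyTable("g", (a, b))})
        cov = build_covariates(dem, [2015])
        assert cov["frac_maternal_kin"].iloc[0] == 0.0

    def test_kin_relation_is_symmetric(self, small_demography):
        # mom and kid are each other's kin; m1 has none -> 2/3
        cov = build_covariates(small_demography, [2015])
        assert cov["frac_maternal_kin"].iloc[0] == pytest.approx(2 / 3)

    def test_empty_roster_year_rejected(self, small_demography):
        with pytest.raises(ValidationError, match="empty roster"):
            build_covariates(small_demography, [1990])

    def test_group4_like_generator_keeps_pct_female_in_band(self):
        """A small male-biased group stays inside its configured 18-38% band."""
        from cofeed.simulate import SimConfig, generate_demography

        cfg = SimConfig(seed=17)
        dem = generate_demography(cfg)
        for year in cfg.years:
            roster = roster_at(dem["g4"], census_date(year))
            frac = sum(i.sex == "female" for i in roster) / len(roster)
            assert 0.18 <= frac <= 0.38

    def test_infant_exclusion_flag_changes_denominator(self):
        mom = make_individual("mom", "female", dt.date(1995, 5, 1))
        baby = make_individual("baby", "male", dt.date(2014, 1, 1), mother="mom",
                               entry=dt.date(2014, 1, 1))
        dem = Demography({"g": DemographyTable("g", (mom, baby))})
        full = build_covariates(dem, [2015], standardize=False)
        no_inf = build_covariates(dem, [2015], standardize=False,
                                  exclude_infants_from_denominator=True)
        assert full["frac_infants_lt3"].iloc[0] == pytest.approx(0.5)
        assert no_inf["frac_infants_lt3"].iloc[0] == pytest.approx(1.0)

    def test_constant_covariate_warns(self):
        a = make_individual("a", "female", dt.date(1990, 1, 1))
        dem = Demography({"g": DemographyTable("g", (a, make_individual("b", "male", dt.date(1991, 1, 1))))})
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            build_covariates(dem, [2015, 2016])
        assert any("constant" in str(w.message) for w in caught)
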