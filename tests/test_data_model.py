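"""Survey-table I/O, preprocessing rules and design-block construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contactfatigue import data_model as dm
from contactfatigue.schema import CHILD_AGE_BANDS, CovariateSchema, age_to_group

from conftest import make_records


class TestReadSurveyTables:
    def test_counts_itemised_contact_rows(self, tmp_path):
        parts = pd.DataFrame({
            "part_id": ["p1", "p2", "p3"], "wave": [1, 1, 1],
            "sex": ["male", "female", "male"], "hh_size": ["2", "1", "3"],
        })
        contacts = pd.DataFrame({"part_id": ["p1"] * 5, "wave": [1] * 5})
        pp, cp = tmp_path / "p.csv", tmp_path / "c.csv"
        parts.to_csv(pp, index=False)
        contacts.to_csv(cp, index=False)
        rec = dm.read_survey_tables(pp, cp)
        assert rec.set_index("part_id")["y"].to_dict() == {"p1": 5, "p2": 0, "p3": 0}

    def test_empty_contact_file_gives_zero_counts(self, tmp_path):
        parts = pd.DataFrame({"part_id": ["p1", "p2"], "wave": [1, 1],
                              "sex": ["male", "male"], "hh_size": ["2", "2"]})
        pp, cp = tmp_path / "p.csv", tmp_path / "c.csv"
        parts.to_csv(pp, index=False)
        pd.DataFrame(columns=["part_id", "wave"]).to_csv(cp, index=False)
        assert (dm.read_survey_tables(pp, cp)["y"] == 0).all()

    def test_group_total_added_to_itemised_rows(self, tmp_path):
        parts = pd.DataFrame({"part_id": ["p1"], "wave": [3], "sex": ["male"],
                              "hh_size": ["2"], "group_contacts": [4]})
        contacts = pd.DataFrame({"part_id": ["p1", "p1"], "wave": [3, 3]})
        pp, cp = tmp_path / "p.csv", tmp_path / "c.csv"
        parts.to_csv(pp, index=False)
        contacts.to_csv(cp, index=False)
        assert dm.read_survey_tables(pp, cp)["y"].iloc[0] == 4 + 2

    def test_missing_mandatory_column_names_the_column(self, tmp_path):
        parts = pd.DataFrame({"part_id": ["p1"], "wave": [1], "hh_size": ["2"]})
        pp, cp = tmp_path / "p.csv", tmp_path / "c.csv"
        parts.to_csv(pp, index=False)
        pd.DataFrame(columns=["part_id", "wave"]).to_csv(cp, index=False)
        with pytest.raises(dm.SchemaError, match="sex"):
            dm.read_survey_tables(pp, cp)

    def test_duplicate_participant_wave_rows_rejected(self, tmp_path):
        parts = pd.DataFrame({"part_id": ["p1", "p1"], "wave": [1, 1],
                              "sex": ["male", "male"], "hh_size": ["2", "2"]})
        pp, cp = tmp_path / "p.csv", tmp_path / "c.csv"
        parts.to_csv(pp, index=False)
        pd.DataFrame(columns=["part_id", "wave"]).to_csv(cp, index=False)
        with pytest.raises(dm.IntegrityError):
            dm.read_survey_tables(pp, cp)

    def test_write_read_round_trip(self, tmp_path, small_cohort):
        _, rec = small_cohort
        pp, cp = tmp_path / "p.csv", tmp_path / "c.csv"
        dm.write_survey_tables(rec, pp, cp)
        back = dm.read_survey_tables(pp, cp)
        lhs = rec.reset_index(drop=True)
        pd.testing.assert_series_equal(lhs["y"].astype(int), back["y"].astype(int))
        for col in ("part_id", "wave", "sex", "hh_size", "date"):
            assert (lhs[col] == back[col]).all()


class TestPreprocessing:
    def test_filter_drops_records_without_sex_or_age(self):
        rec = make_records([
            {"part_id": "a"},
            {"part_id": "b", "sex": None},
            {"part_id": "c", "age": None, "child_age_band": None},
            {"part_id": "d", "age": None, "child_age_band": "5-9"},
        ])
        kept = dm.filter_missing_demographics(rec)
        assert set(kept["part_id"]) == {"a", "d"}

    def test_filter_is_identity_on_complete_records(self, small_cohort):
        _, rec = small_cohort
        pd.testing.assert_frame_equal(dm.filter_missing_demographics(rec), rec)

    def test_impute_child_age_within_band_and_reproducible(self):
        for band, (lo, hi) in CHILD_AGE_BANDS.items():
            vals = [dm.impute_child_age(band, s) for s in range(50)]
            assert all(lo <= v <= hi for v in vals)
        assert dm.impute_child_age("10-14", 7) == dm.impute_child_age("10-14", 7)

    def test_impute_child_age_uniform_frequencies(self):
        # 10,000 draws from the 5-9 band: each of the 5 ages should appear
        # 2000 +- 3 binomial standard errors
        draws = np.array([dm.impute_child_age("5-9", s) for s in range(10_000)])
        se = np.sqrt(10_000 * 0.2 * 0.8)
        for v in range(5, 10):
            assert abs((draws == v).sum() - 2000) <= 3 * se

    def test_impute_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            dm.impute_child_age("30-40", 0)

    @given(st.integers(min_value=0, max_value=200))
    def test_truncation_idempotent_and_monotone(self, y):
        t = dm.truncate_contacts(y)
        assert t == min(y, 30)
        assert dm.truncate_contacts(t) == t
        assert dm.truncate_contacts(y + 1) >= t

    def test_truncation_rejects_negative(self):
        with pytest.raises(ValueError):
            dm.truncate_contacts(-1)

    def test_repeat_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        rows = []
        for pid in "abcde":
            waves = sorted(rng.choice(range(1, 5), size=rng.integers(1, 5),
                                      replace=False))
            rows += [{"part_id": pid, "wave": int(w)} for w in waves]
        rec = make_records(rows)
        out = dm.compute_repeat_counts(rec)
        for _, row in out.iterrows():
            expected = ((rec["part_id"] == row["part_id"])
                        & (rec["wave"] < row["wave"])).sum()
            assert row["repeat_count"] == expected

    def test_repeat_counts_increase_within_participant(self, small_cohort):
        _, rec = small_cohort
        out = dm.compute_repeat_counts(rec)
        for _, grp in out.sort_values("wave").groupby("part_id"):
            assert (np.diff(grp["repeat_count"]) > 0).all() or len(grp) == 1


class TestDesignBlocks:
    def test_block_widths(self, small_dataset):
        assert small_dataset.U.shape[1] == 21
        assert small_dataset.V.shape[1] == 16
        assert small_dataset.W.shape[1] == 33

    def test_baseline_record_has_zero_tested_row(self, schema):
        ds = dm.build_design(make_records([{}]), schema)
        assert ds.V.sum() == 0

    def test_non_reference_levels_set_exactly_their_columns(self, schema):
        ds = dm.build_design(
            make_records([{"employment": "student", "day_type": "weekend"}]), schema)
        names = schema.column_names("tested")
        on = {names[j] for j in np.flatnonzero(ds.V[0])}
        assert on == {"employment:student", "day_type:weekend"}

    def test_fatigue_block_keeps_reference_indicators(self, schema):
        # fatigue effects are contrasts against first-timers, so the row of
        # a reference-category adult carries all five factor indicators
        ds = dm.build_design(make_records([{}]), schema)
        assert ds.W[0].sum() == 5.0

    def test_unknown_category_names_record_and_field(self, schema):
        rec = make_records([{"part_id": "bad", "employment": "astronaut"}])
        with pytest.raises(dm.SchemaError, match="bad.*astronaut|astronaut"):
            dm.build_design(rec, schema)

    def test_estimable_masks(self, schema):
        assert sum(schema.estimable_mask("always_in")) == 18
        assert sum(schema.estimable_mask("tested")) == 12
        assert all(schema.estimable_mask("fatigue"))

    def test_age_group_mapping_boundaries(self):
        assert age_to_group(5, True) == "0-5 preschool"
        assert age_to_group(5, False) == "0-5 home"
        assert age_to_group(6) == "6-9"
        assert age_to_group(84) == "80-84"
        with pytest.raises(ValueError):
            age_to_group(85)


def test_schema_yaml_round_trip(tmp_path, schema):
    from contactfatigue.schema import schema_from_yaml, schema_to_yaml
    path = tmp_path / "schema.yaml"
    schema_to_yaml(schema, path)
    back = schema_from_yaml(path)
    assert back.column_names("fatigue") == schema.column_names("fatigue")
    assert back.reference == schema.reference
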