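"""Record matching, closest-prior-visit linkage, and the filter cascade."""

import numpy as np
import pandas as pd
import pytest

from caniact.linkage import (
    FilterConfig,
    LinkedDataset,
    apply_filters,
    link_activity_to_visit,
    match_dogs,
    normalize_name,
    split_healthy,
)


def _dog_row(key, household="H1", sex="male", name="rex", year=2018, month=4):
    return {
        "dog_key": key,
        "household": household,
        "species": "dog",
        "sex": sex,
        "name": name,
        "birth_year": year,
        "birth_month": month,
    }


class TestMatching:
    def test_identical_keys_match(self):
        res = match_dogs(
            pd.DataFrame([_dog_row("W1")]), pd.DataFrame([_dog_row("B1")])
        )
        assert res.mapping == {"W1": "B1"}

    def test_name_normalisation_tolerates_case_and_punctuation(self):
        res = match_dogs(
            pd.DataFrame([_dog_row("W1", name="  Rex! ")]),
            pd.DataFrame([_dog_row("B1", name="rex")]),
        )
        assert res.mapping == {"W1": "B1"}
        assert normalize_name(normalize_name("  Rex! ")) == normalize_name("  Rex! ")

    def test_birth_month_is_part_of_the_key(self):
        res = match_dogs(
            pd.DataFrame([_dog_row("W1", month=4)]),
            pd.DataFrame([_dog_row("B1", month=5)]),
        )
        assert res.mapping == {}
        assert res.unmatched_activity == ["W1"]

    def test_same_name_littermates_excluded_as_ambiguous(self):
        ehr = pd.DataFrame([_dog_row("B1"), _dog_row("B2")])  # full key clash
        res = match_dogs(pd.DataFrame([_dog_row("W1")]), ehr)
        assert res.mapping == {}
        assert len(res.ambiguous) == 1
        assert set(res.unmatched_ehr) == {"B1", "B2"}

    def test_missing_key_field_is_schema_error(self):
        with pytest.raises(KeyError, match="household"):
            match_dogs(
                pd.DataFrame([{"dog_key": "W1"}]), pd.DataFrame([_dog_row("B1")])
            )


def _activity(rows):
    return pd.DataFrame(rows, columns=["dog_key", "date", "active_minutes"])


def _visits(rows):
    return pd.DataFrame(rows, columns=["dog_key", "visit_date"])


class TestLinking:
    def test_prior_visit_preferred_over_nearer_future_visit(self):
        act = _activity([("D1", "2022-06-01", 30.0)])
        vis = _visits([("D1", "2022-05-02"), ("D1", "2022-06-06")])
        ds = link_activity_to_visit(act, vis)
        assert str(ds.rows["visit_date"].iloc[0].date()) == "2022-05-02"

    def test_closest_prior_wins(self):
        act = _activity([("D1", "2022-06-01", 30.0)])
        vis = _visits([("D1", "2022-05-22"), ("D1", "2022-02-21")])
        ds = link_activity_to_visit(act, vis)
        assert str(ds.rows["visit_date"].iloc[0].date()) == "2022-05-22"

    def test_visit_older_than_a_year_drops_the_row(self):
        act = _activity([("D1", "2022-06-01", 30.0)])
        vis = _visits([("D1", "2021-04-27")])  # 400 days before
        ds = link_activity_to_visit(act, vis)
        assert ds.rows.empty
        assert ds.provenance[-1]["rows_out"] == 0

    def test_invariant_visit_precedes_activity_within_365_days(self):
        rng = np.random.default_rng(4)
        base = pd.Timestamp("2022-01-01")
        act = _activity(
            [("D1", base + pd.Timedelta(days=int(d)), 30.0) for d in rng.integers(0, 700, 80)]
        )
        vis = _visits(
            [("D1", base + pd.Timedelta(days=int(d))) for d in rng.integers(-300, 700, 6)]
        )
        ds = link_activity_to_visit(act, vis)
        gap = (ds.rows["date"] - ds.rows["visit_date"]).dt.days
        assert (gap >= 0).all() and (gap <= 365).all()


def planted_filter_fixture() -> LinkedDataset:
    """20 linked rows with one planted violation of each cleaning rule.

    Hand-computed outcome under the default thresholds:

    * dog A: 12 rows over 2 visits; minutes 9.5 and 600.5 removed by the
      bounds stage (boundary values 10 and 600 kept), leaving 10 rows over 2
      visits (ratio 5.0, kept); all ages in range; 10 > 7 records -> kept.
    * dog B: 5 rows over 1 visit (ratio 5.0, kept); one row at age 12.5
      removed by the age window, leaving 4 rows -> dropped by the
      minimum-records floor.
    * dog C: 3 rows over 1 visit -> ratio 3 < 5, all rows dropped.

    Final: 10 rows, 1 dog; stage row counts 20 -> 18 -> 15 -> 14 -> 10.
    """
    rows = []
    a_minutes = [9.5, 600.5, 10.0, 600.0, 30, 40, 50, 60, 70, 80, 90, 100]
    for i, m in enumerate(a_minutes):
        rows.append(("A", f"2022-03-{i+1:02d}", m, i % 2, 5.0, 4.8))
    for i, (m, age) in enumerate(
        [(30, 5.0), (40, 5.0), (50, 5.0), (60, 5.0), (70, 12.5)]
    ):
        rows.append(("B", f"2022-04-{i+1:02d}", m, 10, age, age - 0.2))
    for i in range(3):
        rows.append(("C", f"2022-05-{i+1:02d}", 45.0, 20, 6.0, 5.9))
    df = pd.DataFrame(
        rows,
        columns=["dog_id", "date", "active_minutes", "visit_id", "age", "age_at_visit"],
    )
    df["date"] = pd.to_datetime(df["date"])
    return LinkedDataset(rows=df)


EXPECTED_STAGE_ROWS = [(20, 18), (18, 15), (15, 14), (14, 10)]
EXPECTED_SURVIVORS = (10, 1)  # rows, dogs


class TestFilterCascade:
    @pytest.mark.parametrize(
        "minutes,kept",
        [(9.5, False), (10.0, True), (600.0, True), (600.5, False)],
    )
    def test_strict_bounds(self, minutes, kept):
        df = pd.DataFrame(
            {
                "dog_id": ["X"] * 10,
                "active_minutes": [minutes] + [50.0] * 9,
                "visit_id": [0] * 10,
                "age": [5.0] * 10,
                "age_at_visit": [5.0] * 10,
            }
        )
        out = apply_filters(LinkedDataset(rows=df))
        assert (minutes in out.rows["active_minutes"].values) == kept

    def test_low_ratio_dog_fully_dropped(self):
        # 12 activity rows over 3 visits: ratio 4 < 5
        df = pd.DataFrame(
            {
                "dog_id": ["X"] * 12,
                "active_minutes": [50.0] * 12,
                "visit_id": [0, 1, 2] * 4,
                "age": [5.0] * 12,
                "age_at_visit": [5.0] * 12,
            }
        )
        out = apply_filters(LinkedDataset(rows=df))
        assert out.rows.empty

    def test_planted_fixture_matches_hand_computation(self):
        out = apply_filters(planted_filter_fixture())
        assert len(out.rows) == EXPECTED_SURVIVORS[0]
        assert out.rows["dog_id"].nunique() == EXPECTED_SURVIVORS[1]
        got = [(p["rows_in"], p["rows_out"]) for p in out.provenance]
        assert got == EXPECTED_STAGE_ROWS

    def test_cascade_idempotent(self):
        once = apply_filters(planted_filter_fixture())
        twice = apply_filters(once)
        pd.testing.assert_frame_equal(
            once.rows.reset_index(drop=True), twice.rows.reset_index(drop=True)
        )
        assert all(
            p["rows_in"] == p["rows_out"] for p in twice.provenance[len(once.provenance):]
        )

    def test_provenance_reconciles(self):
        out = apply_filters(planted_filter_fixture())
        removed = sum(p["rows_in"] - p["rows_out"] for p in out.provenance)
        assert removed == 20 - len(out.rows)
        assert all(p["rows_out"] <= p["rows_in"] for p in out.provenance)

    def test_thresholds_configurable(self):
        cfg = FilterConfig(min_records=0, min_ratio=0.0, max_age_years=99.0)
        out = apply_filters(planted_filter_fixture(), cfg)
        assert len(out.rows) == 18  # only the bounds stage bites


class TestHealthySplit:
    def _linked(self, status, injury):
        df = pd.DataFrame(
            {
                "dog_id": ["X"] * len(status),
                "active_minutes": [50.0] * len(status),
                "visit_id": range(len(status)),
                "age": [5.0] * len(status),
                "age_at_visit": [5.0] * len(status),
                "health_status": status,
                "injury": injury,
                "in_all_visits": [True] * len(status),
            }
        )
        return LinkedDataset(rows=df)

    def test_vaccination_only_visit_in_both_datasets(self):
        ds = split_healthy(self._linked(["healthy"], [False]))
        assert ds.rows["in_healthy_visits"].tolist() == [True]

    def test_chronic_diagnosis_visit_in_all_visits_only(self):
        ds = split_healthy(self._linked(["unhealthy"], [False]))
        assert ds.rows["in_healthy_visits"].tolist() == [False]

    def test_injury_flag_excludes_from_healthy(self):
        ds = split_healthy(self._linked(["healthy"], [True]))
        assert ds.rows["in_healthy_visits"].tolist() == [False]

    def test_all_healthy_gives_identical_subsets(self):
        ds = split_healthy(self._linked(["healthy"] * 4, [False] * 4))
        assert ds.rows["in_healthy_visits"].all()

    def test_unclassified_visit_raises_naming_it(self):
        with pytest.raises(ValueError, match="unclassified"):
            split_healthy(self._linked([np.nan], [False]))

    def test_healthy_subset_of_all_visits(self):
        ds = split_healthy(
            self._linked(["healthy", "unhealthy", "other"], [False, False, False])
        )
        assert (
            ds.rows["in_healthy_visits"] <= ds.rows["in_all_visits"]
        ).all()
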