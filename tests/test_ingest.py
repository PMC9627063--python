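"""Reading, filtering and aggregation of collection-style tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecofingerprint.ingest import (
    AnnualSeries,
    FilterRules,
    aggregate_temperature,
    canonical_binomial,
    filter_marine_annual_range,
    filter_occurrences,
    read_occurrences,
)
from conftest import make_record

HEADER = "scientificName,eventDate,decimalLatitude,decimalLongitude,occurrenceStatus,institutionCode\n"


def write_csv(tmp_path, rows):
    path = tmp_path / "occ.csv"
    path.write_text(HEADER + "".join(rows))
    return path


class TestReadOccurrences:
    def test_empty_table_with_header_gives_empty_list(self, tmp_path):
        assert read_occurrences(write_csv(tmp_path, [])) == []

    def test_row_without_latitude_is_dropped_and_counted(self, tmp_path, caplog):
        rows = [
            "Carex livida,1950-06-12,63.4,10.4,present,TRH\n",
            "Carex livida,1951-06-12,,10.4,present,TRH\n",
            "Carex livida,1952-06-12,63.5,10.4,present,TRH\n",
        ]
        with caplog.at_level("INFO"):
            records = read_occurrences(write_csv(tmp_path, rows))
        assert len(records) == 2
        assert "1 rows without coordinates" in caplog.text

    def test_year_only_date_is_dropped_by_default_but_kept_on_request(self, tmp_path):
        rows = ["Carex livida,1950,63.4,10.4,present,TRH\n"]
        path = write_csv(tmp_path, rows)
        assert read_occurrences(path) == []
        kept = read_occurrences(path, keep_year_only=True)
        assert len(kept) == 1 and kept[0].year == 1950 and kept[0].event_date is None

    def test_missing_mapped_column_is_a_configuration_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,lat,lon\nA b,1,2\n")
        with pytest.raises(ValueError, match="absent from header"):
            read_occurrences(path)


class TestCanonicalBinomial:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Carex livida", "Carex livida"),
            ("carex LIVIDA", "Carex livida"),
            ("Carex livida (Wahlenb.) Willd.", "Carex livida"),
            ("Carex livida var. minor", "Carex livida"),
            ("Carex", None),
            ("Carex sp.", None),
            ("Carex L.", None),
        ],
    )
    def test_canonicalization(self, raw, expected):
        assert canonical_binomial(raw) == expected


class TestFilterOccurrences:
    def test_span_of_49_years_removes_the_taxon(self):
        records = [make_record(year=1900) for _ in range(5)] + \
                  [make_record(year=1949) for _ in range(5)]
        survivors, drops = filter_occurrences(records, FilterRules())
        assert survivors == [] and drops["span"] == 10

    def test_span_of_exactly_50_years_is_kept(self):
        records = [make_record(year=1900) for _ in range(5)] + \
                  [make_record(year=1950) for _ in range(5)]
        survivors, _ = filter_occurrences(records, FilterRules())
        assert len(survivors) == 10

    def test_taxon_year_with_four_records_is_removed(self):
        records = [make_record(year=1900) for _ in range(5)] + \
                  [make_record(year=1980) for _ in range(4)]
        survivors, drops = filter_occurrences(records, FilterRules())
        assert {r.year for r in survivors} == {1900} and drops["per_year_count"] == 4

    def test_known_violations_fixture_matches_hand_count(self):
        records = (
            [make_record(year=1900) for _ in range(5)]       # kept
            + [make_record(year=1960) for _ in range(5)]     # kept (span 60)
            + [make_record(year=1930) for _ in range(3)]     # sparse year: dropped
            + [make_record(year=1950, status="absent") for _ in range(2)]  # absent
            + [make_record(taxon="Carex", year=1970) for _ in range(2)]    # non-binomial
            + [make_record(year=1890) for _ in range(2)]     # before window
            + [make_record(taxon="Brevis brevis", year=2000) for _ in range(1)]  # span 0
        )
        survivors, drops = filter_occurrences(records, FilterRules())
        assert len(survivors) == 10
        assert drops == {"status": 2, "binomial": 2, "year_range": 2,
                         "span": 1, "per_year_count": 3}

    def test_idempotent_and_subset(self):
        records = [make_record(year=y, status=s)
                   for y in (1900, 1930, 1960, 1990) for s in ("present", "absent")
                   for _ in range(5)]
        once, _ = filter_occurrences(records)
        twice, drops2 = filter_occurrences(once)
        assert twice == once
        assert all(v == 0 for v in drops2.values())
        assert set(id(r) for r in once) <= set(id(r) for r in records)

    @settings(max_examples=25, deadline=None)
    @given(
        span=st.integers(0, 60),
        per_year=st.integers(1, 6),
        data=st.lists(
            st.tuples(st.integers(0, 3), st.integers(1900, 1999),
                      st.sampled_from(["present", "absent"])),
            min_size=1, max_size=100,
        ),
    )
    def test_matches_naive_oracle_for_random_thresholds(self, span, per_year, data):
        taxa = ["Aa bb", "Cc dd", "Ee ff", "Gg"]
        records = [make_record(taxon=taxa[t], year=y, status=s) for t, y, s in data]
        rules = FilterRules(min_span_years=span, min_records_per_taxon_year=per_year)
        survivors, _ = filter_occurrences(records, rules)

        # oracle: evaluate each rule over the full record set, one pass
        stage = [r for r in records if r.status == "present"
                 and canonical_binomial(r.taxon) is not None
                 and rules.year_min <= r.year <= rules.year_max]
        years_of = {}
        for r in stage:
            years_of.setdefault(r.taxon, []).append(r.year)
        stage = [r for r in stage
                 if max(years_of[r.taxon]) - min(years_of[r.taxon]) >= span]
        counts = {}
        for r in stage:
            counts[(r.taxon, r.year)] = counts.get((r.taxon, r.year), 0) + 1
        oracle = [r for r in stage if counts[(r.taxon, r.year)] >= per_year]
        assert survivors == oracle


class TestMarineRangeFilter:
    def test_range_below_threshold_removed(self):
        recs = [make_record(lat=63.0), make_record(lat=63.3)]
        assert filter_marine_annual_range(recs, 0.4) == []

    def test_single_record_year_removed(self):
        assert filter_marine_annual_range([make_record()], 0.4) == []

    def test_boundary_is_kept_rule_is_strict_less_than(self):
        # four taxon-years with latitude ranges 0.0, 0.39, 0.4, 1.2
        fixture = {
            1950: [63.0, 63.0],
            1951: [63.0, 63.39],
            1952: [63.0, 63.4],
            1953: [63.0, 64.2],
        }
        recs = [make_record(year=y, lat=lat) for y, lats in fixture.items() for lat in lats]
        out = filter_marine_annual_range(recs, 0.4)
        assert sorted({r.year for r in out}) == [1952, 1953]


class TestAggregateTemperature:
    def test_constant_station_year(self):
        df = pd.DataFrame({"station": "s1", "year": 1950,
                           "month": range(1, 13), "value": 5.0})
        series = aggregate_temperature(df)
        assert list(series.years) == [1950]
        assert series.values[0] == pytest.approx(5.0)

    def test_two_station_mean_is_mean_of_all_24_values(self, rng):
        vals = rng.normal(5, 2, 24)
        df = pd.DataFrame({
            "station": ["s1"] * 12 + ["s2"] * 12,
            "year": 1960, "month": list(range(1, 13)) * 2, "value": vals,
        })
        series = aggregate_temperature(df)
        assert series.values[0] == pytest.approx(vals.mean())

    def test_max_mode_at_depth(self):
        df = pd.DataFrame({
            "depth": [200, 200, 200, 50],
            "date": ["1950-02-01", "1950-06-01", "1950-09-01", "1950-06-01"],
            "value": [7.1, 7.9, 7.4, 11.0],
        })
        series = aggregate_temperature(df, "annual_max_at_depth", depth=200)
        assert series.values[0] == pytest.approx(7.9)

    def test_no_rows_at_depth_warns_and_returns_empty(self, caplog):
        df = pd.DataFrame({"depth": [50], "date": ["1950-06-01"], "value": [11.0]})
        with caplog.at_level("WARNING"):
            series = aggregate_temperature(df, "annual_max_at_depth", depth=200)
        assert len(series) == 0
        assert "no rows at depth" in caplog.text

    def test_mean_invariant_to_row_order_and_station_relabelling(self, rng):
        vals = rng.normal(0, 1, 36)
        df = pd.DataFrame({"station": ["s1"] * 36, "year": 1970,
                           "month": list(range(1, 13)) * 3, "value": vals})
        shuffled = df.sample(frac=1, random_state=0)
        relabelled = df.copy()
        relabelled.loc[::2, "station"] = "s1_duplicate"
        a = aggregate_temperature(df).values[0]
        assert aggregate_temperature(shuffled).values[0] == pytest.approx(a)
        assert aggregate_temperature(relabelled).values[0] == pytest.approx(a)


class TestAnnualSeries:
    def test_duplicate_years_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AnnualSeries("x", [1950, 1950], [1.0, 2.0])

    def test_nan_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            AnnualSeries("x", [1950, 1951], [1.0, np.nan])
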