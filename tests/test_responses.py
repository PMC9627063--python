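"""Phenology, leading-edge, abundance and richness derivations."""

import numpy as np
import pandas as pd
import pytest

from ecofingerprint.responses import (
    PeakFlowerConfig,
    abundance_series,
    earliest_peak_flowering,
    leading_edge_latitude,
    peak_flowering_threshold,
    quantile_type7,
    richness_series,
)
from conftest import make_record, make_specimen


def quantile_oracle(values, q):
    """Order-statistics quantile at position 1+(n-1)q, by explicit interpolation."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


class TestQuantile:
    @pytest.mark.parametrize("q", [0.1, 0.25, 0.5, 0.75, 0.9, 0.999])
    def test_matches_order_statistics_oracle(self, rng, q):
        for _ in range(5):
            values = rng.uniform(0, 100, rng.integers(1, 40))
            assert quantile_type7(values, q) == pytest.approx(quantile_oracle(values, q))


class TestPeakFloweringThreshold:
    def test_constant_intensities_give_that_constant(self):
        specimens = [make_specimen(intensity=40.0) for _ in range(7)]
        assert peak_flowering_threshold(specimens) == pytest.approx(40.0)

    def test_octile_fixture_matches_oracle(self):
        intensities = [0, 10, 20, 30, 40, 50, 60, 80]
        specimens = [make_specimen(intensity=v) for v in intensities]
        expected = quantile_oracle(intensities, 0.75)  # 52.5 by interpolation
        assert peak_flowering_threshold(specimens) == pytest.approx(expected)
        assert expected == pytest.approx(52.5)

    def test_quantile_near_one_gives_max(self):
        specimens = [make_specimen(intensity=v) for v in (5, 60, 95)]
        cfg = PeakFlowerConfig(quantile=0.999999)
        assert peak_flowering_threshold(specimens, cfg) == pytest.approx(95.0, abs=1e-3)

    def test_no_specimens_is_an_error(self):
        with pytest.raises(ValueError):
            peak_flowering_threshold([])


class TestEarliestPeakFlowering:
    def test_single_qualifying_year_is_excluded_below_min_years(self):
        specimens = [make_specimen(year=1950, doy=180, intensity=100.0)]
        assert earliest_peak_flowering(specimens) is None
        cfg = PeakFlowerConfig(min_years=1)
        series = earliest_peak_flowering(specimens, cfg)
        assert list(series.series.years) == [1950]
        assert series.series.values[0] == pytest.approx(180)

    def test_minimum_doy_among_qualifying_specimens(self):
        specimens = [make_specimen(year=1950, doy=d, intensity=90.0)
                     for d in (172, 165, 190)]
        series = earliest_peak_flowering(specimens, PeakFlowerConfig(min_years=1))
        assert series.series.values[0] == pytest.approx(165)

    def test_twelve_year_fixture_matches_exhaustive_scan(self, rng):
        # constructed taxon: intensities and DOYs drawn, truth enumerated by hand-scan
        specimens = []
        for year in range(1950, 1962):
            for _ in range(6):
                specimens.append(make_specimen(
                    year=year, doy=int(rng.integers(120, 240)),
                    intensity=float(rng.integers(0, 101))))
        threshold = quantile_oracle([s.intensity for s in specimens], 0.75)
        expected = {}
        for s in specimens:
            if s.intensity >= threshold:
                expected[s.year] = min(expected.get(s.year, 999), s.doy)
        series = earliest_peak_flowering(specimens, PeakFlowerConfig(min_years=1))
        assert dict(zip(series.series.years.tolist(), series.series.values.tolist())) == \
            {y: float(v) for y, v in expected.items()}

    def test_lowering_threshold_never_delays_peak_dates(self, rng):
        specimens = []
        for year in range(1950, 1960):
            for _ in range(8):
                specimens.append(make_specimen(
                    year=year, doy=int(rng.integers(100, 260)),
                    intensity=float(rng.integers(0, 101))))
        strict = earliest_peak_flowering(specimens, PeakFlowerConfig(quantile=0.9, min_years=1))
        loose = earliest_peak_flowering(specimens, PeakFlowerConfig(quantile=0.5, min_years=1))
        strict_map = dict(zip(strict.series.years.tolist(), strict.series.values))
        loose_map = dict(zip(loose.series.years.tolist(), loose.series.values))
        for year, doy in strict_map.items():
            assert loose_map[year] <= doy
        assert all(1 <= v <= 366 for v in loose.series.values)


class TestLeadingEdge:
    def test_constant_latitudes(self):
        recs = [make_record(lat=63.43) for _ in range(5)]
        series = leading_edge_latitude(recs)
        assert series.series.values[0] == pytest.approx(63.43)

    def test_matches_quantile_oracle(self):
        lats = [62.0, 62.5, 63.0, 63.5, 64.0]
        recs = [make_record(lat=v) for v in lats]
        series = leading_edge_latitude(recs)
        assert series.series.values[0] == pytest.approx(quantile_oracle(lats, 0.9))

    def test_monotone_in_quantile_and_bounded_by_max(self, rng):
        recs = [make_record(lat=float(v)) for v in rng.uniform(60, 66, 20)]
        q90 = leading_edge_latitude(recs, 0.9).series.values[0]
        q100 = leading_edge_latitude(recs, 0.999999).series.values[0]
        assert q90 <= q100 <= max(r.latitude for r in recs) + 1e-9


class TestAbundance:
    def fixture(self):
        rows = []
        # taxon A: 120 rows over 2 years -> kept; known densities
        for year, dens in [(2000, [100.0, 300.0]), (2001, [250.0])]:
            for d in dens:
                rows += [{"station": "s1", "date": f"{year}-06-01", "taxon": "Aa bb",
                          "value": d}] * 40
        # taxon B: 99 rows -> dropped
        rows += [{"station": "s2", "date": "2000-07-01", "taxon": "Cc dd", "value": 5.0}] * 99
        return pd.DataFrame(rows)

    def test_mean_of_two_samples(self):
        df = pd.DataFrame([
            {"station": "s1", "date": "2000-06-01", "taxon": "Aa bb", "value": 100.0},
            {"station": "s1", "date": "2000-08-01", "taxon": "Aa bb", "value": 300.0},
        ])
        out = abundance_series(df, min_total=1)
        assert out[0].series.values[0] == pytest.approx(200.0)

    def test_rare_taxon_dropped_and_means_match_tabulation(self):
        out = abundance_series(self.fixture(), min_total=100)
        assert [r.unit_label for r in out] == ["Aa bb"]
        series = out[0].series
        assert list(series.years) == [2000, 2001]
        assert series.values[0] == pytest.approx(200.0)  # mean of 40x100 + 40x300
        assert series.values[1] == pytest.approx(250.0)

    def test_annual_mean_within_sample_range(self, rng):
        rows = [{"station": "s1", "date": "2000-06-01", "taxon": "Aa bb",
                 "value": float(v)} for v in rng.lognormal(3, 1, 30)]
        df = pd.DataFrame(rows)
        out = abundance_series(df, min_total=1)[0]
        assert df["value"].min() <= out.series.values[0] <= df["value"].max()


class TestRichness:
    def test_max_over_replicates(self):
        rows = []
        for rep, richness in enumerate([3, 5, 4, 4, 2], start=1):
            for i in range(richness):
                rows.append({"station": "s1", "date": "1990-06-10", "method": "surber",
                             "replicate": rep, "taxon": f"t{i}"})
        out = richness_series(pd.DataFrame(rows))
        assert out[0].series.values[0] == pytest.approx(5)

    def test_single_kick_sample(self):
        rows = [{"station": "s1", "date": "2005-06-10", "method": "kick",
                 "replicate": 1, "taxon": f"t{i}"} for i in range(7)]
        out = richness_series(pd.DataFrame(rows))
        assert out[0].series.values[0] == pytest.approx(7)
        assert out[0].covariates == {2005: "kick"}

    def test_method_change_fixture_matches_tabulation(self):
        rows = []
        for station in ("s1", "s2"):
            for rep in (1, 2):
                for i in range(3 + rep):  # richness 4 and 5 -> max 5
                    rows.append({"station": station, "date": "2002-06-10",
                                 "method": "surber", "replicate": rep, "taxon": f"t{i}"})
            for i in range(6):
                rows.append({"station": station, "date": "2003-06-10",
                             "method": "kick", "replicate": 1, "taxon": f"t{i}"})
        out = richness_series(pd.DataFrame(rows))
        assert len(out) == 2
        for rs in out:
            assert dict(zip(rs.series.years.tolist(), rs.series.values.tolist())) == \
                {2002: 5.0, 2003: 6.0}
            assert rs.covariates == {2002: "surber", 2003: "kick"}
            # max over replicates is at least any single replicate's richness
            assert rs.series.values.max() >= 4

    def test_mixed_methods_in_one_station_year_raise(self):
        rows = [
            {"station": "s1", "date": "2003-05-10", "method": "surber", "replicate": 1,
             "taxon": "t1"},
            {"station": "s1", "date": "2003-08-10", "method": "kick", "replicate": 1,
             "taxon": "t2"},
        ]
        with pytest.raises(ValueError, match="ambiguous"):
            richness_series(pd.DataFrame(rows))
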