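"""Synthetic generators for every input type, with the generating truth attached.

The default :class:`Scenario` encodes the study conditions the pipeline is
meant to recover: a century-plus annual temperature series with three phases
(warming 0.05 degC/yr to 1946, a slight cooling of -0.02 degC/yr to 1979,
warming 0.06 degC/yr after) and Gaussian noise of SD 0.5 degC; herbarium-style
phenology responding at -2.06 days per degC; abundance declining with
temperature; occurrence latitudes whose 90th percentile drifts at a known
rate; plus deliberately injected filter violations at known counts so the
cleaning rules can be audited exactly.

Randomness: one seed per scenario, split into named substreams (one per
generator), so adding taxa to one generator never perturbs another's draws.
All generators are bit-reproducible for a fixed seed and package version.
"""

from __future__ import annotations

import datetime as _dt
import string
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ingest import AnnualSeries, OccurrenceRecord, PhenologySpecimen

__all__ = [
    "Scenario",
    "TruthRecord",
    "simulate_temperature",
    "simulate_phenology",
    "simulate_occurrences",
    "simulate_response",
]


@dataclass
class Scenario:
    """Generator settings; defaults are the study conditions, not free dials."""

    seed: int = 0
    year_start: int = 1900
    year_end: int = 2020
    # temperature
    temp_break_years: tuple[int, ...] = (1946, 1979)
    temp_phase_slopes: tuple[float, ...] = (0.05, -0.02, 0.06)
    temp_base: float = 4.0          # degC in year_start
    temp_noise_sd: float = 0.5      # degC
    # phenology
    pheno_sensitivity: float = -2.06   # days per degC
    n_pheno_taxa: int = 22
    pheno_specimens_per_year: float = 5.0   # Poisson mean
    pheno_baseline_range: tuple[float, float] = (150.0, 200.0)  # peak DOY
    pheno_taxon_noise_sd: float = 2.0       # days, latent peak year-to-year
    pheno_date_sd: float = 10.0             # days, collection date around peak
    pheno_intensity_width: float = 30.0     # days to zero intensity
    # occurrences / distribution
    n_occurrence_taxa: int = 8
    occurrence_records_per_year: float = 12.0  # Poisson mean
    occ_lat_center: float = 63.5
    occ_lat_sd: float = 0.5
    edge_drift: float = 0.0      # degrees latitude per year of the 0.9 quantile
    injected_absent: int = 7
    injected_non_binomial: int = 5
    injected_sparse_records: int = 12   # records in taxon-years with <5 records
    injected_short_span_records: int = 10  # records of a 49-year-span taxon
    # abundance / diversity
    abundance_trend: float = -500.0   # individuals m-3 per degC
    n_abundance_taxa: int = 16
    abundance_base_range: tuple[float, float] = (500.0, 8000.0)
    abundance_noise_sd: float = 0.3   # lognormal sigma
    abundance_year_start: int = 1977
    rare_taxon_records: int = 99      # below the 100-observation cutoff
    richness_true: int = 12
    richness_detect_p: float = 0.7
    method_switch_year: int = 2003
    # effort: per-year multiplier on expected record counts
    effort_profile: Callable[[int], float] | None = None

    def __post_init__(self) -> None:
        if len(self.temp_phase_slopes) != len(self.temp_break_years) + 1:
            raise ValueError("need one slope per phase (breaks + 1)")
        if self.temp_noise_sd < 0 or self.pheno_date_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def effort(self, year: int) -> float:
        return 1.0 if self.effort_profile is None else float(self.effort_profile(year))


@dataclass
class TruthRecord:
    """Echo of the generating scenario a recovery test can assert against."""

    scenario: Scenario
    true_breaks: tuple[int, ...] = ()
    true_slopes: tuple[float, ...] = ()
    true_sensitivity: float | None = None
    true_edge_drift: float | None = None
    true_trend: float | None = None
    injected: dict[str, int] = field(default_factory=dict)


def _epithet(i: int) -> str:
    """Letter-only species epithet ('alphus', 'betus', ...) for index i."""
    letters = string.ascii_lowercase
    return "sp" + letters[i // 26] + letters[i % 26]


def _rng(s: Scenario, stream: str) -> np.random.Generator:
    key = zlib.adler32(stream.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(s.seed, spawn_key=(key,)))


def piecewise_mean(s: Scenario) -> np.ndarray:
    """The continuous piecewise-linear temperature mean over scenario years."""
    years = s.years
    slopes = np.empty(years.size)
    edges = (s.year_start,) + tuple(s.temp_break_years) + (s.year_end + 1,)
    for i, sl in enumerate(s.temp_phase_slopes):
        slopes[(years >= edges[i]) & (years < edges[i + 1])] = sl
    # integrate the per-year slope so the line is continuous at each break
    mean = np.empty(years.size)
    mean[0] = s.temp_base
    mean[1:] = s.temp_base + np.cumsum(slopes[:-1])
    return mean


def simulate_temperature(s: Scenario) -> tuple[AnnualSeries, TruthRecord]:
    """Three-phase annual mean temperature with i.i.d. Gaussian noise."""
    rng = _rng(s, "temperature")
    mean = piecewise_mean(s)
    values = mean + rng.normal(0.0, s.temp_noise_sd, size=mean.size)
    series = AnnualSeries("temperature", s.years, values, "degC")
    truth = TruthRecord(scenario=s, true_breaks=tuple(s.temp_break_years),
                        true_slopes=tuple(s.temp_phase_slopes))
    return series, truth


def _date_from_doy(year: int, doy: int) -> _dt.date:
    return _dt.date(year, 1, 1) + _dt.timedelta(days=int(doy) - 1)


def simulate_phenology(
    s: Scenario, temperature: AnnualSeries
) -> tuple[dict[str, list[PhenologySpecimen]], TruthRecord]:
    """Herbarium-style specimens whose peak flowering tracks temperature.

    Each taxon has a latent peak DOY per year = baseline + sensitivity *
    (T_year - mean T) + taxon noise.  Specimens per year are Poisson draws
    scaled by the effort profile; each specimen's collection DOY scatters
    around the latent peak, and its flowering intensity falls off linearly
    (triangular law) with distance from the peak, so threshold-qualifying
    specimens cluster at the true peak.
    """
    rng = _rng(s, "phenology")
    tbar = float(temperature.values.mean())
    temp_of = dict(zip(temperature.years.tolist(), temperature.values))
    out: dict[str, list[PhenologySpecimen]] = {}
    for i in range(s.n_pheno_taxa):
        taxon = f"Synthetica {_epithet(i)}"
        baseline = rng.uniform(*s.pheno_baseline_range)
        specimens: list[PhenologySpecimen] = []
        for year in s.years:
            if int(year) not in temp_of:
                continue
            latent = (baseline + s.pheno_sensitivity * (temp_of[int(year)] - tbar)
                      + rng.normal(0.0, s.pheno_taxon_noise_sd))
            n_spec = rng.poisson(s.pheno_specimens_per_year * s.effort(int(year)))
            for _ in range(n_spec):
                offset = rng.normal(0.0, s.pheno_date_sd)
                doy = int(np.clip(round(latent + offset), 1, 365))
                intensity = 100.0 * max(0.0, 1.0 - abs(offset) / s.pheno_intensity_width)
                specimens.append(PhenologySpecimen(
                    taxon=taxon,
                    event_date=_date_from_doy(int(year), doy),
                    intensity=float(intensity),
                ))
        out[taxon] = specimens
    truth = TruthRecord(scenario=s, true_sensitivity=s.pheno_sensitivity)
    return out, truth


def simulate_occurrences(s: Scenario) -> tuple[list[OccurrenceRecord], TruthRecord]:
    """Occurrence records with a drifting leading edge plus injected violations.

    Clean taxa: per year, a Poisson number of presence records with latitudes
    Normal(center + edge_drift * (year - start), occ_lat_sd), so the 0.9
    latitude quantile drifts at ``edge_drift`` degrees per year.  Injected at
    known counts (echoed in the truth record): absent-status records,
    non-binomial names, sparse taxon-years (<5 records) and a taxon spanning
    only 49 years — one probe per filter rule.
    """
    rng = _rng(s, "occurrences")
    records: list[OccurrenceRecord] = []
    years = s.years
    for i in range(s.n_occurrence_taxa):
        taxon = f"Simulatus {_epithet(i)}"
        center0 = s.occ_lat_center + rng.uniform(-0.5, 0.5)
        for year in years:
            n_rec = rng.poisson(s.occurrence_records_per_year * s.effort(int(year)))
            center = center0 + s.edge_drift * (int(year) - s.year_start)
            for _ in range(n_rec):
                lat = float(np.clip(rng.normal(center, s.occ_lat_sd), -90, 90))
                doy = int(rng.integers(120, 270))
                records.append(OccurrenceRecord(
                    taxon=taxon, event_date=_date_from_doy(int(year), doy),
                    year=int(year), latitude=lat,
                    longitude=float(rng.uniform(8.0, 12.0)), status="present",
                    source="synthetic",
                ))

    def _inject(n: int, taxon: str, status: str = "present",
                year_of: Callable[[int], int] | None = None) -> None:
        for j in range(n):
            year = int(year_of(j)) if year_of else int(rng.choice(years))
            records.append(OccurrenceRecord(
                taxon=taxon, event_date=_date_from_doy(year, 150), year=year,
                latitude=float(rng.normal(s.occ_lat_center, s.occ_lat_sd)),
                longitude=10.4, status=status, source="synthetic",
            ))

    # one injected probe per filter rule
    _inject(s.injected_absent, "Absentia absentis", status="absent")
    _inject(s.injected_non_binomial, "Carex")
    # sparse: 2 records per year, years spread over >=50 years so the taxon
    # passes the span rule and every taxon-year fails the 5-record rule
    n_sparse_years = (s.injected_sparse_records + 1) // 2
    sparse_years = [s.year_start + j * max(51 // max(n_sparse_years - 1, 1), 1)
                    for j in range(n_sparse_years)]
    sparse_years[-1] = max(sparse_years[-1], s.year_start + 51)
    _inject(s.injected_sparse_records, "Sparsus sparsus",
            year_of=lambda j: sparse_years[j // 2])
    # short span: plenty of records but only 49 years between first and last
    _inject(s.injected_short_span_records, "Brevis brevis",
            year_of=lambda j: s.year_start if j % 2 == 0 else s.year_start + 49)

    truth = TruthRecord(
        scenario=s, true_edge_drift=s.edge_drift,
        injected={
            "absent": s.injected_absent,
            "non_binomial": s.injected_non_binomial,
            "sparse": s.injected_sparse_records,
            "short_span": s.injected_short_span_records,
        },
    )
    return records, truth


def simulate_response(
    kind: str, s: Scenario, temperature: AnnualSeries
) -> tuple[pd.DataFrame, TruthRecord]:
    """Sample tables for the abundance or diversity pipelines.

    ``abundance``: long table (station, date, taxon, value) of per-sample
    densities with a linear temperature effect and multiplicative lognormal
    noise, plus one rare taxon below the observation cutoff.  ``diversity``:
    per-replicate species lists (station, date, method, replicate, taxon)
    with constant true richness and a sampling-method switch, so the method
    covariate is exercised.
    """
    if kind == "abundance":
        return _simulate_abundance(s, temperature)
    if kind == "diversity":
        return _simulate_diversity(s, temperature)
    raise ValueError(f"unknown kind {kind!r}")


def _simulate_abundance(s: Scenario, temperature: AnnualSeries) -> tuple[pd.DataFrame, TruthRecord]:
    rng = _rng(s, "abundance")
    temp_of = dict(zip(temperature.years.tolist(), temperature.values))
    tbar = float(temperature.values.mean())
    years = [y for y in range(s.abundance_year_start, s.year_end + 1) if y in temp_of]
    stations = ["basin_A", "basin_B", "basin_C"]
    rows: list[dict] = []
    for i in range(s.n_abundance_taxa):
        taxon = f"Planktonicus {_epithet(i)}"
        base = rng.uniform(*s.abundance_base_range)
        for year in years:
            level = max(base + s.abundance_trend * (temp_of[year] - tbar), 0.0)
            for station in stations:
                for month in (5, 7, 9):  # three sampling dates per season
                    value = level * rng.lognormal(0.0, s.abundance_noise_sd)
                    rows.append({"station": station,
                                 "date": f"{year:04d}-{month:02d}-15",
                                 "taxon": taxon, "value": round(float(value), 3)})
    # a rare taxon with a known sub-threshold number of observation rows
    rare_years = years * ((s.rare_taxon_records // len(years)) + 1)
    for j in range(s.rare_taxon_records):
        rows.append({"station": stations[j % 3], "date": f"{rare_years[j]:04d}-06-15",
                     "taxon": "Rarus rarus",
                     "value": round(float(rng.lognormal(2.0, 0.5)), 3)})
    truth = TruthRecord(scenario=s, true_trend=s.abundance_trend,
                        injected={"rare_records": s.rare_taxon_records})
    return pd.DataFrame(rows), truth


def _simulate_diversity(s: Scenario, temperature: AnnualSeries) -> tuple[pd.DataFrame, TruthRecord]:
    rng = _rng(s, "diversity")
    pool = [f"Benthicus {_epithet(i)}" for i in range(s.richness_true)]
    years = range(max(s.abundance_year_start, s.year_start) + 9, s.year_end + 1)
    rows: list[dict] = []
    for station in ("upper_station", "lower_station"):
        for year in years:
            pre_switch = year < s.method_switch_year
            method = "surber" if pre_switch else "kick"
            n_visits = int(rng.integers(1, 5)) if pre_switch else 1
            n_reps = 5 if pre_switch else 1
            for visit in range(n_visits):
                date = f"{year:04d}-{6 + visit:02d}-10"
                for rep in range(1, n_reps + 1):
                    detected = [t for t in pool if rng.random() < s.richness_detect_p]
                    for taxon in detected:
                        rows.append({"station": station, "date": date, "method": method,
                                     "replicate": rep, "taxon": taxon})
    truth = TruthRecord(scenario=s, injected={"richness_true": s.richness_true})
    return pd.DataFrame(rows), truth
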