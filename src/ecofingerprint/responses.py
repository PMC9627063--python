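"""Derivation of annual ecological response series from canonical records.

Four response families:

* **phenology** — per taxon, the earliest day-of-year each year on which a
  specimen reaches the species' peak-flowering intensity threshold (the 0.75
  empirical quantile of all its intensity scores);
* **distribution** — per taxon, the annual leading-edge latitude (the 0.9
  empirical quantile of that year's record latitudes);
* **abundance** — per taxon, the mean sampled density per year, after
  dropping rarely observed taxa;
* **diversity** — per station, annual species richness as the maximum number
  of distinct taxa over that year's sampling replicates, with the sampling
  method carried as a per-year covariate.

All quantiles use the linear-interpolation ("type 7") convention at position
1+(n-1)q, applied identically to intensity thresholds and latitudes.
Zero-intensity scores are included in the threshold quantile; they are
records like any other, and excluding them would shift thresholds upward.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import AnnualSeries, OccurrenceRecord, PhenologySpecimen

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseSeries",
    "PeakFlowerConfig",
    "peak_flowering_threshold",
    "earliest_peak_flowering",
    "leading_edge_latitude",
    "abundance_series",
    "richness_series",
]

RESPONSE_KINDS = ("phenology", "abundance", "diversity", "distribution")


@dataclass
class ResponseSeries:
    """One unit's (taxon's or station's) annual ecological response."""

    response_id: str
    unit_label: str
    kind: str
    series: AnnualSeries
    covariates: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in RESPONSE_KINDS:
            raise ValueError(f"unknown response kind {self.kind!r}")
        if len(self.series) == 0:
            raise ValueError("series must be non-empty")
        if self.covariates is not None:
            missing = [int(y) for y in self.series.years if int(y) not in self.covariates]
            if missing:
                raise ValueError(f"covariates missing for years {missing}")


@dataclass
class PeakFlowerConfig:
    quantile: float = 0.75
    min_years: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if self.min_years < 1:
            raise ValueError("min_years must be >= 1")


def quantile_type7(values: Iterable[float], q: float) -> float:
    """Linear-interpolation quantile at position 1+(n-1)q of the sorted sample."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    return float(np.quantile(arr, q))  # numpy's default is the type-7 rule


def peak_flowering_threshold(
    specimens: Sequence[PhenologySpecimen], config: PeakFlowerConfig | None = None
) -> float:
    """Peak-flowering intensity threshold for one taxon.

    The threshold is the ``config.quantile`` (default 0.75) empirical quantile
    of *all* intensity scores of the taxon, zeros included.
    """
    config = config or PeakFlowerConfig()
    if not specimens:
        raise ValueError("no specimens for threshold")
    return quantile_type7((s.intensity for s in specimens), config.quantile)


def earliest_peak_flowering(
    specimens: Sequence[PhenologySpecimen], config: PeakFlowerConfig | None = None
) -> ResponseSeries | None:
    """Earliest peak-flowering day-of-year per year for one taxon.

    A specimen is "at peak" when its intensity is at or above the taxon's
    threshold (ties count).  Each year with at least one such specimen
    contributes the minimum DOY among them.  Taxa with fewer than
    ``config.min_years`` qualifying years are excluded (returns ``None``).
    """
    config = config or PeakFlowerConfig()
    if not specimens:
        return None
    threshold = peak_flowering_threshold(specimens, config)
    per_year: dict[int, int] = {}
    for s in specimens:
        if s.intensity >= threshold:
            y = s.year
            per_year[y] = min(per_year.get(y, 367), s.doy)
    if len(per_year) < config.min_years:
        logger.info(
            "earliest_peak_flowering: %s excluded (%d qualifying years < %d)",
            specimens[0].taxon, len(per_year), config.min_years,
        )
        return None
    years = np.array(sorted(per_year), dtype=int)
    values = np.array([per_year[int(y)] for y in years], dtype=float)
    taxon = specimens[0].taxon
    return ResponseSeries(
        response_id="phenology",
        unit_label=taxon,
        kind="phenology",
        series=AnnualSeries(f"{taxon} earliest peak flowering", years, values, "day of year"),
    )


def leading_edge_latitude(
    records: Sequence[OccurrenceRecord],
    quantile: float = 0.9,
    response_id: str = "distribution",
) -> ResponseSeries:
    """Annual leading-edge latitude of one taxon.

    Per year, the 0.9 empirical quantile of record latitudes — a robust
    stand-in for the northernmost record that single extreme localities
    cannot dominate.
    """
    if not records:
        raise ValueError("no records")
    lats: dict[int, list[float]] = defaultdict(list)
    for r in records:
        lats[r.year].append(r.latitude)
    years = np.array(sorted(lats), dtype=int)
    values = np.array([quantile_type7(lats[int(y)], quantile) for y in years])
    taxon = records[0].taxon
    return ResponseSeries(
        response_id=response_id,
        unit_label=taxon,
        kind="distribution",
        series=AnnualSeries(f"{taxon} leading edge", years, values, "deg latitude"),
    )


def abundance_series(
    samples: pd.DataFrame,
    min_total: int = 100,
    count_column: str | None = None,
    response_id: str = "abundance",
) -> list[ResponseSeries]:
    """Per-taxon annual mean density from a long sample table.

    ``samples`` columns: taxon, date (or year), value (density), optionally a
    count column.  Taxa whose summed observations across all sites fall below
    ``min_total`` are dropped; "observations" means the value of
    ``count_column`` summed over rows when given, otherwise the row count.
    Surviving taxa get one series of mean density across each year's samples.
    """
    df = samples.copy()
    if "year" not in df.columns:
        df["year"] = pd.to_datetime(df["date"]).dt.year
    df["value"] = pd.to_numeric(df["value"])
    if count_column is not None:
        totals = df.groupby("taxon")[count_column].apply(lambda s: pd.to_numeric(s).sum())
    else:
        totals = df.groupby("taxon").size()
    keep = totals[totals >= min_total].index
    dropped = sorted(set(df["taxon"]) - set(keep))
    if dropped:
        logger.info("abundance_series: dropped %d taxa below %d observations: %s",
                    len(dropped), min_total, dropped)
    out: list[ResponseSeries] = []
    for taxon, sub in df[df["taxon"].isin(keep)].groupby("taxon"):
        annual = sub.groupby("year")["value"].mean().sort_index()
        out.append(
            ResponseSeries(
                response_id=response_id,
                unit_label=str(taxon),
                kind="abundance",
                series=AnnualSeries(f"{taxon} mean density", annual.index.to_numpy(),
                                    annual.to_numpy(), "individuals m-3"),
            )
        )
    return out


def richness_series(samples: pd.DataFrame, response_id: str = "diversity") -> list[ResponseSeries]:
    """Per-station annual species richness, max over replicates, with method covariate.

    ``samples`` columns: station, date (or year), method, replicate, taxon;
    one row per taxon detected in a replicate.  Richness of a replicate is
    its count of distinct taxa; the annual station value is the maximum over
    all replicates of all that year's sampling events.  A station-year
    sampled with two distinct methods is ambiguous and raises.
    """
    df = samples.copy()
    if "year" not in df.columns:
        df["year"] = pd.to_datetime(df["date"]).dt.year
    out: list[ResponseSeries] = []
    for station, sub in df.groupby("station"):
        years: list[int] = []
        values: list[float] = []
        methods: dict[int, str] = {}
        for year, ysub in sub.groupby("year"):
            year = int(year)
            meths = sorted(set(ysub["method"]))
            if len(meths) > 1:
                raise ValueError(
                    f"station {station!r} year {year}: mixed methods {meths} are ambiguous"
                )
            richness = ysub.groupby(["date", "replicate"])["taxon"].nunique().max()
            years.append(year)
            values.append(float(richness))
            methods[year] = meths[0]
        order = np.argsort(years)
        years_arr = np.asarray(years, dtype=int)[order]
        values_arr = np.asarray(values)[order]
        out.append(
            ResponseSeries(
                response_id=response_id,
                unit_label=str(station),
                kind="diversity",
                series=AnnualSeries(f"{station} richness", years_arr, values_arr, "species"),
                covariates={int(y): methods[int(y)] for y in years_arr},
            )
        )
    return out
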