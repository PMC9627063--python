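"""Reading, validation, filtering and aggregation of collection-style input tables.

Four input families are handled: Darwin-Core-like occurrence tables,
scored herbarium phenology tables, abundance/richness sample tables, and
station temperature tables.  Everything downstream works on the canonical
containers defined here: :class:`OccurrenceRecord`, :class:`PhenologySpecimen`
and :class:`AnnualSeries`.

Filtering follows the collection-effort rules used for distribution series:
presence records only, full binomial names, a bounded year window, a minimum
span (years between first and last record of a taxon) and a minimum number of
records per taxon-year.  A separate per-year latitude-range filter is applied
to marine records, where single-station sampling would otherwise fabricate
range stability.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceRecord",
    "PhenologySpecimen",
    "AnnualSeries",
    "FilterRules",
    "canonical_binomial",
    "read_occurrences",
    "read_phenology",
    "filter_occurrences",
    "filter_marine_annual_range",
    "aggregate_temperature",
    "DARWIN_CORE_COLUMNS",
]

#: Default column mapping: canonical field -> Darwin Core term.
DARWIN_CORE_COLUMNS: dict[str, str] = {
    "taxon": "scientificName",
    "event_date": "eventDate",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "status": "occurrenceStatus",
    "source": "institutionCode",
}

# tokens that mark a non-specific epithet or an infraspecific rank
_NON_EPITHETS = {"sp", "sp.", "spp", "spp.", "cf", "cf.", "aff", "aff.", "indet", "indet."}
_RANK_TOKENS = {"var.", "var", "subsp.", "subsp", "ssp.", "ssp", "f.", "forma"}
_EPITHET_RE = re.compile(r"^[a-zA-Z][a-zA-Z\-]*$")


class ConfigurationError(ValueError):
    """A column map or rule set does not match the data."""


def canonical_binomial(name: str) -> str | None:
    """Canonicalize *name* to ``Genus epithet``; return None if not a binomial.

    Authorship strings and infraspecific ranks are stripped; the genus is
    capitalized and the epithet lower-cased.  Names with a single token or a
    placeholder epithet (``sp.``, ``cf.`` ...) are rejected.
    """
    tokens = str(name).strip().split()
    if len(tokens) < 2:
        return None
    genus, epithet = tokens[0], tokens[1]
    if epithet.lower() in _NON_EPITHETS or epithet.lower() in _RANK_TOKENS:
        return None
    if not (_EPITHET_RE.match(genus) and _EPITHET_RE.match(epithet)):
        return None
    # a title-case or dotted second token is authorship ("Carex L.",
    # "Carex Wahlenb."), not an epithet; all-caps is shouting, not authorship
    if "." in epithet or (epithet[0].isupper() and not epithet.isupper()):
        return None
    return f"{genus.capitalize()} {epithet.lower()}"


@dataclass(frozen=True)
class OccurrenceRecord:
    """One dated, georeferenced collection record for a taxon."""

    taxon: str
    event_date: _dt.date | None
    year: int
    latitude: float
    longitude: float
    status: str = "present"
    source: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.event_date is not None and self.event_date.year != self.year:
            raise ValueError("year does not match event_date")


@dataclass(frozen=True)
class PhenologySpecimen:
    """One scored herbarium sheet: taxon, full date, flowering intensity (%)."""

    taxon: str
    event_date: _dt.date
    intensity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 100.0:
            raise ValueError(f"intensity out of [0, 100]: {self.intensity}")

    @property
    def year(self) -> int:
        return self.event_date.year

    @property
    def doy(self) -> int:
        """Day of year on the actual calendar (leap years give Feb 29 = 60)."""
        return self.event_date.timetuple().tm_yday


@dataclass
class AnnualSeries:
    """A year-indexed series of real values with no gaps filled in.

    Absent years are omitted; ``years`` is strictly increasing and values are
    finite, one per year.
    """

    label: str
    years: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have equal length")
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing (no duplicates)")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("values must be finite (omit absent years)")

    def __len__(self) -> int:
        return int(self.years.size)

    @property
    def span(self) -> int:
        """Years between first and last entry (0 for a single year)."""
        if len(self) == 0:
            return 0
        return int(self.years[-1] - self.years[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})


@dataclass
class FilterRules:
    """Collection-effort filters for occurrence records.

    Defaults mirror the distribution-series rules: presence records with full
    binomial names, 1900-2020, at least 50 years between first and last record
    of a taxon, and at least 5 records per taxon-year.  The marine latitude
    range rule is off unless ``min_annual_lat_range_deg`` is set (0.4 deg for
    the marine collection).
    """

    min_span_years: int = 50
    min_records_per_taxon_year: int = 5
    year_min: int = 1900
    year_max: int = 2020
    require_presence: bool = True
    require_binomial: bool = True
    min_annual_lat_range_deg: float | None = None

    def __post_init__(self) -> None:
        if self.min_span_years < 0:
            raise ValueError("min_span_years must be >= 0")
        if self.year_min > self.year_max:
            raise ValueError("year_min must not exceed year_max")
        if self.min_annual_lat_range_deg is not None and self.min_annual_lat_range_deg <= 0:
            raise ValueError("min_annual_lat_range_deg must be positive when set")


def _parse_date(raw: object) -> tuple[_dt.date | None, int | None]:
    """Parse an ISO-8601 event date.

    Returns ``(date, year)``; a year-only string gives ``(None, year)`` and an
    unparseable value gives ``(None, None)``.  Timestamps with a time part are
    truncated to the date.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None, None
    text = str(raw).strip()
    if not text:
        return None, None
    # trim a time component if present
    for sep in ("T", " "):
        if sep in text:
            text = text.split(sep, 1)[0]
            break
    if re.fullmatch(r"\d{4}", text):
        return None, int(text)
    if re.fullmatch(r"\d{4}-\d{2}", text):  # year-month: not a full date
        return None, int(text[:4])
    try:
        return _dt.date.fromisoformat(text), int(text[:4])
    except ValueError:
        return None, None


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str)
    except FileNotFoundError:
        raise
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot read {path}: {exc}") from exc


def read_occurrences(
    path,
    column_map: Mapping[str, str] | None = None,
    keep_year_only: bool = False,
) -> list[OccurrenceRecord]:
    """Read an occurrence table into canonical records.

    Rows lacking coordinates, or whose event date cannot be parsed as an
    ISO-8601 full date, are dropped and the counts logged.  With
    ``keep_year_only=True`` a bare year is accepted (sufficient for
    distribution analyses; such records carry ``event_date=None``).
    """
    cmap = dict(DARWIN_CORE_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    required = [cmap[k] for k in ("taxon", "event_date", "latitude", "longitude")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"mapped columns absent from header: {missing}")

    records: list[OccurrenceRecord] = []
    n_bad_coord = n_bad_date = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        try:
            lat = float(row_d[cmap["latitude"]])
            lon = float(row_d[cmap["longitude"]])
        except (TypeError, ValueError):
            n_bad_coord += 1
            continue
        if not (np.isfinite(lat) and np.isfinite(lon)):
            n_bad_coord += 1
            continue
        date, year = _parse_date(row_d[cmap["event_date"]])
        if date is None and not (keep_year_only and year is not None):
            n_bad_date += 1
            continue
        raw_name = str(row_d[cmap["taxon"]])
        name = canonical_binomial(raw_name) or raw_name.strip()
        status = str(row_d.get(cmap["status"], "present") or "present").strip().lower()
        records.append(
            OccurrenceRecord(
                taxon=name,
                event_date=date,
                year=int(year),
                latitude=lat,
                longitude=lon,
                status=status,
                source=str(row_d.get(cmap["source"], "") or ""),
            )
        )
    if n_bad_coord or n_bad_date:
        logger.info(
            "read_occurrences(%s): dropped %d rows without coordinates, %d without a parseable date",
            path, n_bad_coord, n_bad_date,
        )
    return records


def read_phenology(path, column_map: Mapping[str, str] | None = None) -> list[PhenologySpecimen]:
    """Read a scored phenology table (columns taxon, date, intensity).

    Records without a precise (full) date or without an intensity are dropped
    with a logged count; phenology cannot use year-only dates.
    """
    cmap = {"taxon": "taxon", "event_date": "date", "intensity": "intensity"}
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(f"mapped columns absent from header: {missing}")
    out: list[PhenologySpecimen] = []
    dropped = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        date, _ = _parse_date(row_d[cmap["event_date"]])
        try:
            intensity = float(row_d[cmap["intensity"]])
        except (TypeError, ValueError):
            intensity = np.nan
        if date is None or not np.isfinite(intensity):
            dropped += 1
            continue
        name = canonical_binomial(str(row_d[cmap["taxon"]])) or str(row_d[cmap["taxon"]]).strip()
        out.append(PhenologySpecimen(taxon=name, event_date=date, intensity=intensity))
    if dropped:
        logger.info("read_phenology(%s): dropped %d rows without full date/intensity", path, dropped)
    return out


def filter_occurrences(
    records: Sequence[OccurrenceRecord],
    rules: FilterRules | None = None,
) -> tuple[list[OccurrenceRecord], dict[str, int]]:
    """Apply the collection-effort filters in their fixed order.

    Order: presence status, binomial name, year window, per-taxon span,
    per-taxon-year record count.  Returns the survivors and a per-rule drop
    count.  The span filter runs before the per-year count filter; the order
    changes survivors and is part of the contract.
    """
    rules = rules or FilterRules()
    drops = {"status": 0, "binomial": 0, "year_range": 0, "span": 0, "per_year_count": 0}
    current = list(records)

    if rules.require_presence:
        kept = [r for r in current if r.status == "present"]
        drops["status"] = len(current) - len(kept)
        current = kept

    if rules.require_binomial:
        kept = [r for r in current if canonical_binomial(r.taxon) is not None]
        drops["binomial"] = len(current) - len(kept)
        current = kept

    kept = [r for r in current if rules.year_min <= r.year <= rules.year_max]
    drops["year_range"] = len(current) - len(kept)
    current = kept

    span: dict[str, tuple[int, int]] = {}
    for r in current:
        lo, hi = span.get(r.taxon, (r.year, r.year))
        span[r.taxon] = (min(lo, r.year), max(hi, r.year))
    kept = [r for r in current if span[r.taxon][1] - span[r.taxon][0] >= rules.min_span_years]
    drops["span"] = len(current) - len(kept)
    current = kept

    counts: dict[tuple[str, int], int] = {}
    for r in current:
        counts[(r.taxon, r.year)] = counts.get((r.taxon, r.year), 0) + 1
    kept = [r for r in current if counts[(r.taxon, r.year)] >= rules.min_records_per_taxon_year]
    drops["per_year_count"] = len(current) - len(kept)
    current = kept

    logger.info("filter_occurrences: %d -> %d records, drops=%s", len(records), len(current), drops)
    return current, drops


def filter_marine_annual_range(
    records: Sequence[OccurrenceRecord], min_range: float = 0.4
) -> list[OccurrenceRecord]:
    """Remove taxon-years whose latitude range is below *min_range* degrees.

    Guards against years in which a species was sampled from a single
    locality; the comparison is strict (< min_range removed, == kept), and a
    single-record taxon-year (range 0) is always removed.
    """
    lat_range: dict[tuple[str, int], tuple[float, float]] = {}
    for r in records:
        key = (r.taxon, r.year)
        lo, hi = lat_range.get(key, (r.latitude, r.latitude))
        lat_range[key] = (min(lo, r.latitude), max(hi, r.latitude))
    # 1e-9 guard so a range exactly at the threshold survives float rounding
    return [
        r
        for r in records
        if lat_range[(r.taxon, r.year)][1] - lat_range[(r.taxon, r.year)][0]
        >= min_range - 1e-9
    ]


def records_to_frame(records: Sequence[OccurrenceRecord]) -> pd.DataFrame:
    """Canonical records as a flat table (one row per record), TSV-ready."""
    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in records],
            "event_date": [r.event_date.isoformat() if r.event_date else "" for r in records],
            "year": [r.year for r in records],
            "latitude": [r.latitude for r in records],
            "longitude": [r.longitude for r in records],
            "status": [r.status for r in records],
            "source": [r.source for r in records],
        }
    )


def aggregate_temperature(
    table: pd.DataFrame,
    mode: str = "annual_mean_across_stations",
    depth: float | None = None,
    label: str = "temperature",
    units: str = "degC",
) -> AnnualSeries:
    """Aggregate a station temperature table to an annual series.

    ``annual_mean_across_stations``: the annual value is the unweighted mean
    of all station-month values in that year (all station-months jointly, not
    station means of month means).  ``annual_max_at_depth``: the annual value
    is the maximum over that year's values at the requested depth.  Years with
    no rows are omitted.
    """
    df = table.copy()
    if "year" not in df.columns:
        if "date" in df.columns:
            df["year"] = pd.to_datetime(df["date"]).dt.year
        else:
            raise ConfigurationError("temperature table needs a 'year' or 'date' column")
    df["value"] = pd.to_numeric(df["value"])
    df["year"] = df["year"].astype(int)

    if mode == "annual_mean_across_stations":
        grouped = df.groupby("year")["value"].mean()
    elif mode == "annual_max_at_depth":
        if depth is None:
            raise ConfigurationError("annual_max_at_depth requires depth")
        sel = df[pd.to_numeric(df["depth"]) == depth]
        if sel.empty:
            logger.warning("aggregate_temperature: no rows at depth %s; empty series", depth)
            return AnnualSeries(label, np.array([], dtype=int), np.array([]), units)
        grouped = sel.groupby("year")["value"].max()
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    grouped = grouped.sort_index()
    return AnnualSeries(label, grouped.index.to_numpy(), grouped.to_numpy(), units)
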