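import datetime as dt

import numpy as np
import pytest

from ecofingerprint.ingest import OccurrenceRecord, PhenologySpecimen


def make_record(taxon="Carex livida", year=1950, lat=63.4, lon=10.4,
                status="present", doy=160):
    date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
    return OccurrenceRecord(taxon=taxon, event_date=date, year=year,
                            latitude=lat, longitude=lon, status=status)


def make_specimen(taxon="Draba alpina", year=1950, doy=170, intensity=50.0):
    date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
    return PhenologySpecimen(taxon=taxon, event_date=date, intensity=intensity)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
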