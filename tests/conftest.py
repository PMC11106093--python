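import datetime as dt

import pytest

from consortkit.ethogram import default_catalog
from consortkit.observations import Individual, ScanRecord, canonical_pair

#: arbitrary season anchor for date fixtures; day(n) = BASE + n days
BASE = dt.date(2019, 10, 1)


def day(n: int) -> dt.date:
    return BASE + dt.timedelta(days=n)


def scan(a: str, b: str, n: int, mount: bool = True, vd: bool = False,
         pair_type: str = "FF") -> ScanRecord:
    pa, pb = canonical_pair(a, b)
    return ScanRecord(date=day(n), id_a=pa, id_b=pb, pair_type=pair_type,
                      mount_observed=mount, vd_contact_observed=vd)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def small_roster():
    return [
        Individual("F01", "F", 8.0, "mat01", "parous", sterilized=True),
        Individual("F02", "F", 4.0, "mat01", "nulliparous"),
        Individual("F03", "F", 12.0, "mat02", "lactating"),
        Individual("F04", "F", 27.0, "mat03", "menopausal_like"),
        Individual("F05", "F", 6.5, "mat02", "parous"),
        Individual("M01", "M", 9.0, "mat04", "not_applicable"),
        Individual("M02", "M", 15.0, "mat01", "not_applicable"),
    ]
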