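import datetime as dt

import pytest

from rxcohort.records import DeathRecord, DispensingRecord


@pytest.fixture
def make_record():
    """Factory for dispensing records with sensible defaults."""

    def _make(
        patient_id="p1",
        day=0,
        atc_code="A10BA02",
        ddd_total=28.0,
        gender="male",
        birth_date=dt.date(1960, 1, 1),
        base=dt.date(2019, 2, 1),
        n_packages=1,
    ):
        return DispensingRecord(
            patient_id=patient_id,
            birth_date=birth_date,
            gender=gender,
            dispense_date=base + dt.timedelta(days=day),
            atc_code=atc_code,
            n_packages=n_packages,
            ddd_total=ddd_total,
        )

    return _make


@pytest.fixture(scope="session")
def subgroups_fixture():
    from rxcohort.synthetic import make_fixture

    return make_fixture("subgroups")


@pytest.fixture(scope="session")
def nine_day_fixture():
    from rxcohort.synthetic import make_fixture

    return make_fixture("nine_day")


@pytest.fixture(scope="session")
def enrollment_fixture():
    from rxcohort.synthetic import make_fixture

    return make_fixture("enrollment")
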