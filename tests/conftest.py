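import pytest

from sustainaswap import (
    IntakeRecord,
    NutrientVector,
    bundled_food_table,
    bundled_nrvs,
)


@pytest.fixture(scope="session")
def table():
    return bundled_food_table()


@pytest.fixture(scope="session")
def nrvs():
    return bundled_nrvs()


def make_record(pid="p1", serves=2.0, **nutrients) -> IntakeRecord:
    return IntakeRecord(
        person_id=pid,
        daily_intake=NutrientVector(**nutrients),
        reference_serves_per_week=serves,
    )


@pytest.fixture
def toy_cohort():
    """Ten records with hand-checkable intakes; 6 of 10 eat beef weekly."""
    irons = [10, 22, 23, 5, 30, 12, 22, 8, 15, 25]
    serves = [2, 0, 1, 3, 0, 0.5, 4, 0, 1, 2]
    return [
        make_record(f"p{i}", serves=s, iron=fe, protein=80.0, zinc=12.0,
                    calcium=900.0, dietary_fiber=20.0, folate_dfe=250.0)
        for i, (fe, s) in enumerate(zip(irons, serves))
    ]
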