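import pytest

from psyaudit import (
    CohortConfig,
    Cohort,
    Patient,
    Prescription,
    default_registry,
    generate_cohort,
    generate_kb_fixture,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def kb():
    """Knowledge-base fixture with only the published-table pairs."""
    return generate_kb_fixture()


@pytest.fixture(scope="session")
def kb_extended():
    """Fixture plus synthetic sedation pairs (higher match density)."""
    return generate_kb_fixture(extended=True)


@pytest.fixture
def make_patient(registry):
    counter = iter(range(10_000))

    def _make(drug_names, age=84, gender="F", prn=(), pid=None):
        prescriptions = [
            Prescription(drug=registry.lookup(name), as_needed=name in prn)
            for name in drug_names
        ]
        return Patient(
            id=pid or f"p{next(counter)}",
            age=age,
            gender=gender,
            prescriptions=prescriptions,
        )

    return _make


@pytest.fixture
def make_cohort(make_patient):
    def _make(drug_lists, label="test"):
        return Cohort(
            label=label, patients=[make_patient(names) for names in drug_lists]
        )

    return _make


@pytest.fixture(scope="session")
def cohort_2016(registry):
    return generate_cohort(CohortConfig.year_2016(seed=20160), registry)


@pytest.fixture(scope="session")
def cohort_2000(registry):
    return generate_cohort(CohortConfig.year_2000(seed=20000), registry)
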