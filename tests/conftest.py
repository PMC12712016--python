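import pytest

from cpnquant import (
    CountTable,
    InjectionCase,
    LabelingDataset,
    NeuronRecord,
    default_parcellation,
    load_table2_fixture,
)


@pytest.fixture(scope="session")
def parcellation():
    return default_parcellation()


@pytest.fixture(scope="session")
def fixture_entries():
    return load_table2_fixture()


@pytest.fixture()
def toy_dataset(parcellation):
    """Injection in F7: 10 ipsi F2 + 5 ipsi in F7 itself + 4 contra F7 + 2 contra F6."""
    case = InjectionCase(case_id="TOY", injected_hemisphere="R", injected_area="F7")
    records = (
        [NeuronRecord("TOY", 600 * i, "ipsi", "F2", "superficial") for i in range(10)]
        + [NeuronRecord("TOY", 600 * i, "ipsi", "F7", "deep") for i in range(5)]
        + [NeuronRecord("TOY", 600 * i, "contra", "F7", "superficial") for i in range(4)]
        + [NeuronRecord("TOY", 600 * i, "contra", "F6", "deep") for i in range(2)]
    )
    return LabelingDataset(cases=[case], records=records, parcellation=parcellation)


@pytest.fixture()
def toy_table():
    """Hand-checkable per-area counts for an injection in F7."""
    return CountTable(
        case_id="TOY2",
        injected_area="F7",
        per_area_ipsi={"F2": 30, "F6": 50, "24": 20},
        per_area_contra={"F7": 40, "F6": 30, "F2": 30},
    )
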