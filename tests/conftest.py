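import pytest

from healthdea import load_fixture, split_outcomes


@pytest.fixture(scope="session")
def surgery_table():
    """Six Ethiopian surgical-access policies; three negative impoverishment cells."""
    return load_fixture("ethiopia_surgery")


@pytest.fixture(scope="session")
def interventions_table():
    """Nine unrelated Ethiopian interventions; all outcomes nonnegative."""
    return load_fixture("ethiopia_interventions")


@pytest.fixture(scope="session")
def cancer_table():
    """Nine Ugandan surgical-oncology platforms; four outcomes incl. equity."""
    return load_fixture("uganda_cancer")


@pytest.fixture(scope="session")
def surgery_matrix(surgery_table):
    return split_outcomes(surgery_table)


@pytest.fixture(scope="session")
def interventions_matrix(interventions_table):
    return split_outcomes(interventions_table)


@pytest.fixture(scope="session")
def cancer_matrix(cancer_table):
    return split_outcomes(cancer_table)
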