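import pytest

from thermospot.classification import classify_table
from thermospot.spot_model import StudyRegion
from thermospot.studydata import reference_logs, reference_table


@pytest.fixture(scope="session")
def region():
    return StudyRegion()


@pytest.fixture(scope="session")
def ref_table():
    """Reference table matching the study's printed marginal counts."""
    return reference_table()


@pytest.fixture(scope="session")
def ref_logs(ref_table):
    return reference_logs(ref_table)


@pytest.fixture(scope="session")
def ref_classified(ref_table, ref_logs):
    """Reference table with categories re-derived from the response logs."""
    return classify_table(ref_table, ref_logs)
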