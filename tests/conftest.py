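import pytest

from rossercea import default_valuation_matrix
from rossercea.reference import reference_records, state_count_matrices


@pytest.fixture(scope="session")
def valuation():
    return default_valuation_matrix()


@pytest.fixture(scope="session")
def ref_matrices():
    """Published per-arm, per-timepoint health-state counts."""
    return state_count_matrices()


@pytest.fixture(scope="session")
def ref_records():
    """Participant records regenerated from the published state counts."""
    return reference_records()
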