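import pytest

from neocea import (
    TwoByTwoTable,
    default_control_profile,
    default_cost_parameters,
    default_intervention_profile,
)


@pytest.fixture
def params():
    return default_cost_parameters()


@pytest.fixture
def profiles():
    """(intervention, control) resource profiles of the reference scenario."""
    return default_intervention_profile(), default_control_profile()


@pytest.fixture
def table_1mo():
    """Reference 1-month ED-visit table: 18/114 control vs 5/90 intervention."""
    return TwoByTwoTable("1 month", 18, 96, 5, 85)


@pytest.fixture
def table_2mo():
    """Reference 2-month ED-visit table: 29/114 control vs 7/90 intervention."""
    return TwoByTwoTable("2 months", 29, 85, 7, 83)
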