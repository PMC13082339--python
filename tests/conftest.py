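import pytest

from phyllidsim import simulate
from phyllidsim.fixtures import TemplateSpec, make_template


@pytest.fixture(scope="session")
def template():
    return make_template(TemplateSpec())


@pytest.fixture(scope="session")
def wt_trajectory():
    """Full calibrated wild-type upper-phyllid run (shared across tests)."""
    return simulate("wt_upper")


@pytest.fixture(scope="session")
def pina_pinb_trajectory():
    return simulate("pina_pinb")


@pytest.fixture(scope="session")
def basal_trajectory():
    return simulate("basal")


@pytest.fixture(scope="session")
def auxin_wt_trajectory():
    return simulate("auxin_wt")


@pytest.fixture(scope="session")
def auxin_pina_pinb_trajectory():
    return simulate("auxin_pina_pinb")
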