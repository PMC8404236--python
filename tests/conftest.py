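import pytest
from hypothesis import settings

from ampliscreen.frda import default_decoy_reference
from ampliscreen.panel import build_amplicons, default_panel, load_table1, load_table3

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def panel_by_id(panel):
    return {v.variant_id: v for v in panel}


@pytest.fixture(scope="session")
def phenotypes(panel):
    return {v.variant_id: v.phenotype for v in panel}


@pytest.fixture(scope="session")
def genes(panel):
    return {v.variant_id: v.gene for v in panel}


@pytest.fixture(scope="session")
def amplicons(panel):
    return build_amplicons(panel)


@pytest.fixture(scope="session")
def amplicons_by_id(amplicons):
    return {a.amplicon_id: a for a in amplicons}


@pytest.fixture(scope="session")
def decoy():
    return default_decoy_reference()


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table3():
    return load_table3()
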