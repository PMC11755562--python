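import logging

import pytest

from piakit import build_paper_panel, fixtures

# panel assembly logs the documented coordinate corrections and overrides on
# every build; keep test output quiet
logging.getLogger("piakit").setLevel(logging.ERROR)
logging.getLogger("piakit.seqcore").setLevel(logging.ERROR)
logging.getLogger("piakit.paneldesign").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ecori_chain():
    return fixtures.ecori_chain()


@pytest.fixture(scope="session")
def paper_panel(ecori_chain):
    return build_paper_panel(ecori_chain)


@pytest.fixture(scope="session")
def golden():
    return fixtures.golden_descriptors()


@pytest.fixture(scope="session")
def whitelist():
    return fixtures.anomalous_cells()
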