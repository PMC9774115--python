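import hypothesis
import numpy as np
import pytest

from assayval import (
    InterlabSpec,
    PanelSpec,
    make_interlab,
    make_spike_panel,
    reconstruct_panel,
)
from assayval.fixtures import paper_fixture

hypothesis.settings.register_profile(
    "assayval", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("assayval")


@pytest.fixture(scope="session")
def fixture_panel():
    """Deterministic panel reproducing the published per-level moments."""
    return reconstruct_panel()


@pytest.fixture(scope="session")
def fixture():
    return paper_fixture()


@pytest.fixture(scope="session")
def default_panel():
    return make_spike_panel(PanelSpec(seed=11))


@pytest.fixture(scope="session")
def default_pairs():
    return make_interlab(InterlabSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
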