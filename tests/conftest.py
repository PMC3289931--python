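import numpy as np
import pytest

from sagesig.libnorm import make_virtual_library, normalize
from sagesig.synthetic import paper_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def scenario():
    """The study-shaped synthetic dataset, built once per session."""
    return paper_scenario(seed=1)


@pytest.fixture(scope="session")
def scenario_virtual(scenario):
    nm = [lib.gene_counts for lib in scenario.nm_libraries]
    return make_virtual_library(normalize(nm[0]), normalize(nm[1]),
                                library_id="NMvirtual")
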