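import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from crmou import builtin_regimes, drosophila_tree, parse_newick


@pytest.fixture(scope="session")
def tree12():
    return drosophila_tree()


@pytest.fixture(scope="session")
def paintings12(tree12):
    return {p.model_id: p for p in builtin_regimes(tree12)}


@pytest.fixture(scope="session")
def tree5():
    return parse_newick("((A:1,B:1):1,(C:0.5,(D:0.3,E:0.3):0.2):1.5);")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
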