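import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from intronsim.engine import MD, run
from intronsim.experiment import named_tests
from intronsim.tree import fixture_tree

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tree14():
    """The default 14-leaf fixture guide tree."""
    return fixture_tree(1)


@pytest.fixture(scope="session")
def md23_result(tree14):
    """One deletion-model run with the best-performing named parameters."""
    return run(tree14, named_tests(MD)["MD_23"].with_seed(7))


@pytest.fixture(scope="session")
def md23_leaves(md23_result):
    return list(md23_result.leaves.values())
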