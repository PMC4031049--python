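from __future__ import annotations

import pytest

from synlethal.model import apply_medium
from synlethal.synthetic_data import fixture_suite, kitchen_sink, toy_psl, toy_rsl

SUITE_SEED = 1234
SUITE_SIZE = 100


@pytest.fixture(scope="session")
def fixture_suite_dirs(tmp_path_factory):
    """The full randomized fixture suite, written once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return fixture_suite(SUITE_SEED, SUITE_SIZE, out)


@pytest.fixture(scope="session")
def rsl_fixture():
    """(model-with-medium, reference medium, truth) for the redundancy toy."""
    model, medium, truth = toy_rsl()
    return apply_medium(model, medium), medium, truth


@pytest.fixture(scope="session")
def psl_fixture():
    model, medium, truth = toy_psl()
    return apply_medium(model, medium), medium, truth


@pytest.fixture(scope="session")
def kitchen_sink_fixture():
    model, medium, truth = kitchen_sink(seed=7)
    return model, medium, truth
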