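"""Shared fixtures: toy structures and models, built once per session."""

import numpy as np
import pytest

from switchpath.fixtures import (build_hairpin_model, make_hairpin,
                                 make_toy_aff, make_two_hand_fold)

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def hairpin_structure():
    return make_hairpin()


@pytest.fixture(scope="session")
def hairpin_model():
    return build_hairpin_model()


@pytest.fixture(scope="session")
def two_hand_structure():
    return make_two_hand_fold()


@pytest.fixture(scope="session")
def toy_aff():
    return make_toy_aff()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
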