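import dataclasses

import numpy as np
import pytest

from bindsteer import FixtureSpec, build_synthetic_system


@pytest.fixture(scope="session")
def fixture_system():
    """Synthetic receptor structure + draft engine config (crystal-geometry layout)."""
    return build_synthetic_system(FixtureSpec())


@pytest.fixture(scope="session")
def structure(fixture_system):
    return fixture_system[0]


@pytest.fixture(scope="session")
def draft_config(fixture_system):
    return fixture_system[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20210423)


def small_run_config(draft_config, **overrides):
    defaults = dict(n_steps=2000, record_stride=20, seed=7)
    defaults.update(overrides)
    return dataclasses.replace(draft_config, **defaults)
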