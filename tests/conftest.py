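"""Shared fixtures.

The expensive simulation artifacts (a settled 10-cycle mechanics run and
its fluid counterpart) are session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from cardioloop.config import RunConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from cardioloop.geometry import build_grid, make_chamber
from cardioloop.mechanics import run_mechanics


@pytest.fixture()
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def default_geom():
    return make_chamber()


@pytest.fixture(scope="session")
def default_mesh(default_geom):
    return build_grid(default_geom, n_r=8)


@pytest.fixture(scope="session")
def settled_mech():
    """Uncoupled 10-cycle mechanics run on the default preset."""
    return run_mechanics(RunConfig(), n_cycles=10)


@pytest.fixture(scope="session")
def short_mech():
    """Cheap 3-cycle mechanics run for tests that only need a plausible
    wall-motion/pressure hand-off."""
    return run_mechanics(RunConfig(), n_cycles=3)
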