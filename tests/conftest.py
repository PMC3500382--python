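"""Shared fixtures: small huddles with known geometry."""

import numpy as np
import pytest

from huddlesim.lattice import Huddle


@pytest.fixture(scope="session")
def hex7():
    """Filled hexagon: centre penguin plus its six neighbours."""
    return Huddle([(0, 0), (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1),
                   (1, -1)])


@pytest.fixture(scope="session")
def strip2x10():
    """Two-row strip, ten penguins per row."""
    return Huddle([(a, 0) for a in range(10)] + [(a, 1) for a in range(10)])


@pytest.fixture(scope="session")
def hex19():
    """Filled hexagon of radius 2 (19 penguins)."""
    sites = [(a, b) for a in range(-2, 3) for b in range(-2, 3)
             if max(abs(a), abs(b), abs(a + b)) <= 2]
    return Huddle(sites)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
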