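"""Shared fixtures: synthetic faces, scan pairs, and cohorts.

Everything is generated programmatically; the heavier cohorts are
session-scoped so the whole suite builds them once.
"""

import numpy as np
import pytest

from prosthoface.synthetic import (
    CollapseParams,
    FaceParams,
    generate_cohort,
    generate_face,
    generate_pair,
    icosphere,
    plane_grid,
)


@pytest.fixture(scope="session")
def default_face():
    """The default symmetric synthetic face and its landmarks."""
    return generate_face(FaceParams())


@pytest.fixture(scope="session")
def default_pair():
    """One pre/post pair at 2 mm collapse depth with scanner noise."""
    return generate_pair(collapse=CollapseParams(latent=(2.0, 0.0), noise_sd=0.02, seed=7))


@pytest.fixture(scope="session")
def cohort10():
    """The default 10-subject study cohort (nominal depth 2 mm)."""
    return generate_cohort(10, collapse=CollapseParams(latent=(2.0, 0.0)), seed=42)


@pytest.fixture(scope="session")
def cohort200():
    """Large cohort for parameter-recovery statistics."""
    return generate_cohort(200, collapse=CollapseParams(latent=(2.0, 0.0)), seed=5)


@pytest.fixture(scope="session")
def unit_sphere():
    return icosphere(1.0, 4)


@pytest.fixture()
def flat_grid():
    return plane_grid(20, 20, 10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
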