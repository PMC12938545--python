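"""Shared fixtures: compact phantoms kept session-scoped because rasterization
dominates test runtime."""

import numpy as np
import pytest

from plugforge.geometry import LumenMap
from plugforge.phantom import PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A compact depth-2 phantom that builds in well under a second."""
    defaults = dict(
        volume_shape=(72, 72, 72),
        spacing_mm=(1.0, 1.0, 1.0),
        tree_depth=2,
        root_radius_mm=3.5,
        radius_taper=0.8,
        branch_length_mm=18.0,
        length_taper=0.85,
        vessel_offset_mm=9.0,
        seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def anatomy():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def clean_anatomy():
    """Noise-free variant (deterministic HU values)."""
    return generate_phantom(small_spec(noise_sigma_hu=0.0))


@pytest.fixture(scope="session")
def lumen_map(anatomy):
    return LumenMap(anatomy)


@pytest.fixture(scope="session")
def default_anatomy():
    """One phantom at the full default (study-condition) geometry."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def default_lumen_map(default_anatomy):
    return LumenMap(default_anatomy)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
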