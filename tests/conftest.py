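import numpy as np
import pytest

import embryomech as em
from embryomech.geometry import build_fluid_domain
from embryomech.pipeline import build_embryo


@pytest.fixture(scope="session")
def small_spec():
    return em.EmbryoGeometrySpec(n_cells=60, seed=1, lloyd_iterations=25)


@pytest.fixture(scope="session")
def small_tiling(small_spec):
    return em.make_ellipsoid_tiling(small_spec)


@pytest.fixture(scope="session")
def small_mesh(small_spec, small_tiling):
    return em.build_embryo_mesh(small_tiling, small_spec)


@pytest.fixture(scope="session")
def ball_domain():
    """Near-spherical uniform-viscosity test domain (coarse)."""
    spec = em.EmbryoGeometrySpec(
        long_axis=102.0, short_axis=100.0, n_cells=20,
        height_mid=10.0, height_pole=5.0, perivitelline_gap=3.0,
    )
    return build_fluid_domain(spec, resolution=10.0, collapse_gap=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
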