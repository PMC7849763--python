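"""Shared fixtures: small phantoms and geometries sized for fast tests."""

import numpy as np
import pytest

import recon4d as r4d
from recon4d.pipeline import desk_geometry, simulate_projections


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_spec():
    """Coarse 32x32x24 @ 4 mm phantom — same physical extent as the desk
    grid, eight times fewer voxels."""
    return r4d.PhantomSpec(grid_shape=(24, 32, 32), voxel_mm=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def small_phases(small_spec):
    return [r4d.build_phantom_phase(small_spec, t)
            for t in range(small_spec.n_phases)]


@pytest.fixture(scope="session")
def small_motion(small_spec):
    return r4d.ground_truth_motion(small_spec)


@pytest.fixture(scope="session")
def geometry():
    return desk_geometry()


@pytest.fixture(scope="session")
def small_projections(small_spec, geometry):
    projs, phases = simulate_projections(small_spec, geometry, 20)
    return projs


@pytest.fixture
def tiny_geometry():
    return r4d.ConeBeamGeometry(sad=1000.0, sdd=1500.0, det_rows=24,
                                det_cols=24, det_pitch=8.0)
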