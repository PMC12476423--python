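import numpy as np
import pytest

import octodeform as od


@pytest.fixture(scope="session")
def sphere_mesh():
    """Unit geodesic sphere, ~640 vertices."""
    return od.make_synthetic_organ("icosphere", 640)


@pytest.fixture(scope="session")
def blob_mesh():
    """Perturbed organ-like blob, ~2500 vertices, fixed seed."""
    return od.make_synthetic_organ("blob", 2500, seed=7, bump_amplitude=0.15)


@pytest.fixture(scope="session")
def blob_lattice(blob_mesh):
    return od.build_octree(blob_mesh, max_level=2)


@pytest.fixture(scope="session")
def blob_pieces(blob_mesh, blob_lattice):
    return od.split_mesh(blob_mesh, blob_lattice)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def unit_cube_rest():
    """Rest corner positions of the unit cube in the fixed corner convention."""
    from octodeform.octree import CORNER_OFFSETS
    return CORNER_OFFSETS.astype(float)


def deformed_state(lattice, amplitude=0.08, seed=0):
    """Lattice state with a seeded smooth random corner perturbation."""
    state = od.LatticeState.from_lattice(lattice)
    r = np.random.default_rng(seed)
    state.positions = state.positions + amplitude * r.normal(size=state.positions.shape)
    state.predicted = state.positions.copy()
    return state
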