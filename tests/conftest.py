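import numpy as np
import pytest

from ilsolv.core import AtomDef, Box, SpeciesDef, Topology, Trajectory


@pytest.fixture
def box4000():
    return Box(np.array([4000.0, 4000.0, 4000.0]))


@pytest.fixture
def two_atom_topology():
    """Two single-atom molecules with distinct labels A and B."""
    a = SpeciesDef(name="molA", atoms=(AtomDef("N", "A", 14.0),))
    b = SpeciesDef(name="molB", atoms=(AtomDef("O", "B", 16.0),))
    return Topology([(a, 1), (b, 1)])


def make_static_trajectory(positions, box_edge=4000.0, n_frames=1, timestep=1.0):
    """Trajectory repeating the same frame."""
    positions = np.asarray(positions, dtype=float)
    coords = np.broadcast_to(positions, (n_frames, *positions.shape)).copy()
    return Trajectory(coords, np.array([box_edge] * 3), timestep=timestep, wrapped=True)


def brute_force_min_image(a, b, lengths):
    """Reference minimum-image displacement by enumerating all 27 neighbor images."""
    best = None
    best_norm = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz], dtype=float) * lengths
                d = np.asarray(b) - np.asarray(a) + shift
                n = np.linalg.norm(d)
                if n < best_norm:
                    best_norm = n
                    best = d
    return best, best_norm
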