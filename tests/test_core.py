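import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ilsolv.core import (
    AtomDef,
    Box,
    SpeciesDef,
    Topology,
    Trajectory,
    center_of_mass,
    fold,
    minimum_image,
    read_trajectory,
    unwrap,
)
from ilsolv.errors import ConfigError, FormatError, SelectionError, UnwrapError

from conftest import brute_force_min_image


# ---------------------------------------------------------------------------
# Box / minimum image
# ---------------------------------------------------------------------------

class TestMinimumImage:
    def test_no_wrap(self, box4000):
        d = minimum_image([0, 0, 0], [100, 0, 0], box4000)
        assert np.allclose(d, [100, 0, 0])

    def test_wrap(self, box4000):
        d = minimum_image([0, 0, 0], [3900, 0, 0], box4000)
        assert np.allclose(d, [-100, 0, 0])

    def test_half_edge_convention(self, box4000):
        # components must land in (-L/2, L/2]
        d = minimum_image([0, 0, 0], [2000, 0, 0], box4000)
        assert d[0] == 2000.0
        d = minimum_image([0, 0, 0], [-2000, 0, 0], box4000)
        assert d[0] == 2000.0

    def test_brute_force_agreement_bulk(self):
        rng = np.random.default_rng(42)
        lengths = np.array([3100.0, 4000.0, 5300.0])
        box = Box(lengths)
        a = rng.uniform(-2e4, 2e4, size=(10_000, 3))
        b = rng.uniform(-2e4, 2e4, size=(10_000, 3))
        mi = box.minimum_image(b - a)
        norms = np.linalg.norm(mi, axis=1)
        for i in range(0, 10_000, 13):
            _, ref_norm = brute_force_min_image(a[i] % lengths, b[i] % lengths, lengths)
            assert norms[i] <= ref_norm + 1e-9

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=6, max_size=6))
    def test_brute_force_agreement_property(self, vals):
        lengths = np.array([3000.0, 4000.0, 5000.0])
        box = Box(lengths)
        a, b = np.array(vals[:3]), np.array(vals[3:])
        d = box.minimum_image(b - a)
        _, ref_norm = brute_force_min_image(a % lengths, b % lengths, lengths)
        assert np.linalg.norm(d) <= ref_norm + 1e-9

    def test_invalid_box_rejected(self):
        with pytest.raises(ConfigError):
            Box(np.array([0.0, 1.0, 1.0]))
        with pytest.raises(ConfigError):
            Box(np.array([-5.0, 1.0, 1.0]))


# ---------------------------------------------------------------------------
# Trajectory type
# ---------------------------------------------------------------------------

class TestTrajectory:
    def test_invariants_enforced(self):
        coords = np.zeros((2, 3, 3))
        with pytest.raises(ConfigError):
            Trajectory(coords, np.array([4000.0, 4000.0, 4000.0]), timestep=0.0)
        bad = coords.copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ConfigError):
            Trajectory(bad, np.array([4000.0] * 3), timestep=1.0)
        with pytest.raises(ConfigError):
            Trajectory(coords, np.array([4000.0, -1.0, 4000.0]), timestep=1.0)


# ---------------------------------------------------------------------------
# XYZ reader
# ---------------------------------------------------------------------------

XYZ_TWO_FRAMES = """3
frame 0
C 1.0 2.0 3.0
H 0.0 0.0 0.0
O 5.0 5.0 5.0
3
frame 1
C 1.5 2.0 3.0
H 0.1 0.0 0.0
O 5.0 5.5 5.0
"""


class TestXYZReader:
    def test_counts_and_units(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text(XYZ_TWO_FRAMES)
        traj = read_trajectory(path, format="xyz", timestep=0.5, box=[4000.0] * 3)
        assert traj.n_frames == 2
        assert traj.n_atoms == 3
        # 1 Angstrom = 100 pm
        assert np.allclose(traj.coords[0, 0], [100.0, 200.0, 300.0])
        assert np.allclose(traj.box, 4000.0)

    def test_lattice_comment_box(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text('1\nLattice="40 0 0 0 40 0 0 0 40"\nC 0 0 0\n')
        traj = read_trajectory(path, format="xyz", timestep=1.0)
        assert np.allclose(traj.box[0], 4000.0)

    def test_triclinic_lattice_rejected(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text('1\nLattice="40 1 0 0 40 0 0 0 40"\nC 0 0 0\n')
        with pytest.raises(ConfigError):
            read_trajectory(path, format="xyz", timestep=1.0)

    def test_missing_box_is_config_error(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text("1\nno box here at all\nC 0 0 0\n")
        with pytest.raises(ConfigError):
            read_trajectory(path, format="xyz", timestep=1.0)

    def test_atom_count_mismatch_names_frame(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text(
            "3\nc0\nC 0 0 0\nC 1 0 0\nC 2 0 0\n"
            "3\nc1\nC 0 0 0\nC 1 0 0\nC 2 0 0\n"
            "4\nc2\nC 0 0 0\nC 1 0 0\nC 2 0 0\nC 3 0 0\n")
        with pytest.raises(FormatError, match="frame 2"):
            read_trajectory(path, format="xyz", timestep=1.0, box=[4000.0] * 3)

    def test_truncated_final_frame_names_offset(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text("2\nc0\nC 0 0 0\nC 1 0 0\n2\nc1\nC 0 0 0\n")
        with pytest.raises(FormatError, match="byte offset"):
            read_trajectory(path, format="xyz", timestep=1.0, box=[4000.0] * 3)


# ---------------------------------------------------------------------------
# LAMMPS dump reader
# ---------------------------------------------------------------------------

def dump_text(frames, wrapped=True, lo=0.0, hi=40.0):
    cols = "x y z" if wrapped else "xu yu zu"
    out = []
    for t, coords in enumerate(frames):
        out.append("ITEM: TIMESTEP\n%d\n" % t)
        out.append("ITEM: NUMBER OF ATOMS\n%d\n" % len(coords))
        out.append("ITEM: BOX BOUNDS pp pp pp\n")
        out.extend(f"{lo} {hi}\n" for _ in range(3))
        out.append(f"ITEM: ATOMS id type {cols}\n")
        for i, (x, y, z) in enumerate(coords):
            out.append(f"{i + 1} 1 {x} {y} {z}\n")
    return "".join(out)


class TestDumpReader:
    def test_box_bounds_unit_conversion(self, tmp_path):
        path = tmp_path / "t.dump"
        path.write_text(dump_text([[(1.0, 2.0, 3.0)]], lo=0.0, hi=40.0))
        traj = read_trajectory(path, format="lammps-dump", timestep=1.0)
        assert np.allclose(traj.box[0], [4000.0, 4000.0, 4000.0])
        assert np.allclose(traj.coords[0, 0], [100.0, 200.0, 300.0])
        assert traj.wrapped

    def test_unwrapped_columns_detected(self, tmp_path):
        path = tmp_path / "t.dump"
        path.write_text(dump_text([[(1.0, 2.0, 3.0)]], wrapped=False))
        traj = read_trajectory(path, format="lammps-dump", timestep=1.0)
        assert not traj.wrapped

    def test_atom_ids_reordered(self, tmp_path):
        text = ("ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n2\n"
                "ITEM: BOX BOUNDS pp pp pp\n0 40\n0 40\n0 40\n"
                "ITEM: ATOMS id type x y z\n2 1 9 9 9\n1 1 1 1 1\n")
        path = tmp_path / "t.dump"
        path.write_text(text)
        traj = read_trajectory(path, format="lammps-dump", timestep=1.0)
        assert np.allclose(traj.coords[0, 0], [100.0, 100.0, 100.0])

    def test_triclinic_rejected(self, tmp_path):
        text = ("ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n1\n"
                "ITEM: BOX BOUNDS xy xz yz pp pp pp\n0 40 1\n0 40 0\n0 40 0\n"
                "ITEM: ATOMS id type x y z\n1 1 1 1 1\n")
        path = tmp_path / "t.dump"
        path.write_text(text)
        with pytest.raises(ConfigError):
            read_trajectory(path, format="lammps-dump", timestep=1.0)

    def test_count_mismatch(self, tmp_path):
        frames = [[(1.0, 1.0, 1.0)], [(1.0, 1.0, 1.0), (2.0, 2.0, 2.0)]]
        path = tmp_path / "t.dump"
        path.write_text(dump_text(frames))
        with pytest.raises(FormatError, match="frame 1"):
            read_trajectory(path, format="lammps-dump", timestep=1.0)


# ---------------------------------------------------------------------------
# unwrap / fold
# ---------------------------------------------------------------------------

class TestUnwrap:
    def test_constructed_drift(self):
        # +150 pm/frame through a 4000 pm box for 100 frames
        x = (np.arange(101) * 150.0) % 4000.0
        coords = np.zeros((101, 1, 3))
        coords[:, 0, 0] = x
        traj = Trajectory(coords, np.array([4000.0] * 3), timestep=1.0, wrapped=True)
        un = unwrap(traj)
        assert un.coords[100, 0, 0] == pytest.approx(15000.0)
        assert not un.wrapped

    def test_stationary_identity(self):
        coords = np.full((10, 4, 3), 1234.5)
        traj = Trajectory(coords, np.array([4000.0] * 3), timestep=1.0, wrapped=True)
        un = unwrap(traj)
        assert np.array_equal(un.coords, coords)

    def test_round_trip_bit_identical_quantized(self):
        # coordinates on a 2^-20 pm lattice in a power-of-two box: every
        # image shift is exact in binary floating point, so the fold/unwrap
        # round trip must be bit-identical
        rng = np.random.default_rng(7)
        L = 4096.0
        steps = np.round(rng.normal(0, 30, size=(400, 50, 3)) * 2 ** 20) / 2 ** 20
        start = np.round(rng.uniform(0, L, size=(50, 3)) * 2 ** 20) / 2 ** 20
        path = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
        wrapped = path - L * np.floor(path / L)
        traj = Trajectory(wrapped, np.array([L] * 3), timestep=1.0, wrapped=True)
        back = fold(unwrap(traj))
        assert np.array_equal(back.coords, traj.coords)

    def test_round_trip_close_generic(self):
        from ilsolv.synth import gen_brownian
        traj, _ = gen_brownian(20, 200, 4000.0, 50.0, seed=11)
        wrapped = fold(traj)
        back = fold(unwrap(wrapped))
        assert np.allclose(back.coords, wrapped.coords, atol=1e-9)

    def test_ambiguous_jump_names_atom_and_frame(self):
        coords = np.zeros((2, 2, 3))
        coords[1, 1, 0] = 2000.0   # exactly L/2: ambiguous
        traj = Trajectory(coords, np.array([4000.0] * 3), timestep=1.0, wrapped=True)
        with pytest.raises(UnwrapError, match="atom 1.*frames 0 and 1"):
            unwrap(traj)

    def test_already_unwrapped_rejected(self):
        traj = Trajectory(np.zeros((2, 1, 3)), np.array([4000.0] * 3),
                          timestep=1.0, wrapped=False)
        with pytest.raises(ConfigError):
            unwrap(traj)


# ---------------------------------------------------------------------------
# center of mass
# ---------------------------------------------------------------------------

def _two_atom_topo(m1, m2):
    spec = SpeciesDef(name="dimer", atoms=(AtomDef("C", "C1", m1), AtomDef("C", "C2", m2)))
    return Topology([(spec, 1)])


class TestCenterOfMass:
    def test_equal_masses_symmetry(self):
        topo = _two_atom_topo(12.0, 12.0)
        coords = np.array([[0.0, 0, 0], [200.0, 0, 0]])
        com = center_of_mass(coords, [0, 1], topo)
        assert np.allclose(com, [100.0, 0, 0])

    def test_weighted_mean(self):
        topo = _two_atom_topo(1.0, 3.0)
        coords = np.array([[0.0, 0, 0], [400.0, 0, 0]])
        com = center_of_mass(coords, [0, 1], topo)
        assert np.allclose(com, [300.0, 0, 0])

    def test_split_across_boundary(self, box4000):
        topo = _two_atom_topo(12.0, 12.0)
        coords = np.array([[3950.0, 0, 0], [50.0, 0, 0]])
        com = center_of_mass(coords, [0, 1], topo, box=box4000)
        # the molecule is whole at 3950..4050, so its center is at 0 (mod L)
        assert min(com[0], 4000.0 - com[0]) == pytest.approx(0.0, abs=1e-9)

    def test_zero_mass_error(self):
        spec = SpeciesDef(name="x", atoms=(AtomDef("C", "C1", 1e-30),))
        topo = Topology([(spec, 1)])
        topo.mass[:] = 0.0
        with pytest.raises(ConfigError):
            center_of_mass(np.zeros((1, 3)), [0], topo)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1000, 1000), min_size=3, max_size=3))
    def test_translation_equivariance(self, shift):
        topo = _two_atom_topo(1.0, 3.0)
        box = Box(np.array([4000.0] * 3))
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 500, size=(2, 3))
        v = np.array(shift)
        com0 = center_of_mass(box.wrap(coords), [0, 1], topo, box=box)
        com1 = center_of_mass(box.wrap(coords + v), [0, 1], topo, box=box)
        d = box.minimum_image(com1 - (com0 + v))
        assert np.allclose(d, 0.0, atol=1e-6)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

class TestTopology:
    def test_yaml_round_trip(self, tmp_path):
        spec = SpeciesDef(
            name="cation",
            atoms=(AtomDef("H", "H(Ring)", 1.008, charge=0.2),
                   AtomDef("C", "C(Ring)", 12.011, sigma=350.0, epsilon=0.29)),
            rings={"aromatic": [0, 1]})
        topo = Topology([(spec, 3)])
        path = tmp_path / "topo.yaml"
        topo.to_yaml(path)
        back = Topology.from_yaml(path)
        assert back.n_atoms == topo.n_atoms
        assert back.n_molecules == 3
        assert list(back.site_label) == list(topo.site_label)
        assert np.allclose(back.mass, topo.mass)
        assert back.species["cation"].rings == {"aromatic": [0, 1]}

    def test_every_atom_in_exactly_one_molecule(self):
        spec = SpeciesDef(name="m", atoms=(AtomDef("C", "C1", 12.0),) * 3)
        topo = Topology([(spec, 4)])
        seen = np.concatenate([m.indices for m in topo.molecules])
        assert np.array_equal(np.sort(seen), np.arange(12))

    def test_unknown_label_raises(self, two_atom_topology):
        with pytest.raises(SelectionError, match="H\\(Foo\\)"):
            two_atom_topology.select("H(Foo)")

    def test_mass_positive_enforced(self):
        with pytest.raises(ConfigError):
            SpeciesDef(name="m", atoms=(AtomDef("C", "C1", -1.0),))
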