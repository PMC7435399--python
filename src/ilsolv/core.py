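"""Domain types, trajectory/topology readers and periodic-boundary geometry.

Internal unit conventions, applied on ingest by every reader:

* length  -- picometre (pm); file formats using Angstrom are converted (1 A = 100 pm)
* time    -- picosecond (ps)
* mass    -- atomic mass unit (amu)
* energy  -- kJ/mol
* charge  -- elementary charge (e)

Only orthorhombic simulation cells are supported; triclinic input is
rejected with :class:`~ilsolv.errors.ConfigError`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ConfigError, FormatError, SelectionError, UnwrapError

PM_PER_ANGSTROM = 100.0


# ---------------------------------------------------------------------------
# Box and minimum-image geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic cell with edge lengths in pm."""

    lengths: np.ndarray

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.shape != (3,):
            raise ConfigError(f"box must have three edge lengths, got shape {lengths.shape}")
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise ConfigError(f"box edges must be positive and finite, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def volume_pm3(self) -> float:
        return float(np.prod(self.lengths))

    def minimum_image(self, delta: np.ndarray) -> np.ndarray:
        """Map displacement components into (-L/2, L/2]."""
        delta = np.asarray(delta, dtype=float)
        L = self.lengths
        return delta - L * np.ceil(delta / L - 0.5)

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Fold coordinates into [0, L) per component."""
        coords = np.asarray(coords, dtype=float)
        L = self.lengths
        wrapped = coords - L * np.floor(coords / L)
        # floor can leave exactly L for values a hair below 0
        wrapped[wrapped >= L] -= np.broadcast_to(L, wrapped.shape)[wrapped >= L]
        return wrapped


def minimum_image(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image displacement from ``a`` to ``b`` (``b - a`` wrapped).

    Each component of the result lies in ``(-L/2, L/2]``.
    """
    return box.minimum_image(np.asarray(b, dtype=float) - np.asarray(a, dtype=float))


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    d = minimum_image(a, b, box)
    return np.linalg.norm(d, axis=-1)


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames x atoms Cartesian coordinates with a periodic box per frame.

    Attributes
    ----------
    coords : (n_frames, n_atoms, 3) float array, pm
    box : (n_frames, 3) float array, pm, orthorhombic edge lengths
    timestep : frame spacing in ps
    wrapped : True when coordinates are folded into the box
    images : optional (n_frames, n_atoms, 3) integer array of periodic image
        counts recorded by :func:`unwrap`, used by :func:`fold` for an exact
        round trip.
    """

    coords: np.ndarray
    box: np.ndarray
    timestep: float
    wrapped: bool = True
    images: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConfigError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ConfigError("coordinates contain non-finite values")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape == (3,):
            self.box = np.broadcast_to(self.box, (self.n_frames, 3)).copy()
        if self.box.shape != (self.n_frames, 3):
            raise ConfigError(f"box must be (frames, 3) or (3,), got {self.box.shape}")
        if np.any(self.box <= 0) or not np.all(np.isfinite(self.box)):
            raise ConfigError("box edges must be positive and finite")
        if not (self.timestep > 0):
            raise ConfigError(f"timestep must be > 0, got {self.timestep}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def box_at(self, frame: int) -> Box:
        return Box(self.box[frame])

    def constant_box(self) -> Box:
        if not np.all(self.box == self.box[0]):
            raise ConfigError("operation requires a constant box across frames")
        return Box(self.box[0])


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomDef:
    """One atom in a species template."""

    element: str
    label: str
    mass: float
    charge: float = float("nan")
    sigma: float = float("nan")    # LJ sigma, pm
    epsilon: float = float("nan")  # LJ epsilon, kJ/mol


@dataclass(frozen=True)
class SpeciesDef:
    """A molecule template: ordered atoms plus named ring index lists."""

    name: str
    atoms: tuple
    rings: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        for atom in self.atoms:
            if atom.mass <= 0:
                raise ConfigError(f"species {self.name!r}: mass must be > 0 for {atom.label}")
        n = len(self.atoms)
        for ring_name, idx in self.rings.items():
            if any(i < 0 or i >= n for i in idx):
                raise ConfigError(
                    f"species {self.name!r}: ring {ring_name!r} references atom out of range")


@dataclass
class Molecule:
    species: str
    indices: np.ndarray  # absolute atom indices, contiguous


class Topology:
    """Per-atom roles (element, site label, mass, nonbonded parameters) and
    molecule membership for a simulation system.

    Built by repeating species templates; every atom belongs to exactly one
    molecule.
    """

    def __init__(self, blocks: list[tuple[SpeciesDef, int]]):
        elements, labels, masses, charges, sigmas, epsilons = [], [], [], [], [], []
        mol_ids, species_per_atom = [], []
        self.molecules: list[Molecule] = []
        self.species: dict[str, SpeciesDef] = {}
        offset = 0
        for spec, count in blocks:
            if count < 0:
                raise ConfigError(f"species {spec.name!r}: count must be >= 0")
            if spec.name in self.species and self.species[spec.name] is not spec:
                raise ConfigError(f"duplicate species name {spec.name!r}")
            self.species[spec.name] = spec
            natoms = len(spec.atoms)
            for _ in range(count):
                idx = np.arange(offset, offset + natoms)
                self.molecules.append(Molecule(spec.name, idx))
                for atom in spec.atoms:
                    elements.append(atom.element)
                    labels.append(atom.label)
                    masses.append(atom.mass)
                    charges.append(atom.charge)
                    sigmas.append(atom.sigma)
                    epsilons.append(atom.epsilon)
                    mol_ids.append(len(self.molecules) - 1)
                    species_per_atom.append(spec.name)
                offset += natoms
        self.element = np.array(elements, dtype=object)
        self.site_label = np.array(labels, dtype=object)
        self.mass = np.array(masses, dtype=float)
        self.charge = np.array(charges, dtype=float)
        self.sigma = np.array(sigmas, dtype=float)
        self.epsilon = np.array(epsilons, dtype=float)
        self.molecule_id = np.array(mol_ids, dtype=np.int64)
        self.atom_species = np.array(species_per_atom, dtype=object)

    @property
    def n_atoms(self) -> int:
        return self.element.size

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def labels(self) -> set:
        return set(self.site_label.tolist())

    def select(self, labels) -> np.ndarray:
        """Atom indices whose site label is in ``labels`` (str or iterable)."""
        if isinstance(labels, str):
            labels = [labels]
        labels = list(labels)
        known = self.labels()
        for lab in labels:
            if lab not in known:
                raise SelectionError(f"unknown site label {lab!r}")
        mask = np.isin(self.site_label, labels)
        return np.nonzero(mask)[0]

    def molecules_of(self, species: str) -> list[Molecule]:
        mols = [m for m in self.molecules if m.species == species]
        if not mols:
            raise SelectionError(f"no molecules of species {species!r}")
        return mols

    def ring_indices(self, species: str, ring: str) -> list[np.ndarray]:
        """Absolute atom indices of a named ring for every molecule of a species."""
        spec = self.species.get(species)
        if spec is None:
            raise SelectionError(f"unknown species {species!r}")
        if ring not in spec.rings:
            raise SelectionError(f"species {species!r} has no ring {ring!r}")
        rel = np.asarray(spec.rings[ring], dtype=np.int64)
        return [mol.indices[rel] for mol in self.molecules_of(species)]

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        blocks = []
        counts: dict[str, int] = {}
        for mol in self.molecules:
            counts[mol.species] = counts.get(mol.species, 0) + 1
        for name, spec in self.species.items():
            atoms = []
            for a in spec.atoms:
                rec = {"element": a.element, "label": a.label, "mass": a.mass}
                if np.isfinite(a.charge):
                    rec["charge"] = a.charge
                if np.isfinite(a.sigma):
                    rec["sigma"] = a.sigma
                if np.isfinite(a.epsilon):
                    rec["epsilon"] = a.epsilon
                atoms.append(rec)
            block = {"name": name, "count": counts.get(name, 0), "atoms": atoms}
            if spec.rings:
                block["rings"] = {k: list(map(int, v)) for k, v in spec.rings.items()}
            blocks.append(block)
        with open(path, "w") as fh:
            yaml.safe_dump({"species": blocks}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Topology":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "species" not in doc:
            raise FormatError(f"{path}: topology file must contain a 'species' list")
        blocks = []
        for block in doc["species"]:
            try:
                atoms = tuple(
                    AtomDef(
                        element=str(a["element"]),
                        label=str(a["label"]),
                        mass=float(a["mass"]),
                        charge=float(a.get("charge", float("nan"))),
                        sigma=float(a.get("sigma", float("nan"))),
                        epsilon=float(a.get("epsilon", float("nan"))),
                    )
                    for a in block["atoms"]
                )
                rings = {str(k): list(map(int, v)) for k, v in block.get("rings", {}).items()}
                spec = SpeciesDef(name=str(block["name"]), atoms=atoms, rings=rings)
                blocks.append((spec, int(block.get("count", 1))))
            except KeyError as exc:
                raise FormatError(f"{path}: species block missing key {exc}") from exc
        return cls(blocks)


# ---------------------------------------------------------------------------
# Trajectory readers
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _parse_xyz_comment_box(comment: str, unit_factor: float):
    """Box edges (pm) from an extended-XYZ comment line, or None."""
    m = _LATTICE_RE.search(comment)
    if m:
        vals = [float(x) for x in m.group(1).split()]
        if len(vals) != 9:
            raise FormatError(f"Lattice entry must have 9 numbers, got {len(vals)}")
        mat = np.array(vals).reshape(3, 3)
        off = mat - np.diag(np.diag(mat))
        if np.any(off != 0):
            raise ConfigError("triclinic cells are not supported (non-zero Lattice off-diagonals)")
        return np.diag(mat) * unit_factor
    parts = comment.split()
    if len(parts) == 3:
        try:
            return np.array([float(p) for p in parts]) * unit_factor
        except ValueError:
            return None
    return None


def _read_xyz(path, timestep: float, box, length_unit: str) -> Trajectory:
    factor = {"angstrom": PM_PER_ANGSTROM, "pm": 1.0}.get(length_unit)
    if factor is None:
        raise ConfigError(f"unknown length unit {length_unit!r}")
    frames, boxes = [], []
    n_atoms = None
    with open(path) as fh:
        frame_no = 0
        while True:
            offset = fh.tell()
            header = fh.readline()
            if not header.strip():
                if header == "" or not fh.readline():
                    break
                continue
            try:
                count = int(header.split()[0])
            except ValueError:
                raise FormatError(
                    f"{path}: frame {frame_no}: expected atom count, got {header.strip()!r}")
            comment = fh.readline()
            if comment == "":
                raise FormatError(f"{path}: truncated frame {frame_no} at byte offset {offset}")
            frame_box = _parse_xyz_comment_box(comment, factor)
            coords = np.empty((count, 3), dtype=float)
            for i in range(count):
                line_off = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) < 4:
                    raise FormatError(
                        f"{path}: truncated frame {frame_no} at byte offset {line_off}")
                try:
                    coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                except ValueError:
                    raise FormatError(
                        f"{path}: frame {frame_no}: bad coordinate line {line.strip()!r}")
            if n_atoms is None:
                n_atoms = count
            elif count != n_atoms:
                raise FormatError(
                    f"{path}: atom count mismatch at frame {frame_no}: "
                    f"expected {n_atoms}, found {count}")
            frames.append(coords * factor)
            if frame_box is not None:
                boxes.append(np.asarray(frame_box, dtype=float))
            elif box is not None:
                boxes.append(np.asarray(box, dtype=float))
            else:
                raise ConfigError(
                    f"{path}: frame {frame_no}: no box in comment line and none supplied")
            frame_no += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return Trajectory(np.stack(frames), np.stack(boxes), timestep=timestep, wrapped=True)


def _read_lammps_dump(path, timestep: float) -> Trajectory:
    frames, boxes = [], []
    n_atoms = None
    wrapped_flags = []
    with open(path) as fh:
        frame_no = 0
        while True:
            offset = fh.tell()
            line = fh.readline()
            if line == "":
                break
            if not line.startswith("ITEM: TIMESTEP"):
                if not line.strip():
                    continue
                raise FormatError(
                    f"{path}: frame {frame_no}: expected 'ITEM: TIMESTEP' at byte offset {offset}")
            fh.readline()  # timestep value (frame spacing comes from the caller)
            item = fh.readline()
            if not item.startswith("ITEM: NUMBER OF ATOMS"):
                raise FormatError(f"{path}: frame {frame_no}: missing 'ITEM: NUMBER OF ATOMS'")
            try:
                count = int(fh.readline().split()[0])
            except (ValueError, IndexError):
                raise FormatError(f"{path}: frame {frame_no}: bad atom count")
            item = fh.readline()
            if not item.startswith("ITEM: BOX BOUNDS"):
                raise ConfigError(f"{path}: frame {frame_no}: missing 'ITEM: BOX BOUNDS'")
            if "xy" in item:
                raise ConfigError(f"{path}: frame {frame_no}: triclinic cells are not supported")
            edges = []
            for _ in range(3):
                parts = fh.readline().split()
                if len(parts) < 2:
                    raise FormatError(f"{path}: frame {frame_no}: bad BOX BOUNDS line")
                lo, hi = float(parts[0]), float(parts[1])
                edges.append((hi - lo) * PM_PER_ANGSTROM)
            item = fh.readline()
            if not item.startswith("ITEM: ATOMS"):
                raise FormatError(f"{path}: frame {frame_no}: missing 'ITEM: ATOMS'")
            columns = item.split()[2:]
            col = {name: i for i, name in enumerate(columns)}
            if "id" not in col:
                raise FormatError(f"{path}: frame {frame_no}: ATOMS section lacks an 'id' column")
            if all(c in col for c in ("x", "y", "z")):
                xyz_cols, wrapped = ("x", "y", "z"), True
            elif all(c in col for c in ("xu", "yu", "zu")):
                xyz_cols, wrapped = ("xu", "yu", "zu"), False
            else:
                raise FormatError(
                    f"{path}: frame {frame_no}: need x/y/z or xu/yu/zu columns, got {columns}")
            coords = np.empty((count, 3), dtype=float)
            seen = np.zeros(count, dtype=bool)
            for _ in range(count):
                line_off = fh.tell()
                parts = fh.readline().split()
                if len(parts) < len(columns):
                    raise FormatError(
                        f"{path}: truncated frame {frame_no} at byte offset {line_off}")
                atom_id = int(parts[col["id"]]) - 1
                if atom_id < 0 or atom_id >= count:
                    raise FormatError(
                        f"{path}: frame {frame_no}: atom id {atom_id + 1} out of range 1..{count}")
                coords[atom_id] = [float(parts[col[c]]) for c in xyz_cols]
                seen[atom_id] = True
            if not seen.all():
                raise FormatError(f"{path}: frame {frame_no}: duplicate or missing atom ids")
            if n_atoms is None:
                n_atoms = count
            elif count != n_atoms:
                raise FormatError(
                    f"{path}: atom count mismatch at frame {frame_no}: "
                    f"expected {n_atoms}, found {count}")
            frames.append(coords * PM_PER_ANGSTROM)
            boxes.append(np.array(edges))
            wrapped_flags.append(wrapped)
            frame_no += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    if len(set(wrapped_flags)) != 1:
        raise FormatError(f"{path}: mixed wrapped/unwrapped coordinate columns across frames")
    return Trajectory(np.stack(frames), np.stack(boxes), timestep=timestep,
                      wrapped=wrapped_flags[0])


def read_trajectory(path, format: str, timestep: float, box=None,
                    length_unit: str = "angstrom") -> Trajectory:
    """Read a multi-frame trajectory, converting lengths to pm.

    Parameters
    ----------
    format : ``"xyz"`` or ``"lammps-dump"``
    timestep : frame spacing in ps
    box : optional (3,) edge lengths in pm for XYZ files without an
        extended-XYZ ``Lattice`` comment
    length_unit : unit of XYZ coordinates (``"angstrom"`` default, or ``"pm"``)
    """
    if format == "xyz":
        return _read_xyz(path, timestep, box, length_unit)
    if format == "lammps-dump":
        return _read_lammps_dump(path, timestep)
    raise ConfigError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Unwrapping / folding
# ---------------------------------------------------------------------------

def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps so coordinates are continuous across boundaries.

    Tracks integer image counts so that :func:`fold` can reverse the
    operation exactly. Requires a constant box and per-frame displacements
    below half a box edge for every atom.
    """
    if not traj.wrapped:
        raise ConfigError("trajectory is already unwrapped")
    box = traj.constant_box()
    L = box.lengths
    coords = traj.coords
    delta = np.diff(coords, axis=0)
    # number of boundary crossings between consecutive frames, per component
    shifts = np.floor(delta / L + 0.5).astype(np.int64)
    mi = delta - shifts * L
    bad = np.abs(mi) >= 0.5 * L
    if np.any(bad):
        f, a, _ = np.argwhere(bad)[0]
        raise UnwrapError(
            f"displacement of atom {a} between frames {f} and {f + 1} is at least half a "
            f"box edge; periodic image is ambiguous")
    images = np.zeros_like(coords, dtype=np.int64)
    np.cumsum(-shifts, axis=0, out=images[1:])
    return Trajectory(coords + images * L, traj.box.copy(), timestep=traj.timestep,
                      wrapped=False, images=images)


def fold(traj: Trajectory) -> Trajectory:
    """Fold coordinates back into the box. Exact inverse of :func:`unwrap`
    when image counts are present."""
    if traj.wrapped:
        return replace(traj, coords=traj.coords.copy(), box=traj.box.copy())
    if traj.images is not None:
        box = traj.constant_box()
        coords = traj.coords - traj.images * box.lengths
    else:
        coords = np.empty_like(traj.coords)
        for f in range(traj.n_frames):
            coords[f] = Box(traj.box[f]).wrap(traj.coords[f])
    return Trajectory(coords, traj.box.copy(), timestep=traj.timestep, wrapped=True)


# ---------------------------------------------------------------------------
# Centers of mass
# ---------------------------------------------------------------------------

def make_whole(coords: np.ndarray, indices: np.ndarray, box: Box) -> np.ndarray:
    """Positions of the selected atoms reconstructed by minimum image
    against the first selected atom (for molecules split across the boundary)."""
    pos = np.asarray(coords, dtype=float)[indices]
    anchor = pos[0]
    return anchor + box.minimum_image(pos - anchor)


def center_of_mass(coords: np.ndarray, indices, topology: Topology,
                   box: Box | None = None) -> np.ndarray:
    """Mass-weighted mean position of a set of atoms in one frame.

    With ``box`` given (wrapped input) the atom set is first made whole by
    minimum-image reconstruction against its first atom and the result is
    folded into [0, L). Without a box, a plain weighted mean (unwrapped
    whole molecules).
    """
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size == 0:
        raise SelectionError("center_of_mass: empty atom set")
    masses = topology.mass[indices]
    total = masses.sum()
    if total <= 0:
        raise ConfigError("center_of_mass: zero total mass")
    if box is not None:
        pos = make_whole(coords, indices, box)
        com = (masses[:, None] * pos).sum(axis=0) / total
        return box.wrap(com)
    pos = np.asarray(coords, dtype=float)[indices]
    return (masses[:, None] * pos).sum(axis=0) / total


def com_trajectory(traj: Trajectory, topo: Topology, species: str) -> np.ndarray:
    """(n_frames, n_molecules, 3) center-of-mass positions for a species.

    Wrapped trajectories use per-frame minimum-image reconstruction;
    unwrapped ones a plain weighted mean.
    """
    mols = topo.molecules_of(species)
    out = np.empty((traj.n_frames, len(mols), 3), dtype=float)
    for f in range(traj.n_frames):
        box = traj.box_at(f) if traj.wrapped else None
        frame = traj.coords[f]
        for m, mol in enumerate(mols):
            out[f, m] = center_of_mass(frame, mol.indices, topo, box=box)
    return out
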