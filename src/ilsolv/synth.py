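"""Synthetic fixtures with known ground truth.

Every generator here is a pure function of its seed: identical arguments
produce bit-identical output. The fixtures are sized so each downstream
analysis stage (RDF normalization, lifetime autocorrelation, diffusion
fitting, enthalpy estimation, solubility regression) can be validated
against an analytic or enumerable truth without any MD input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .core import AtomDef, Box, SpeciesDef, Topology, Trajectory
from .errors import ConfigError


@dataclass(frozen=True)
class GeneratorSpec:
    """Bag of generator parameters, mainly for the ``synth`` CLI subcommand."""

    seed: int = 0
    n_particles: int = 100
    n_pairs: int = 50
    frames: int = 100
    timestep: float = 1.0           # ps
    box: float = 4000.0             # pm, cubic edge
    d_true: float = 100.0           # pm^2/ps
    k_form: float = 0.001           # 1/ps
    k_break: float = 0.01           # 1/ps
    means: tuple = (-1000.0, -400.0, 100.0)   # kJ/mol: solution, pure IL, vacuum
    sds: tuple = (10.0, 10.0, 10.0)
    c1: float = -110.0              # kJ/mol/unit
    c2: float = -9.0                # kJ/mol/unit per ln-unit
    noise_sd: float = 0.0
    n_points: int = 8


def _point_topology(n: int, label: str, species: str, mass: float = 1.0) -> Topology:
    spec = SpeciesDef(name=species, atoms=(AtomDef("X", label, mass),))
    return Topology([(spec, n)])


def gen_ideal_gas(n_particles: int, frames: int, box: float, timestep: float = 1.0,
                  seed: int = 0) -> tuple[Trajectory, Topology]:
    """Uncorrelated uniform positions each frame: g(r) = 1 for all r."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(frames, n_particles, 3))
    traj = Trajectory(coords, np.array([box] * 3), timestep=timestep, wrapped=True)
    return traj, _point_topology(n_particles, "gas", "gas")


def gen_brownian(n_particles: int, frames: int, box: float, d_true: float,
                 timestep: float = 1.0, seed: int = 0) -> tuple[Trajectory, Topology]:
    """Unwrapped random walk: i.i.d. Gaussian steps with per-dimension
    variance 2 * d_true * dt, so MSD(tau) = 6 * d_true * tau."""
    if d_true < 0:
        raise ConfigError("d_true must be >= 0")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, box, size=(n_particles, 3))
    if d_true == 0:
        coords = np.broadcast_to(start, (frames, n_particles, 3)).copy()
    else:
        sigma = np.sqrt(2.0 * d_true * timestep)
        steps = rng.normal(0.0, sigma, size=(frames - 1, n_particles, 3))
        coords = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    traj = Trajectory(coords, np.array([box] * 3), timestep=timestep, wrapped=False)
    return traj, _point_topology(n_particles, "bead", "bead")


def telegraph_states(n_pairs: int, frames: int, timestep: float, k_form: float,
                     k_break: float, seed: int = 0,
                     start_bound: bool | None = None) -> np.ndarray:
    """Two-state Markov chains (bound=True) with exact exponential-clock
    per-step transition probabilities 1 - exp(-k dt)."""
    if k_form < 0 or k_break < 0:
        raise ConfigError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    p_bind = -np.expm1(-k_form * timestep)
    p_break = -np.expm1(-k_break * timestep)
    states = np.empty((n_pairs, frames), dtype=bool)
    if start_bound is None:
        total = k_form + k_break
        p0 = k_form / total if total > 0 else 0.5
        states[:, 0] = rng.random(n_pairs) < p0
    else:
        states[:, 0] = start_bound
    u = rng.random((n_pairs, frames - 1))
    for t in range(1, frames):
        prev = states[:, t - 1]
        flip = np.where(prev, u[:, t - 1] < p_break, u[:, t - 1] < p_bind)
        states[:, t] = prev ^ flip
    return states


def gen_telegraph_bonds(n_pairs: int, frames: int, timestep: float, k_form: float,
                        k_break: float, seed: int = 0,
                        bound_dist: float = 250.0, unbound_dist: float = 500.0,
                        start_bound: bool | None = None,
                        ) -> tuple[Trajectory, Topology, np.ndarray]:
    """Donor/acceptor pairs whose O...H distance follows hidden two-state
    Markov chains: 250 pm when bound, 500 pm when unbound, straddling the
    300 pm detection cutoff with margin.

    Pairs sit on a cubic grid with 2000 pm spacing so no cross-pair contact
    is ever within cutoff. Returns (trajectory, topology, hidden states);
    the topology lists all donors first (species ``don``, label ``H(Ring)``),
    then all acceptors (species ``acc``, label ``O(Car)``), pair *i* being
    (donor *i*, acceptor *i*).
    """
    states = telegraph_states(n_pairs, frames, timestep, k_form, k_break,
                              seed=seed, start_bound=start_bound)
    spacing = 2000.0
    per_edge = int(np.ceil(n_pairs ** (1.0 / 3.0)))
    box = max(per_edge * spacing, 2.0 * unbound_dist + spacing)
    grid = np.array([
        ((i % per_edge) + 0.5,
         ((i // per_edge) % per_edge) + 0.5,
         (i // per_edge ** 2) + 0.5)
        for i in range(n_pairs)
    ]) * spacing
    dist = np.where(states, bound_dist, unbound_dist)            # (pairs, frames)
    coords = np.empty((frames, 2 * n_pairs, 3), dtype=float)
    coords[:, n_pairs:, :] = grid[None, :, :]                    # acceptors fixed
    coords[:, :n_pairs, :] = grid[None, :, :]
    coords[:, :n_pairs, 0] += dist.T                             # donors offset in x
    traj = Trajectory(coords, np.array([box] * 3), timestep=timestep, wrapped=True)
    donor = SpeciesDef(name="don", atoms=(AtomDef("H", "H(Ring)", 1.008),))
    acceptor = SpeciesDef(name="acc", atoms=(AtomDef("O", "O(Car)", 15.999),))
    topo = Topology([(donor, n_pairs), (acceptor, n_pairs)])
    return traj, topo, states


def _hexagon(radius: float) -> np.ndarray:
    ang = np.arange(6) * np.pi / 3.0
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def gen_stacked_pair(frames: int, seed: int = 0, offset: float = 350.0,
                     jitter: float = 30.0, box: float = 4000.0,
                     ring_radius: float = 140.0) -> tuple[Trajectory, Topology]:
    """A rigid reference ring at the box center plus a parallel partner ring
    whose centroid sits at (0, 0, +-offset) relative to the reference plane,
    with Gaussian jitter; the sign alternates randomly per frame.

    An SDF of the partner ring centroid in the reference ring's local frame
    shows exactly two maxima, at z = +offset and z = -offset.
    """
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2.0)
    ring = _hexagon(ring_radius)
    signs = np.where(rng.random(frames) < 0.5, -1.0, 1.0)
    noise = rng.normal(0.0, jitter, size=(frames, 3))
    coords = np.empty((frames, 12, 3), dtype=float)
    coords[:, :6, :] = center + ring
    partner_centroid = center + noise
    partner_centroid[:, 2] += signs * offset
    coords[:, 6:, :] = partner_centroid[:, None, :] + ring[None, :, :]
    traj = Trajectory(coords, np.array([box] * 3), timestep=1.0, wrapped=True)
    ring_atoms = tuple(AtomDef("C", "C(Ring)", 12.011) for _ in range(6))
    ref = SpeciesDef(name="ringA", atoms=ring_atoms, rings={"ring": [0, 1, 2, 3, 4, 5]})
    partner = SpeciesDef(
        name="ringB",
        atoms=tuple(AtomDef("C", "C(Partner)", 12.011) for _ in range(6)),
        rings={"ring": [0, 1, 2, 3, 4, 5]},
    )
    topo = Topology([(ref, 1), (partner, 1)])
    return traj, topo


def gen_energy_traces(frames: int, means, sds, seed: int = 0):
    """Three i.i.d. Gaussian potential-energy series (kJ/mol):
    solution, pure IL, solute strand in vacuum."""
    from .energetics import EnergyTrace
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != (3,) or sds.shape != (3,):
        raise ConfigError("means and sds must each have three entries")
    if np.any(sds < 0):
        raise ConfigError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    labels = ("solution", "pure IL", "vacuum strand")
    traces = []
    for mu, sd, label in zip(means, sds, labels):
        values = np.full(frames, mu) if sd == 0 else rng.normal(mu, sd, size=frames)
        traces.append(EnergyTrace(values=values, label=label))
    return tuple(traces)


def gen_solubility_points(n_points: int, c1: float, c2: float, noise_sd: float = 0.0,
                          seed: int = 0, s_range=(1.0, 20.0)) -> list[tuple[float, float]]:
    """(solubility wt.-%, dH kJ/mol/unit) pairs obeying
    dH = c2 * ln(S) + c1 + Gaussian noise."""
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if s_range[0] <= 0:
        raise ConfigError("solubilities must be > 0")
    rng = np.random.default_rng(seed)
    log_s = rng.uniform(np.log(s_range[0]), np.log(s_range[1]), size=n_points)
    s = np.exp(log_s)
    dh = c2 * log_s + c1
    if noise_sd > 0:
        dh = dh + rng.normal(0.0, noise_sd, size=n_points)
    return list(zip(s.tolist(), dh.tolist()))


# ---------------------------------------------------------------------------
# Fixture writers (plain-text formats readable by the core module)
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, topo: Topology, path) -> None:
    """Multi-frame extended XYZ in Angstrom with a Lattice comment line."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            lx, ly, lz = traj.box[f] / 100.0
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f'Lattice="{lx:.10g} 0 0 0 {ly:.10g} 0 0 0 {lz:.10g}"\n')
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i] / 100.0
                fh.write(f"{topo.element[i]} {x:.10f} {y:.10f} {z:.10f}\n")


def write_lammps_dump(traj: Trajectory, topo: Topology, path) -> None:
    """LAMMPS text dump (Angstrom); wrapped flag chooses x/y/z vs xu/yu/zu."""
    cols = "x y z" if traj.wrapped else "xu yu zu"
    types = {lab: i + 1 for i, lab in enumerate(sorted(set(topo.site_label)))}
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{f}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{traj.n_atoms}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write(f"0.0 {traj.box[f, d] / 100.0:.10g}\n")
            fh.write(f"ITEM: ATOMS id type {cols}\n")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i] / 100.0
                fh.write(f"{i + 1} {types[topo.site_label[i]]} {x:.10f} {y:.10f} {z:.10f}\n")


def write_truth(path, **truth) -> None:
    """JSON sidecar recording generator parameters and ground-truth values."""
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating, np.bool_)):
            return obj.item()
        if isinstance(obj, GeneratorSpec):
            return asdict(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=default)
        fh.write("\n")
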