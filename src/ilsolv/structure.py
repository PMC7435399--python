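"""Radial and spatial distribution functions in local molecular frames.

RDFs are normalized to uniform density: g(r) is the ratio of the observed
pair density in a spherical shell to the expectation for ideally mixed
(uniform) observed atoms, so g = 1 means no structure and peaks at
200-300 pm signal hydrogen bonding. SDFs are 3-D number densities (nm^-3)
of an observed site in a coordinate frame rigidly attached to a reference
molecule, averaged over all reference molecules and frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Box, Topology, Trajectory, make_whole
from .errors import ConfigError, DegenerateFrameError, SelectionError

_PM3_PER_NM3 = 1.0e9


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray          # bin centers, pm
    g: np.ndarray          # dimensionless density ratio
    counts: np.ndarray     # raw pair counts, frame-summed
    r_max: float
    bin_width: float
    n_frames: int
    n_ref: int
    n_obs: int

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("r_pm,g\n")
            for r, g in zip(self.r, self.g):
                fh.write(f"{r:.6f},{g:.8f}\n")


def _pair_histogram(ref: np.ndarray, obs: np.ndarray, box: Box,
                    edges: np.ndarray) -> np.ndarray:
    """Counts of directed (ref, obs) minimum-image distances per bin
    [e_i, e_{i+1}). Coincident pairs (d = 0, i.e. self pairs) are never
    counted. Uses periodic KD-trees; coordinates must lie in [0, L)."""
    tree_ref = cKDTree(ref, boxsize=box.lengths)
    tree_obs = cKDTree(obs, boxsize=box.lengths)
    # count_neighbors counts d <= r; shift edges down one ulp so each bin is
    # half-open [e_i, e_{i+1}), matching np.histogram. The first query radius
    # underflows to 0 when squared internally, so d = 0 pairs land in cum[0]
    # and drop out of the diff: exactly the self-pair exclusion we need.
    query = np.nextafter(edges, -np.inf)
    cum = tree_ref.count_neighbors(tree_obs, query)
    return np.diff(cum).astype(np.int64)


def compute_rdf(traj: Trajectory, topo: Topology, ref_sel, obs_sel,
                r_max: float, n_bins: int,
                exclude_intramolecular: bool = True) -> RDFResult:
    """Site-to-site radial distribution function.

    g(r) = <pair count in shell> / (shell volume * N_obs/V * N_ref), averaged
    over frames. Self pairs are always excluded; pairs within one molecule
    are excluded iff ``exclude_intramolecular``. Distances use the minimum
    image convention and bins are half-open [r, r + dr).
    """
    ref_idx = topo.select(ref_sel)
    obs_idx = topo.select(obs_sel)
    if ref_idx.size == 0:
        raise SelectionError(f"empty reference selection {ref_sel!r}")
    if obs_idx.size == 0:
        raise SelectionError(f"empty observed selection {obs_sel!r}")
    half_min_edge = float(traj.box.min()) / 2.0
    if r_max > half_min_edge:
        raise ConfigError(
            f"r_max={r_max} pm exceeds half the smallest box edge ({half_min_edge} pm)")
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    # molecules contributing excluded (same-molecule or self) pairs
    mol_ids = topo.molecule_id
    shared_mols = np.intersect1d(np.unique(mol_ids[ref_idx]), np.unique(mol_ids[obs_idx]))
    density_sum = 0.0
    for f in range(traj.n_frames):
        box = traj.box_at(f)
        frame = box.wrap(traj.coords[f])
        counts += _pair_histogram(frame[ref_idx], frame[obs_idx], box, edges)
        if exclude_intramolecular:
            counts -= _intramolecular_histogram(frame, box, edges, ref_idx, obs_idx,
                                                mol_ids, shared_mols)
        density_sum += obs_idx.size / box.volume_pm3
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = shell_vol * density_sum * ref_idx.size
    g = np.where(norm > 0, counts / np.where(norm > 0, norm, 1.0), 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centers, g=g, counts=counts, r_max=r_max,
                     bin_width=float(edges[1] - edges[0]), n_frames=traj.n_frames,
                     n_ref=ref_idx.size, n_obs=obs_idx.size)


def _intramolecular_histogram(frame, box, edges, ref_idx, obs_idx, mol_ids,
                              shared_mols):
    """Histogram of same-molecule cross pairs (self pairs at d = 0 excluded,
    matching :func:`_pair_histogram` which never counts them)."""
    out = np.zeros(edges.size - 1, dtype=np.int64)
    for mol in shared_mols:
        r_in = ref_idx[mol_ids[ref_idx] == mol]
        o_in = obs_idx[mol_ids[obs_idx] == mol]
        if r_in.size == 0 or o_in.size == 0:
            continue
        delta = box.minimum_image(frame[o_in][None, :, :] - frame[r_in][:, None, :])
        d = np.linalg.norm(delta, axis=-1).ravel()
        hist, _ = np.histogram(d[d > 0], bins=edges)
        out += hist
    return out


# ---------------------------------------------------------------------------
# Local frames
# ---------------------------------------------------------------------------

@dataclass
class LocalFrame:
    """Right-handed orthonormal frame anchored on a molecule."""

    origin: np.ndarray    # pm
    axes: np.ndarray      # rows are ex, ey, ez

    def to_local(self, positions: np.ndarray, box: Box | None = None) -> np.ndarray:
        rel = np.asarray(positions, dtype=float) - self.origin
        if box is not None:
            rel = box.minimum_image(rel)
        return rel @ self.axes.T


@dataclass(frozen=True)
class FrameSpec:
    """Anchor atoms (indices relative to the molecule start) defining a
    local frame on every molecule of a species: origin at the centroid of
    ``origin``, x toward the centroid of ``x``, z normal to the plane of the
    three centroids."""

    species: str
    origin: tuple
    x: tuple
    plane: tuple


def build_local_frame(coords: np.ndarray, origin_idx, x_idx, plane_idx,
                      box: Box | None = None) -> LocalFrame:
    """Gram-Schmidt frame from three anchor centroids.

    Raises :class:`DegenerateFrameError` when the centroids are collinear
    or coincident.
    """
    coords = np.asarray(coords, dtype=float)

    def centroid(idx):
        idx = np.asarray(idx, dtype=np.int64)
        if box is not None:
            return make_whole(coords, idx, box).mean(axis=0)
        return coords[idx].mean(axis=0)

    o = centroid(origin_idx)
    cx = centroid(x_idx)
    cp = centroid(plane_idx)
    vx = cx - o
    vp = cp - o
    if box is not None:
        vx = box.minimum_image(vx)
        vp = box.minimum_image(vp)
    nx = np.linalg.norm(vx)
    if nx < 1e-9:
        raise DegenerateFrameError("origin and x anchors coincide")
    ex = vx / nx
    ez = np.cross(ex, vp)
    nz = np.linalg.norm(ez)
    if nz < 1e-9:
        raise DegenerateFrameError("frame anchors are collinear")
    ez = ez / nz
    ey = np.cross(ez, ex)
    return LocalFrame(origin=o, axes=np.stack([ex, ey, ez]))


# ---------------------------------------------------------------------------
# Ring centroids
# ---------------------------------------------------------------------------

def ring_centroid(coords: np.ndarray, ring_indices, box: Box | None = None) -> np.ndarray:
    """Unweighted mean of ring-atom positions, made whole by minimum image
    against the first ring atom when a box is given."""
    idx = np.asarray(ring_indices, dtype=np.int64)
    if idx.size == 0:
        raise SelectionError("ring_centroid: empty ring atom list")
    if idx.size < 3:
        raise ConfigError("ring_centroid: a ring needs at least 3 atoms")
    if box is not None:
        return make_whole(coords, idx, box).mean(axis=0)
    return np.asarray(coords, dtype=float)[idx].mean(axis=0)


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

@dataclass
class SDFGrid:
    """Cubic voxel grid of number density (nm^-3) in a molecular local frame.

    The grid spans [-extent, +extent) per axis. ``density.sum() * voxel
    volume`` equals the average number of observed sites inside the grid per
    reference molecule per frame.
    """

    extent: float          # pm
    voxel: float           # pm
    density: np.ndarray    # (n, n, n), nm^-3
    counts: np.ndarray     # raw voxel counts
    n_references: int      # molecules x frames averaged

    @property
    def voxel_volume_nm3(self) -> float:
        return self.voxel ** 3 / _PM3_PER_NM3

    @property
    def integral(self) -> float:
        """Average observed count inside the grid per reference per frame."""
        return float(self.density.sum() * self.voxel_volume_nm3)

    def axis_centers(self) -> np.ndarray:
        n = self.density.shape[0]
        return -self.extent + (np.arange(n) + 0.5) * self.voxel

    def maxima_positions(self, n_max: int = 2) -> np.ndarray:
        """Centers of the ``n_max`` highest-density voxels (pm, local frame)."""
        flat = np.argsort(self.density.ravel())[::-1][:n_max]
        ijk = np.column_stack(np.unravel_index(flat, self.density.shape))
        return -self.extent + (ijk + 0.5) * self.voxel


def compute_sdf(traj: Trajectory, topo: Topology, ref_spec: FrameSpec,
                obs_sel=None, obs_ring: tuple | None = None,
                extent: float = 800.0, voxel: float = 50.0,
                exclude_self_molecule: bool = True) -> SDFGrid:
    """Bin observed sites (atoms by label, or ring centroids of a species)
    into each reference molecule's local frame.

    Density is counts / (voxel volume * references * frames) in nm^-3.
    """
    if (obs_sel is None) == (obs_ring is None):
        raise ConfigError("exactly one of obs_sel / obs_ring must be given")
    half_min_edge = float(traj.box.min()) / 2.0
    if extent > half_min_edge:
        raise ConfigError(
            f"extent={extent} pm exceeds half the smallest box edge ({half_min_edge} pm)")
    n_side = 2.0 * extent / voxel
    if abs(n_side - round(n_side)) > 1e-9:
        raise ConfigError(f"voxel edge {voxel} pm does not divide the grid extent {extent} pm")
    n_side = int(round(n_side))
    ref_mols = topo.molecules_of(ref_spec.species)
    counts = np.zeros((n_side, n_side, n_side), dtype=np.int64)

    if obs_sel is not None:
        obs_idx = topo.select(obs_sel)
        obs_mol = topo.molecule_id[obs_idx]
    else:
        ring_species, ring_name = obs_ring
        ring_sets = topo.ring_indices(ring_species, ring_name)
        obs_mol = np.array([topo.molecule_id[r[0]] for r in ring_sets])

    n_ref_samples = 0
    for f in range(traj.n_frames):
        box = traj.box_at(f)
        frame = traj.coords[f]
        if obs_sel is not None:
            obs_pos = frame[obs_idx]
        else:
            obs_pos = np.stack([ring_centroid(frame, r, box) for r in ring_sets])
        for mol in ref_mols:
            base = mol.indices[0]
            frame_axes = build_local_frame(
                frame,
                mol.indices[np.asarray(ref_spec.origin, dtype=np.int64)],
                mol.indices[np.asarray(ref_spec.x, dtype=np.int64)],
                mol.indices[np.asarray(ref_spec.plane, dtype=np.int64)],
                box=box,
            )
            pos = obs_pos
            mids = obs_mol
            if exclude_self_molecule:
                keep = mids != topo.molecule_id[base]
                pos = pos[keep]
            local = frame_axes.to_local(pos, box=box)
            inside = np.all((local >= -extent) & (local < extent), axis=1)
            if np.any(inside):
                ijk = np.floor((local[inside] + extent) / voxel).astype(np.int64)
                np.clip(ijk, 0, n_side - 1, out=ijk)
                np.add.at(counts, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), 1)
            n_ref_samples += 1
    voxel_vol_nm3 = voxel ** 3 / _PM3_PER_NM3
    density = counts / (voxel_vol_nm3 * max(n_ref_samples, 1))
    return SDFGrid(extent=extent, voxel=voxel, density=density, counts=counts,
                   n_references=n_ref_samples)


# ---------------------------------------------------------------------------
# Cube export
# ---------------------------------------------------------------------------

_BOHR_PER_PM = 1.0 / 52.9177210903


def write_cube(grid: SDFGrid, path, sidecar_path=None, comment: str = "") -> None:
    """Gaussian cube file of the SDF density (values in nm^-3, axes in Bohr)
    plus an optional JSON sidecar with the frame definition."""
    n = grid.density.shape[0]
    step = grid.voxel * _BOHR_PER_PM
    org = -grid.extent * _BOHR_PER_PM
    with open(path, "w") as fh:
        fh.write("ilsolv spatial distribution function (density in nm^-3)\n")
        fh.write(f"{comment or 'local molecular frame'}\n")
        fh.write(f"{1:5d} {org:12.6f} {org:12.6f} {org:12.6f}\n")
        fh.write(f"{n:5d} {step:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{n:5d} {0.0:12.6f} {step:12.6f} {0.0:12.6f}\n")
        fh.write(f"{n:5d} {0.0:12.6f} {0.0:12.6f} {step:12.6f}\n")
        fh.write(f"{1:5d} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        vals = grid.density.ravel()
        for i in range(0, vals.size, 6):
            fh.write(" ".join(f"{v:13.5e}" for v in vals[i:i + 6]) + "\n")
    if sidecar_path is not None:
        meta = {
            "extent_pm": grid.extent,
            "voxel_pm": grid.voxel,
            "n_references": grid.n_references,
            "integral": grid.integral,
            "max_density_nm3": float(grid.density.max()),
            "isovalue_suggestions_nm3": [
                float(grid.density.max()) * frac for frac in (0.25, 0.5, 0.75)
            ],
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
            fh.write("\n")
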