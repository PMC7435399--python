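"""Hydrogen-bond detection, intermittent lifetimes and network topology.

A hydrogen bond exists between a donor-bound H site and an acceptor site
whenever their minimum-image distance is at most ``r_cut`` (closed ball,
default 300 pm). No angle criterion is applied. The pair indicator h(t)
stays associated with its (donor-H, acceptor) pair across breaks and
reformation, so the autocorrelation of h yields *intermittent* lifetimes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import Topology, Trajectory
from .errors import ConfigError, SelectionError

__all__ = [
    "HBondCriterion", "BondOccupancy", "LifetimeResult", "SankeyTable",
    "occupancy", "intermittent_lifetime", "sankey", "per_molecule_counts",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Distance-only geometric criterion: donor-H labels, acceptor labels,
    and the O...H cutoff in pm."""

    donors: tuple
    acceptors: tuple
    r_cut: float = 300.0

    def __post_init__(self):
        object.__setattr__(self, "donors",
                           (self.donors,) if isinstance(self.donors, str)
                           else tuple(self.donors))
        object.__setattr__(self, "acceptors",
                           (self.acceptors,) if isinstance(self.acceptors, str)
                           else tuple(self.acceptors))
        if not (self.r_cut > 0):
            raise ConfigError(f"r_cut must be > 0, got {self.r_cut}")


@dataclass
class BondOccupancy:
    """Boolean pair x frame matrix of hydrogen-bond existence.

    Only pairs bonded in at least one frame are stored; pairs never within
    the cutoff carry no information for any downstream analysis here.
    """

    pairs: np.ndarray            # (P, 2) donor-H atom index, acceptor atom index
    intramolecular: np.ndarray   # (P,) donor and acceptor share a molecule
    matrix: np.ndarray           # (P, F) bool
    timestep: float              # ps

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.matrix = np.asarray(self.matrix, dtype=bool)
        self.intramolecular = np.asarray(self.intramolecular, dtype=bool)
        if self.matrix.shape[0] != self.pairs.shape[0]:
            raise ConfigError("occupancy matrix rows must match the pair list")
        if self.intramolecular.shape[0] != self.pairs.shape[0]:
            raise ConfigError("intramolecular flags must match the pair list")

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    def export(self, manifest_path, matrix_path) -> None:
        """Pair manifest as CSV plus the boolean matrix as a packed-bit npz."""
        with open(manifest_path, "w") as fh:
            fh.write("pair,donor_atom,acceptor_atom,intramolecular\n")
            for p in range(self.n_pairs):
                fh.write(f"{p},{self.pairs[p, 0]},{self.pairs[p, 1]},"
                         f"{int(self.intramolecular[p])}\n")
        np.savez_compressed(matrix_path, bits=np.packbits(self.matrix, axis=1),
                            n_frames=self.n_frames, timestep=self.timestep)


def occupancy(traj: Trajectory, topo: Topology, criterion: HBondCriterion) -> BondOccupancy:
    """Detect hydrogen bonds in every frame.

    An entry is True iff the minimum-image donor-H...acceptor distance is
    <= r_cut at that frame (a distance of exactly r_cut counts as bonded).
    """
    donor_idx = topo.select(list(criterion.donors))
    acceptor_idx = topo.select(list(criterion.acceptors))
    if donor_idx.size == 0:
        raise SelectionError("empty donor selection")
    if acceptor_idx.size == 0:
        raise SelectionError("empty acceptor selection")
    half_min_edge = float(traj.box.min()) / 2.0
    if criterion.r_cut > half_min_edge:
        raise ConfigError(
            f"r_cut={criterion.r_cut} pm exceeds half the smallest box edge")
    bonded_frames: dict[tuple[int, int], list[int]] = {}
    for f in range(traj.n_frames):
        box = traj.box_at(f)
        frame = box.wrap(traj.coords[f])
        tree_d = cKDTree(frame[donor_idx], boxsize=box.lengths)
        tree_a = cKDTree(frame[acceptor_idx], boxsize=box.lengths)
        # closed ball: query_ball_tree includes points at exactly r
        hits = tree_d.query_ball_tree(tree_a, criterion.r_cut)
        for d_local, a_list in enumerate(hits):
            for a_local in a_list:
                bonded_frames.setdefault((d_local, a_local), []).append(f)
    pair_keys = sorted(bonded_frames)
    pairs = np.array([[donor_idx[d], acceptor_idx[a]] for d, a in pair_keys],
                     dtype=np.int64).reshape(-1, 2)
    matrix = np.zeros((len(pair_keys), traj.n_frames), dtype=bool)
    for p, key in enumerate(pair_keys):
        matrix[p, bonded_frames[key]] = True
    intra = (topo.molecule_id[pairs[:, 0]] == topo.molecule_id[pairs[:, 1]]
             if len(pair_keys) else np.zeros(0, dtype=bool))
    return BondOccupancy(pairs=pairs, intramolecular=intra, matrix=matrix,
                         timestep=traj.timestep)


# ---------------------------------------------------------------------------
# Intermittent lifetimes
# ---------------------------------------------------------------------------

@dataclass
class LifetimeResult:
    lags_ps: np.ndarray
    c: np.ndarray
    tau_ps: float | None
    unresolved: bool = False
    reason: str | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("lag_ps,c\n")
            for lag, c in zip(self.lags_ps, self.c):
                fh.write(f"{lag:.6f},{c:.8f}\n")

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"tau_ps": self.tau_ps, "unresolved": self.unresolved,
                       "reason": self.reason, "diagnostics": self.diagnostics},
                      fh, indent=2)
            fh.write("\n")


def _pooled_autocorrelation(h: np.ndarray, max_lag_frames: int) -> np.ndarray:
    """<h(0) h(t)> pooled over pairs and sliding time origins, via FFT."""
    n_pairs, n_frames = h.shape
    nfft = 1
    while nfft < 2 * n_frames:
        nfft *= 2
    spec = np.fft.rfft(h, n=nfft, axis=1)
    corr = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, :max_lag_frames + 1]
    totals = corr.sum(axis=0)
    origins = n_frames - np.arange(max_lag_frames + 1)
    return totals / (n_pairs * origins)


def intermittent_lifetime(occ: BondOccupancy, max_lag: float,
                          tail_fit: bool = True) -> LifetimeResult:
    """Occupancy autocorrelation C(t) and its integral lifetime.

    C(t) = (<h(0)h(t)> - <h>^2) / (<h> - <h>^2), averaged over all
    ever-bonded pairs and all time origins. tau is the trapezoid integral of
    C over resolved positive lags plus an exponential tail extension fitted
    on the last resolved decade.
    """
    if occ.n_pairs == 0 or not occ.matrix.any():
        raise ConfigError("no pair was ever bonded; cannot compute a lifetime")
    dt = occ.timestep
    max_lag_frames = int(round(max_lag / dt))
    if max_lag_frames < 1 or max_lag_frames > occ.n_frames - 1:
        raise ConfigError(
            f"max_lag={max_lag} ps must span 1..{occ.n_frames - 1} frames at dt={dt} ps")
    ever = occ.matrix.any(axis=1)
    h = occ.matrix[ever].astype(float)
    mean_h = h.mean()
    var = mean_h - mean_h ** 2
    lags = np.arange(max_lag_frames + 1) * dt
    if var <= 0:
        # occupancy constant at 1 for every ever-bonded pair: no decay
        return LifetimeResult(lags_ps=lags, c=np.ones_like(lags), tau_ps=None,
                              unresolved=True, reason="no decay: occupancy is constant",
                              diagnostics={"mean_occupancy": float(mean_h)})
    raw = _pooled_autocorrelation(h, max_lag_frames)
    c = (raw - mean_h ** 2) / var
    # resolved region: up to the first non-positive value of C
    nonpos = np.nonzero(c <= 0)[0]
    end = int(nonpos[0]) if nonpos.size else max_lag_frames
    if end < 1:
        return LifetimeResult(lags_ps=lags, c=c, tau_ps=None, unresolved=True,
                              reason="correlation lost within one frame spacing",
                              diagnostics={"mean_occupancy": float(mean_h)})
    tau = float(np.trapezoid(c[:end + 1], lags[:end + 1])) if end < max_lag_frames \
        else float(np.trapezoid(c, lags))
    diagnostics = {
        "mean_occupancy": float(mean_h),
        "n_pairs_averaged": int(h.shape[0]),
        "resolved_to_ps": float(lags[min(end, max_lag_frames)]),
        "plateau_subtracted": float(mean_h ** 2),
        "tail": None,
    }
    if tail_fit:
        t_end = lags[min(end, max_lag_frames)]
        lo = t_end / 10.0
        sel = (lags >= lo) & (lags <= t_end) & (c > 0)
        if sel.sum() >= 5:
            x = lags[sel]
            y = np.log(c[sel])
            slope, intercept = np.polyfit(x, y, 1)
            if slope < 0:
                tau_tail = -1.0 / slope
                amp = np.exp(intercept)
                tail_integral = amp * tau_tail * np.exp(-t_end / tau_tail)
                tau += tail_integral
                resid = y - (slope * x + intercept)
                ss_tot = float(np.sum((y - y.mean()) ** 2))
                r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
                diagnostics["tail"] = {
                    "window_ps": [float(lo), float(t_end)],
                    "tau_tail_ps": float(tau_tail),
                    "amplitude": float(amp),
                    "integral_ps": float(tail_integral),
                    "fit_r2": r2,
                }
    if c[min(end, max_lag_frames) - 1] > np.exp(-1):
        diagnostics["poorly_resolved"] = True
    return LifetimeResult(lags_ps=lags, c=c, tau_ps=tau, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Sankey network-topology accounting
# ---------------------------------------------------------------------------

@dataclass
class SankeyTable:
    """Donor-class x acceptor-class average hydrogen-bond flows.

    ``flows[i, j]`` is the time-averaged number of bonds between donor class
    i and acceptor class j divided by the number of donor atoms of class i
    (bonds per donor atom). Donor-side and acceptor-side totals balance
    exactly by construction.
    """

    donor_classes: list
    acceptor_classes: list
    flows: np.ndarray              # (D, A), bonds per donor atom
    donor_atoms: np.ndarray        # (D,)
    acceptor_atoms: np.ndarray     # (A,)
    donor_molecules: np.ndarray    # (D,) molecules contributing donor atoms
    acceptor_molecules: np.ndarray

    @property
    def donor_per_atom(self) -> np.ndarray:
        return self.flows.sum(axis=1)

    @property
    def acceptor_per_atom(self) -> np.ndarray:
        totals = self.flows * self.donor_atoms[:, None]
        return totals.sum(axis=0) / self.acceptor_atoms

    @property
    def total_bonds(self) -> float:
        """System-wide time-averaged bond count."""
        return float((self.flows * self.donor_atoms[:, None]).sum())

    def conservation_gap(self) -> float:
        donor_total = float((self.donor_per_atom * self.donor_atoms).sum())
        acceptor_total = float((self.acceptor_per_atom * self.acceptor_atoms).sum())
        return donor_total - acceptor_total

    def to_json(self, path) -> None:
        doc = {
            "donor_classes": [
                {"name": c, "atoms": int(self.donor_atoms[i]),
                 "molecules": int(self.donor_molecules[i]),
                 "per_atom": float(self.donor_per_atom[i])}
                for i, c in enumerate(self.donor_classes)
            ],
            "acceptor_classes": [
                {"name": c, "atoms": int(self.acceptor_atoms[j]),
                 "molecules": int(self.acceptor_molecules[j]),
                 "per_atom": float(self.acceptor_per_atom[j])}
                for j, c in enumerate(self.acceptor_classes)
            ],
            "flows_per_donor_atom": [
                {"donor": d, "acceptor": a, "value": float(self.flows[i, j])}
                for i, d in enumerate(self.donor_classes)
                for j, a in enumerate(self.acceptor_classes)
                if self.flows[i, j] != 0
            ],
            "total_bonds": self.total_bonds,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("donor_class," + ",".join(self.acceptor_classes) + "\n")
            for i, d in enumerate(self.donor_classes):
                fh.write(d + "," + ",".join(f"{v:.8f}" for v in self.flows[i]) + "\n")


def sankey(occ: BondOccupancy, topo: Topology, class_map: dict,
           intramolecular_policy: dict | None = None) -> SankeyTable:
    """Average hydrogen-bond flows between donor and acceptor classes.

    Parameters
    ----------
    class_map : site label -> class name; every label occurring among the
        occupancy pairs (and any label whose atoms should enter the per-atom
        denominators) must be mapped.
    intramolecular_policy : optional (donor class, acceptor class) ->
        ``"include"`` | ``"exclude"``. Under ``"exclude"`` the bonds flagged
        intramolecular for that class pair are omitted from all sums
        (intermolecular bonds between the same classes are kept). Default is
        include everywhere.
    """
    policy = {}
    for key, value in (intramolecular_policy or {}).items():
        if value not in ("include", "exclude"):
            raise ConfigError(f"policy for {key} must be 'include' or 'exclude'")
        policy[tuple(key)] = value

    labels = topo.site_label
    for p in range(occ.n_pairs):
        for atom in occ.pairs[p]:
            if labels[atom] not in class_map:
                raise ConfigError(f"site label {labels[atom]!r} is not mapped to a class")

    donor_label_set = sorted({labels[a] for a in occ.pairs[:, 0]})
    acceptor_label_set = sorted({labels[a] for a in occ.pairs[:, 1]})
    donor_classes = sorted({class_map[lab] for lab in donor_label_set})
    acceptor_classes = sorted({class_map[lab] for lab in acceptor_label_set})
    d_index = {c: i for i, c in enumerate(donor_classes)}
    a_index = {c: j for j, c in enumerate(acceptor_classes)}

    def class_atom_stats(label_set, classes):
        atoms = np.zeros(len(classes), dtype=np.int64)
        mols = np.zeros(len(classes), dtype=np.int64)
        cindex = {c: i for i, c in enumerate(classes)}
        for cls in classes:
            cls_labels = [lab for lab in class_map if class_map[lab] == cls
                          and lab in topo.labels()]
            idx = topo.select(cls_labels)
            atoms[cindex[cls]] = idx.size
            mols[cindex[cls]] = np.unique(topo.molecule_id[idx]).size
        return atoms, mols

    donor_atoms, donor_mols = class_atom_stats(donor_label_set, donor_classes)
    acceptor_atoms, acceptor_mols = class_atom_stats(acceptor_label_set, acceptor_classes)

    bond_sums = np.zeros((len(donor_classes), len(acceptor_classes)), dtype=float)
    per_pair_mean = occ.matrix.mean(axis=1)
    for p in range(occ.n_pairs):
        dc = class_map[labels[occ.pairs[p, 0]]]
        ac = class_map[labels[occ.pairs[p, 1]]]
        if occ.intramolecular[p] and policy.get((dc, ac)) == "exclude":
            continue
        bond_sums[d_index[dc], a_index[ac]] += per_pair_mean[p]
    flows = bond_sums / donor_atoms[:, None]
    return SankeyTable(donor_classes=donor_classes, acceptor_classes=acceptor_classes,
                       flows=flows, donor_atoms=donor_atoms, acceptor_atoms=acceptor_atoms,
                       donor_molecules=donor_mols, acceptor_molecules=acceptor_mols)


def per_molecule_counts(table: SankeyTable, topo: Topology | None = None) -> dict:
    """Per-molecule donated/accepted averages: per-atom value times the
    number of class atoms per molecule.

    E.g. a per-atom average of 0.83 with three such ring protons per cation
    gives 0.83 x 3 = 2.49 bonds donated per cation.
    """
    out = {"donated": {}, "accepted": {}}
    for i, cls in enumerate(table.donor_classes):
        per_mol_atoms = table.donor_atoms[i] / table.donor_molecules[i]
        out["donated"][cls] = float(table.donor_per_atom[i] * per_mol_atoms)
    for j, cls in enumerate(table.acceptor_classes):
        per_mol_atoms = table.acceptor_atoms[j] / table.acceptor_molecules[j]
        out["accepted"][cls] = float(table.acceptor_per_atom[j] * per_mol_atoms)
    return out
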