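"""Group-group nonbonded interaction energies and solvation-enthalpy estimation.

Pairwise energies use plain cutoff truncation for both Lennard-Jones and
Coulomb terms; no reciprocal-space electrostatics. The module's role is an
oracle-testable decomposition of interaction energies and the difference
estimator

    dH_solv = (  <E_pot(solution)> - <E_pot(pure solvent)>
               - <E_pot(solute strand in vacuum)> ) / n_units

with the three runs treated as statistically independent.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np

from .core import Box, Topology
from .errors import ConfigError, FormatError

# Coulomb constant e^2 / (4 pi eps0) in kJ * pm / mol
COULOMB_KJ_PM_PER_MOL = 138935.4585


@dataclass
class EnergyTrace:
    """Per-frame potential energy series in kJ/mol."""

    values: np.ndarray
    label: str = "custom"

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.size < 1:
            raise ConfigError(f"energy trace {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError(f"energy trace {self.label!r} contains non-finite values")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        """Standard error of the mean (0 for a single sample)."""
        if self.values.size < 2:
            return 0.0
        return float(self.values.std(ddof=1) / np.sqrt(self.values.size))


def read_energy_csv(path, label: str = "custom") -> EnergyTrace:
    """Single-column or (step, energy) numeric CSV/whitespace series."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            try:
                values.append(float(parts[-1]))
            except ValueError:
                if lineno == 1:     # header row
                    continue
                raise FormatError(f"{path}:{lineno}: not a numeric energy value: {line!r}")
    if not values:
        raise FormatError(f"{path}: no energy values found")
    return EnergyTrace(values=np.array(values), label=label)


def read_lammps_log(path, column: str = "PotEng", label: str = "custom") -> EnergyTrace:
    """Extract a thermo column (default ``PotEng``) from a LAMMPS log file."""
    values = []
    col_idx = None
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if column in parts:
                col_idx = parts.index(column)
                continue
            if col_idx is None or len(parts) <= col_idx:
                continue
            try:
                values.append(float(parts[col_idx]))
            except ValueError:
                col_idx = None      # left the thermo block
    if not values:
        raise FormatError(f"{path}: no {column!r} thermo column found")
    return EnergyTrace(values=np.array(values), label=label)


@dataclass(frozen=True)
class NonbondedParams:
    """Settings for pairwise nonbonded evaluation.

    ``charge_scale`` (default 0.8) is applied as scale^2 on every Coulomb
    pair term. ``coulomb`` selects the physical constant (kJ pm / mol e^2)
    or reduced units (k_C = 1). LJ cross parameters use geometric mixing by
    default (OPLS convention); ``mixing="lorentz-berthelot"`` switches to an
    arithmetic-mean sigma.
    """

    cutoff: float                   # pm
    charge_scale: float = 0.8
    coulomb: str = "physical"
    mixing: str = "geometric"

    def __post_init__(self):
        if not (self.cutoff > 0):
            raise ConfigError("cutoff must be > 0")
        if not (0 < self.charge_scale <= 1):
            raise ConfigError("charge scale must be in (0, 1]")
        if self.coulomb not in ("physical", "reduced"):
            raise ConfigError(f"unknown coulomb setting {self.coulomb!r}")
        if self.mixing not in ("geometric", "lorentz-berthelot"):
            raise ConfigError(f"unknown mixing rule {self.mixing!r}")

    @property
    def k_coulomb(self) -> float:
        return COULOMB_KJ_PM_PER_MOL if self.coulomb == "physical" else 1.0


def group_interaction_energy(coords: np.ndarray, topo: Topology, group_a, group_b,
                             params: NonbondedParams, box: Box) -> float:
    """Sum of LJ + Coulomb energies over cross pairs within the cutoff.

    Groups must be disjoint; intra-group pairs are never counted. Atoms with
    NaN charge raise an error naming them; NaN epsilon disables the LJ term
    for that atom's pairs.
    """
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ConfigError("both groups must be non-empty")
    overlap = np.intersect1d(a, b)
    if overlap.size:
        raise ConfigError(f"groups overlap on atoms {overlap.tolist()}")
    for name, grp in (("a", a), ("b", b)):
        bad = grp[~np.isfinite(topo.charge[grp])]
        if bad.size:
            raise ConfigError(
                f"group_{name}: missing partial charge for atoms {bad.tolist()}")
    coords = np.asarray(coords, dtype=float)
    delta = box.minimum_image(coords[b][None, :, :] - coords[a][:, None, :])
    r = np.linalg.norm(delta, axis=-1)
    mask = r <= params.cutoff
    if not np.any(mask):
        return 0.0
    r = r[mask]
    qq = (topo.charge[a][:, None] * topo.charge[b][None, :])[mask]
    e_coul = params.k_coulomb * params.charge_scale ** 2 * qq / r

    eps_a, eps_b = topo.epsilon[a], topo.epsilon[b]
    sig_a, sig_b = topo.sigma[a], topo.sigma[b]
    eps = np.sqrt(np.nan_to_num(eps_a[:, None] * eps_b[None, :], nan=0.0))[mask]
    if params.mixing == "geometric":
        sig = np.sqrt(np.nan_to_num(sig_a[:, None] * sig_b[None, :], nan=0.0))[mask]
    else:
        sig = np.nan_to_num(0.5 * (sig_a[:, None] + sig_b[None, :]), nan=0.0)[mask]
    has_lj = eps > 0
    e_lj = np.zeros_like(r)
    if np.any(has_lj):
        sr6 = (sig[has_lj] / r[has_lj]) ** 6
        e_lj[has_lj] = 4.0 * eps[has_lj] * (sr6 ** 2 - sr6)
    return float(e_coul.sum() + e_lj.sum())


@dataclass
class SolvationEnthalpy:
    """Per-unit solvation-enthalpy estimate with propagated standard error."""

    dh: float               # kJ/mol per solute unit
    se: float
    n_units: int
    mean_solution: float
    mean_solvent: float
    mean_vacuum: float

    def summary_json(self, path, extra: dict | None = None) -> None:
        doc = {"dh_kj_per_mol_unit": self.dh, "standard_error": self.se,
               "n_units": self.n_units,
               "components_kj_per_mol": {"solution": self.mean_solution,
                                         "pure_solvent": self.mean_solvent,
                                         "vacuum_strand": self.mean_vacuum}}
        if extra:
            doc.update(extra)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")


def solvation_enthalpy(e_sol: EnergyTrace, e_il: EnergyTrace, e_vac: EnergyTrace,
                       n_units: int) -> SolvationEnthalpy:
    """Per-unit difference of trace means with uncorrelated error propagation."""
    if n_units < 1:
        raise ConfigError("n_units must be >= 1")
    dh = (e_sol.mean - e_il.mean - e_vac.mean) / n_units
    se = float(np.sqrt(e_sol.sem ** 2 + e_il.sem ** 2 + e_vac.sem ** 2)) / n_units
    return SolvationEnthalpy(dh=float(dh), se=se, n_units=n_units,
                             mean_solution=e_sol.mean, mean_solvent=e_il.mean,
                             mean_vacuum=e_vac.mean)


def anion_dominates(cellulose_anion: float, cellulose_cation: float) -> bool:
    """Diagnostic: is the solute-anion interaction stronger in magnitude than
    the solute-cation one? Reported, never assumed."""
    return abs(cellulose_anion) > abs(cellulose_cation)
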