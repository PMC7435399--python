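"""Calibrated log-model mapping solvation enthalpy to solubility.

Dissolution is treated as an equilibrium with constant K, so
dG = -R T ln K and dG = dH - T dS; for structurally similar solvents the
entropy term is absorbed into a constant, leaving dH - c1 = c2 * ln S.
The model is calibrated by ordinary least squares of dH on ln S and
inverted for prediction, with a fixed factor-of-two accuracy band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError


@dataclass
class SolubilityModel:
    """dH = c2 * ln S + c1 with the correlation coefficient R of the fit.

    ``r`` is the magnitude of the Pearson correlation of (ln S, dH) — the
    slope is negative in the physical regime, and the coefficient is
    conventionally quoted as a positive number; ``r_signed`` keeps the sign.
    Solubilities are in wt.-% unless ``unit`` says otherwise; calibrations
    in different units must never be mixed in one fit.
    """

    c1: float                   # kJ/mol/unit, absorbs the -T*dS constant
    c2: float                   # kJ/mol/unit per ln-unit
    r: float
    r_signed: float = 0.0
    points: list = field(default_factory=list)   # (name, S, dH)
    unit: str = "wt%"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"c1": self.c1, "c2": self.c2, "r": self.r,
                       "r_signed": self.r_signed, "unit": self.unit,
                       "points": [list(p) for p in self.points],
                       "convention": "dH = c2 * ln(S) + c1; prediction inverts the line"},
                      fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SolubilityModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(c1=doc["c1"], c2=doc["c2"], r=doc["r"],
                   r_signed=doc.get("r_signed", doc["r"]),
                   points=[tuple(p) for p in doc.get("points", [])],
                   unit=doc.get("unit", "wt%"))


@dataclass(frozen=True)
class SolubilityPrediction:
    """Point estimate plus the fixed multiplicative factor-of-two band."""

    s: float
    band: tuple

    def __post_init__(self):
        if not (self.band[0] <= self.s <= self.band[1]):
            raise ConfigError("prediction band must contain the point estimate")


@dataclass(frozen=True)
class CarbeneEquilibrium:
    """Proton-transfer equilibrium from cation acid to anion base:
    log10 K = pKa(anion's conjugate acid) - pKa(cation)."""

    pka_cation: float
    pka_anion_acid: float

    @property
    def log10_k(self) -> float:
        return self.pka_anion_acid - self.pka_cation


def fit_model(points, unit: str = "wt%") -> SolubilityModel:
    """Ordinary least squares of dH on ln S over (S, dH) or (name, S, dH)
    calibration points."""
    named = []
    for p in points:
        if len(p) == 3:
            named.append((str(p[0]), float(p[1]), float(p[2])))
        else:
            named.append((f"point{len(named) + 1}", float(p[0]), float(p[1])))
    if len(named) < 3:
        raise ConfigError(f"need at least 3 calibration points, got {len(named)}")
    s = np.array([p[1] for p in named])
    dh = np.array([p[2] for p in named])
    if np.any(s <= 0):
        raise ConfigError("solubilities must be > 0 for the log model")
    x = np.log(s)
    if np.ptp(x) == 0:
        raise ConfigError("all solubilities identical: the log model is undetermined")
    c2, c1 = np.polyfit(x, dh, 1)
    r_signed = float(np.corrcoef(x, dh)[0, 1])
    return SolubilityModel(c1=float(c1), c2=float(c2), r=abs(r_signed),
                           r_signed=r_signed, points=named, unit=unit)


def predict(model: SolubilityModel, dh: float) -> SolubilityPrediction:
    """Invert the fitted line: S = exp((dH - c1) / c2), band [S/2, 2S]."""
    if model.c2 == 0:
        raise ConfigError("c2 = 0: the model carries no information about solubility")
    s = float(np.exp((dh - model.c1) / model.c2))
    return SolubilityPrediction(s=s, band=(s / 2.0, 2.0 * s))


def carbene_log_k(pka1: float, pka2: float) -> CarbeneEquilibrium:
    """Carbene-formation equilibrium from the cation acidity (pka1) and the
    acidity of the anion's conjugate acid (pka2)."""
    if not (np.isfinite(pka1) and np.isfinite(pka2)):
        raise ConfigError("pKa values must be finite")
    return CarbeneEquilibrium(pka_cation=float(pka1), pka_anion_acid=float(pka2))


def bootstrap_slope_ci(points, n_boot: int = 2000, seed: int = 0,
                       level: float = 0.95) -> tuple:
    """Percentile bootstrap confidence interval for c2 (an extension beyond
    the fixed factor-of-two band; labeled as such in outputs)."""
    pts = [(float(p[-2]), float(p[-1])) for p in points]
    if len(pts) < 3:
        raise ConfigError("need at least 3 points to bootstrap")
    rng = np.random.default_rng(seed)
    s = np.log(np.array([p[0] for p in pts]))
    dh = np.array([p[1] for p in pts])
    slopes = []
    n = len(pts)
    while len(slopes) < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.ptp(s[idx]) == 0:
            continue
        slopes.append(np.polyfit(s[idx], dh[idx], 1)[0])
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(slopes, lo)), float(np.quantile(slopes, 1.0 - lo)))


def read_calibration_csv(path) -> list:
    """Calibration table ``name,solubility_wtpct,dh_kj_per_mol_unit``."""
    points = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and any(not _is_float(p) for p in parts[1:]):
                continue    # header
            if len(parts) < 3:
                raise ConfigError(f"{path}:{lineno}: need name,solubility,dh columns")
            points.append((parts[0], float(parts[1]), float(parts[2])))
    return points


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
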