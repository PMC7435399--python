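"""Run-configuration validation and the end-to-end analysis pipeline.

A run config is a single structured (YAML) document; every analysis it
requests is validated against the topology before any computation starts,
and each output directory gets a provenance record (config hash, seed,
package version) so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .core import Topology, Trajectory, read_trajectory, unwrap
from .energetics import read_energy_csv, solvation_enthalpy
from .errors import ConfigError, SelectionError
from .hbond import HBondCriterion, intermittent_lifetime, occupancy, sankey
from .solubility import fit_model
from .structure import FrameSpec, compute_rdf, compute_sdf, write_cube
from .transport import compute_msd, fit_diffusion

DEFAULT_R_CUT_PM = 300.0


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    trajectory: str
    format: str
    timestep: float
    topology: str
    output: str
    seed: int = 0
    box: list | None = None
    temperature_c: float | None = 80.0   # metadata only, recorded in provenance
    analyses: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        missing = [k for k in ("trajectory", "format", "timestep", "topology", "output")
                   if k not in doc]
        if missing:
            raise ConfigError(f"{path}: missing config keys: {', '.join(missing)}")
        cfg = cls(
            trajectory=str(doc["trajectory"]), format=str(doc["format"]),
            timestep=float(doc["timestep"]), topology=str(doc["topology"]),
            output=str(doc["output"]), seed=int(doc.get("seed", 0)),
            box=doc.get("box"), temperature_c=doc.get("temperature_c", 80.0),
            analyses=doc.get("analyses", {}) or {}, raw=doc,
        )
        if cfg.timestep <= 0:
            raise ConfigError("timestep must be positive")
        return cfg

    def validate(self, topo: Topology) -> None:
        """Check every referenced site label/species and numeric setting
        before any computation runs."""
        known = topo.labels()

        def check_labels(labels, where):
            labels = [labels] if isinstance(labels, str) else list(labels)
            for lab in labels:
                if lab not in known:
                    raise ConfigError(f"{where}: unknown site label {lab!r}")

        def check_positive(value, where):
            if not (float(value) > 0):
                raise ConfigError(f"{where}: must be positive, got {value}")

        for name, opts in self.analyses.items():
            opts = opts or {}
            if name == "rdf":
                check_labels(opts.get("ref", []), "rdf.ref")
                check_labels(opts.get("obs", []), "rdf.obs")
                check_positive(opts.get("r_max", 1000.0), "rdf.r_max")
                check_positive(opts.get("bins", 100), "rdf.bins")
            elif name == "sdf":
                species = opts.get("species")
                if species not in topo.species:
                    raise ConfigError(f"sdf.species: unknown species {species!r}")
                if "obs" in opts:
                    check_labels(opts["obs"], "sdf.obs")
                check_positive(opts.get("extent", 800.0), "sdf.extent")
                check_positive(opts.get("voxel", 50.0), "sdf.voxel")
            elif name in ("hbonds", "lifetimes", "sankey"):
                check_labels(opts.get("donors", []), f"{name}.donors")
                check_labels(opts.get("acceptors", []), f"{name}.acceptors")
                check_positive(opts.get("r_cut", DEFAULT_R_CUT_PM), f"{name}.r_cut")
                if name == "lifetimes":
                    check_positive(opts.get("max_lag", 1.0), "lifetimes.max_lag")
                if name == "sankey":
                    for lab in (opts.get("class_map") or {}):
                        check_labels(lab, "sankey.class_map")
            elif name == "msd":
                species = opts.get("species")
                if species not in topo.species:
                    raise ConfigError(f"msd.species: unknown species {species!r}")
                check_positive(opts.get("max_lag", 1.0), "msd.max_lag")
            elif name == "dhsolv":
                check_positive(opts.get("n_units", 1), "dhsolv.n_units")
            elif name == "fit":
                pass
            else:
                raise ConfigError(f"unknown analysis {name!r}")


def config_hash(doc: dict) -> str:
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()


def write_provenance(outdir: Path, cfg: RunConfig, applied_defaults: list) -> None:
    doc = {
        "config_sha256": config_hash(cfg.raw),
        "seed": cfg.seed,
        "ilsolv_version": __version__,
        "temperature_c": cfg.temperature_c,
        "applied_defaults": applied_defaults,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every requested analysis in dependency order.

    Validation failures raise before any output is produced. Returns the
    output directory.
    """
    topo = Topology.from_yaml(cfg.topology)
    cfg.validate(topo)
    applied_defaults: list[str] = []

    traj = read_trajectory(cfg.trajectory, format=cfg.format, timestep=cfg.timestep,
                           box=cfg.box)
    outdir = Path(cfg.output)
    outdir.mkdir(parents=True, exist_ok=True)

    occ = None
    criterion_opts = cfg.analyses.get("hbonds") or cfg.analyses.get("lifetimes") \
        or cfg.analyses.get("sankey")

    if criterion_opts is not None:
        r_cut = float(criterion_opts.get("r_cut", DEFAULT_R_CUT_PM))
        if "r_cut" not in criterion_opts:
            applied_defaults.append(f"hbond r_cut defaulted to {DEFAULT_R_CUT_PM} pm")
        criterion = HBondCriterion(donors=tuple(criterion_opts["donors"]),
                                   acceptors=tuple(criterion_opts["acceptors"]),
                                   r_cut=r_cut)
        occ = occupancy(traj, topo, criterion)
        occ.export(outdir / "hbond_pairs.csv", outdir / "hbond_occupancy.npz")

    for name, opts in cfg.analyses.items():
        opts = opts or {}
        if name == "rdf":
            result = compute_rdf(
                traj, topo, opts["ref"], opts["obs"],
                r_max=float(opts.get("r_max", 1000.0)),
                n_bins=int(opts.get("bins", 100)),
                exclude_intramolecular=bool(opts.get("exclude_intramolecular", True)))
            result.to_csv(outdir / "rdf.csv")
        elif name == "sdf":
            spec = FrameSpec(species=opts["species"], origin=tuple(opts["origin"]),
                             x=tuple(opts["x"]), plane=tuple(opts["plane"]))
            grid = compute_sdf(
                traj, topo, spec,
                obs_sel=opts.get("obs"),
                obs_ring=tuple(opts["obs_ring"]) if "obs_ring" in opts else None,
                extent=float(opts.get("extent", 800.0)),
                voxel=float(opts.get("voxel", 50.0)))
            write_cube(grid, outdir / "sdf.cube", outdir / "sdf.json")
        elif name == "lifetimes":
            result = intermittent_lifetime(occ, max_lag=float(opts["max_lag"]))
            result.to_csv(outdir / "lifetime_acf.csv")
            result.summary_json(outdir / "lifetime.json")
        elif name == "sankey":
            table = sankey(occ, topo, class_map=dict(opts["class_map"]),
                           intramolecular_policy={
                               tuple(k): v for k, v in
                               (opts.get("intramolecular_policy") or {}).items()})
            table.to_json(outdir / "sankey.json")
            table.to_csv(outdir / "sankey.csv")
        elif name == "msd":
            work = unwrap(traj) if traj.wrapped else traj
            curve = compute_msd(work, topo, opts["species"],
                                max_lag=float(opts["max_lag"]))
            curve.to_csv(outdir / "msd.csv")
            window = tuple(opts.get("window_frac", (0.1, 0.5)))
            if "window_frac" not in opts:
                applied_defaults.append("msd fit window defaulted to 10-50% of max lag")
            est = fit_diffusion(curve, window_frac=window)
            est.summary_json(outdir / "diffusion.json")
        elif name == "dhsolv":
            traces = [read_energy_csv(opts[key], label=key)
                      for key in ("solution", "pure_il", "vacuum")]
            result = solvation_enthalpy(*traces, n_units=int(opts["n_units"]))
            result.summary_json(outdir / "dhsolv.json")
        elif name == "fit":
            from .solubility import read_calibration_csv
            model = fit_model(read_calibration_csv(opts["calibration"]))
            model.save(outdir / "solubility_model.json")

    write_provenance(outdir, cfg, applied_defaults)
    return outdir
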