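# ilsolv

Trajectory analysis of hydrogen-bond structure, dynamics and solvation
energetics in ionic-liquid cellulose solvents — plus a calibrated log-model
that maps solvation enthalpy to cellulose solubility.

The package analyses classical MD output (multi-frame XYZ or LAMMPS text
dumps with orthorhombic periodic boxes) and provides:

- **core**: trajectory/topology readers, minimum-image geometry, exact
  unwrap/fold with integer image tracking, centers of mass. Internal units
  are pm / ps / amu / kJ/mol / e; Angstrom-based formats are converted on
  ingest.
- **synth**: synthetic fixtures with known ground truth — ideal gas
  (uniform density), Brownian walks (known diffusion coefficient),
  two-state telegraph hydrogen bonds (known formation/breaking rates,
  realized as O⋯H distance time series straddling the 300 pm cutoff),
  stacked aromatic ring pairs, Gaussian energy traces, and log-law
  solubility/enthalpy point sets. Every generator is a pure function of its
  seed and ships writers for the plain-text formats the readers consume.
- **structure**: radial distribution functions normalized to uniform
  density (periodic KD-tree pair counting, exact agreement with a naive
  double loop), local molecular frames, spatial distribution functions in
  nm⁻³ with Gaussian-cube export, ring centroids.
- **hbond**: distance-criterion hydrogen-bond occupancy (default 300 pm,
  closed ball, no angle term), intermittent lifetimes from the pooled
  occupancy autocorrelation (trapezoid integral plus exponential tail
  extension), and Sankey-style network-topology accounting with per-atom /
  per-molecule averages and per-class-pair intramolecular exclusion.
- **transport**: center-of-mass MSD over all sliding time origins and
  self-diffusion from the linear-window slope, D = slope/6
  (1 pm²/ps = 10⁻¹² m²/s).
- **energetics**: cutoff-truncated LJ + Coulomb group–group interaction
  energies (0.8 charge scaling by default) and the solvation-enthalpy
  estimator ΔH = (⟨E_sol⟩ − ⟨E_solvent⟩ − ⟨E_vacuum⟩)/n_units with
  propagated standard errors.
- **solubility**: least-squares calibration of ΔH = c2·ln S + c1, inverted
  prediction with a fixed factor-of-two band, bootstrap slope intervals,
  and the carbene-equilibrium helper log₁₀K = pKa₂ − pKa₁.

## CLI

The `ilsolv` entry point exposes `synth`, `rdf`, `sdf`, `hbonds`,
`lifetimes`, `sankey`, `msd`, `energy`, `dhsolv`, `fit`, `predict` and
`pipeline`. Exit codes: 0 success, 2 validation error, 3 data error.

Self-contained example (no external data needed):

```sh
# generate a telegraph hydrogen-bond fixture
ilsolv synth --generator telegraph --n 50 --frames 2000 --timestep 0.5 \
    --k-form 0.002 --k-break 0.02 --seed 1 --out fixture/

# intermittent hydrogen-bond lifetime with the 300 pm criterion
ilsolv lifetimes --traj fixture/traj.xyz --format xyz --timestep 0.5 \
    --topology fixture/topology.yaml --donor "H(Ring)" --acceptor "O(Car)" \
    --max-lag 400 --out lifetimes/

# whole-pipeline run from a YAML config (see tests/test_cli.py for a sample)
ilsolv pipeline --config config.yaml
```

Calibrating and applying the solubility model:

```sh
ilsolv fit --calibration calibration.csv --out model.json
ilsolv predict --model model.json --dh -85.0
```

where `calibration.csv` has columns `name,solubility_wtpct,dh_kj_per_mol_unit`.

## Layout

```
src/ilsolv/       core, synth, structure, hbond, transport, energetics,
                  solubility, pipeline, cli
tests/            unit + property tests per module, test_acceptance.py
scripts/          acceptance.py
```
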