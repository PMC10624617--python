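# pdpxtal

Simulation and analysis tools for pump–dump–probe (PDP) coherent-control
experiments on photoswitchable proteins, combining:

- **Vibronic quantum dynamics** — Lindblad density-matrix propagation of a
  displaced-harmonic two-surface system driven by Gaussian pump and dump
  pulses, with coherence, phase-space and Wigner-function observables.
- **Time-resolved crystallography** — Q-weighted Fo–Fo difference maps,
  structure-factor extrapolation, population-transfer estimation from the
  negative-density onset (PT = 200/N_EXT), and model geometry reports.
- **Kinetics and thermodynamics** — Arrhenius and two-channel
  (convex-Arrhenius) recovery fits, flash-photolysis yield curves with a
  nonlinear loss channel, and pump–dump action traces.
- **Transient-absorption analysis** — chirp correction and sequential
  global fitting (variable projection, EADS) of TA surfaces.
- **Synthetic data** — deterministic, seeded generators with embedded
  ground truth for every analysis path above.

## Command line

A single executable with subcommands (all emit JSON reports; data go to
files; logs to stderr):

```bash
pdpxtal simulate --dump-delay-fs 350          # PDP coherence simulation
pdpxtal diffmap light.hkl dark.hkl dark.pdb --map-out diff.ccp4
pdpxtal extrapolate light.hkl dark.hkl dark.pdb --scan-out scan.csv
pdpxtal geometry a.pdb b.pdb --pair "OO=A/65/OH:A/220/O"
pdpxtal fit-arrhenius rates.csv
pdpxtal fit-convex rates.csv
pdpxtal fit-flashyield yields.csv
pdpxtal action-trace trace.csv
pdpxtal globalfit ta_surface.csv --n-compartments 2 --initial-taus 1,30
pdpxtal synth toy_crystal --out-dir data --seed 1
pdpxtal workflow extrapolation_demo --out-dir run1 --seed 1
```

Workflows (`pdp_coherence`, `extrapolation_demo`, `kinetics_demo`) write a
`manifest.json` (inputs, parameters, library versions, seeds) and a
`summary.json`; re-running a workflow from the same configuration
reproduces every numeric output bit-for-bit.

## Python API

```python
from pdpxtal.quantum import simulate_pdp_experiment
from pdpxtal.quantum.experiment import coherent_control_study

study = coherent_control_study()
result = simulate_pdp_experiment(study.system, study.dissipation,
                                 study.pump, study.dump(350.0))
print(result.coherence_ratio(dump_time=350.0))   # ~1.8: coherence doubling
```

```python
from pdpxtal.synth import ToyCrystalSpec, make_toy_crystal
from pdpxtal.xtal import q_weight_differences, scan_n_ext

data = make_toy_crystal(ToyCrystalSpec(population_fraction=0.2, seed=1))
qw = q_weight_differences(data.light_reflections, data.dark_reflections,
                          alpha=0.0)
scan = scan_n_ext(qw.reflections, data.dark_calc, data.dark_model,
                  data.dark_model.atom_positions(), radius=1.2)
print(scan.population_transfer_percent)          # ~20 for f = 0.2
```

See `examples/` for runnable scripts and `docs/methods.md` for the
numerical methods, estimator choices and known biases.

## Tests

```bash
python -m pytest
```

`tests/test_acceptance.py` holds the end-to-end acceptance checks. The
deposited-model geometry test requires two protein coordinate files that
cannot be redistributed; place them at `data/pdb/7qlm.pdb` and
`data/pdb/7qln.pdb` to enable it (it fails with instructions otherwise).

The headline recovery metrics can be recomputed standalone:

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```
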