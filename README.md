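# cryphase

Crystallographic phase retrieval with iterative projection algorithms
(IPAs), treated as a nonconvex feasibility problem between measured
Fourier amplitudes and real-space constraints (solvent flatness plus
histogram equivalence). The package provides:

* five update rules — **ER**, **DM** (difference map), **RRR**
  (relaxed-reflect-reflect), **revRRR** and **RAAR** — with per-iteration
  constraint-satisfying solution estimates and per-iteration envelope
  re-estimation;
* a circular **phase-error model** (von Mises for acentric phases,
  wrapped-Bernoulli flips for centric ones) parameterized by a single
  circular variance, for controlled corruption experiments;
* **circular agreement statistics**: mean absolute phase difference, the
  real-space map correlation in amplitude/phase-difference form, the
  Fisher–Lee circular correlation, von Mises fits;
* **trajectory analysis**: per-reflection circular averaging over the
  stationary tail of a run, weighted map synthesis, ER polishing, the
  phase-retrieval transfer function (PRTF) in resolution shells, and a
  stationarity diagnostic;
* a **synthetic toy crystal** generator (high solvent content, exact
  amplitudes, known phases) and a geometry-free Wilson-data generator;
* file I/O (hkl text, MTZ import, CCP4/MRC maps, YAML configs), a tidy
  experiment harness, and a CLI.

See `docs/methods.md` for conventions and design choices.

## Worked example (Python)

Simulate a toy crystal, corrupt its phases at circular variance 0.5, run
RRR, and compare the trajectory-averaged map with the final iterate:

```python
import numpy as np
import cryphase as cp

# 30 A cubic P1 cell, 32^3 grid, 3.0 A data, 74% solvent
cell = cp.UnitCellGrid((30, 30, 30), (90, 90, 90), (32, 32, 32), d_min=3.0)
spec = cp.ToyCrystalSpec(cell=cell, seed=1, n_blobs=40, blob_width=1.8)
truth, envelope, prior = cp.make_toy_crystal(spec)
refl = cp.simulate_data(truth, seed=1)          # exact |F| + reference phases

config = cp.AlgorithmConfig(name="RRR", beta=0.8, n_iterations=150,
                            solvent_fraction=0.74, window_radius=2.5)
record = cp.run_replicate(refl, prior, config, variance=0.5,
                          replicate_seed=7, envelope=envelope)
print(f"final correlation vs truth: {record.final_correlation:.3f}")

# circular averaging over the trailing 30-iteration window
summaries = cp.trajectory_summaries(record)
avg_map = cp.synthesize_averaged_map(summaries, refl)

coeffs = cp.density_to_structure_factors(avg_map, refl)
cc = cp.map_correlation(np.abs(coeffs), refl.amplitudes,
                        cp.wrapped_difference(np.angle(coeffs), refl.phases))
print(f"averaged-map correlation:   {cc:.3f}")

per_refl, per_shell = cp.prtf(record)
print(per_shell)
```

Replicated sweeps over algorithms, relaxation parameters and error levels
return tidy long-format tables:

```python
table = cp.experiment_return_to_solution(
    refl, prior, [("RRR", 0.8), ("DM", 0.7)], variances=[0.3, 0.5, 0.7],
    n_replicates=10, n_iterations=150, seed=0, envelope=envelope,
)
finals = table.query("iteration == 150").groupby(["algorithm", "variance"])
print(finals["correlation"].mean())
```

## Worked example (CLI)

```bash
cryphase simulate --out toy.hkl --cell 30 --grid 32 --d-min 3.0 \
    --n-blobs 40 --blob-width 1.8 --seed 1
cryphase corrupt -V 0.5 --seed 7 --in toy.hkl --out noisy.hkl
cryphase metrics --in1 toy.hkl --in2 noisy.hkl
cryphase run --in toy.hkl --algorithm RRR --beta 0.8 --iterations 150 \
    -V 0.5 --seed 7 --metrics-out metrics.csv --map-out final.ccp4
cryphase sweep --in toy.hkl --algorithm DM --betas 0.6,0.75 \
    --variances 0.3,0.5 --replicates 10 --iterations 150 --out sweep.csv
```

All commands honor `--seed`; identical inputs and seeds give identical
outputs.

## Tests and calibration targets

```bash
python -m pytest -q tests/                     # unit + property + acceptance tests
python scripts/acceptance.py --seed 1 --out targets.json
```

The acceptance script recomputes the phase-error calibration targets
(mean absolute phase difference and starting map correlation at circular
variances 0.6–0.8) from scratch over 10 seeded replicates of 10,000
mostly-acentric reflections.

## Package layout

| Module | Contents |
| --- | --- |
| `cryphase.reciprocal` | unit-cell grid, reflection set, Fourier mapping, shells |
| `cryphase.projections` | envelope estimation and registration, P_A, P_B |
| `cryphase.engine` | update rules, run loop, trajectory records |
| `cryphase.phase_error` | circular error model and von Mises sampler |
| `cryphase.circular` | circular agreement statistics and fits |
| `cryphase.trajectory` | averaging, PRTF, ER polish, stationarity |
| `cryphase.synthetic` | toy crystals and Wilson calibration data |
| `cryphase.experiments` | replicated return-to-solution harness |
| `cryphase.hklio`, `cryphase.cli` | file formats and the `cryphase` CLI |
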