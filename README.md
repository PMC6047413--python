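# somno

Simulation and parameter estimation for a two-process model of sleep
homeostasis in mouse EEG, at 4-second epoch ("ts") resolution.

The package:

* models EEG slow-wave activity (SWA, 0.5–4 Hz power, % of baseline NREMS
  mean) and homeostatic sleep pressure (Process S) as a pair of coupled ODEs
  driven by binary wake/REM **trigger functions** that anticipate and outlast
  the scored vigilance states;
* detects **NREMS episodes** (> 1 min, tolerating interruptions ≤ 16 s),
  long NREMS episodes (≥ 3 min) and consolidated long wake bouts from a
  hypnogram;
* estimates the three homeostatic parameters **(gc, rs, S_U)** per animal and
  derivation by a two-stage, 3×3 multi-start Nelder–Mead minimisation of a
  light/dark-balanced squared error over per-episode SWA means;
* generates fully **synthetic mouse datasets** (semi-Markov 12:12 light/dark
  hypnograms matching published state occupancies, model-generated SWA with
  lognormal epoch noise, known ground truth) so the entire pipeline is
  testable offline.

## Command line

```bash
# seeded synthetic dataset: epochs.tsv + truth.json + manifest.json
somno generate --seed 1 --out data/

# two-stage fit + final simulation + error reports
somno fit --input data/epochs.tsv --protocol rw --derivation frontal --out results/

# forward simulation with known parameters
somno simulate --input data/epochs.tsv --params data/truth.json \
    --derivation frontal --out results/sim.tsv

# objective report for an existing simulation
somno evaluate --input data/epochs.tsv --simulation results/sim.tsv \
    --derivation frontal --out results/objective.json

# everything in one go
somno run-all --seed 1 --protocol rw --out results/
```

Protocols: `rw` (48 h undisturbed baseline), `cw` (fit on the 48 h before a
wheel exchange), `ew` (24 h baseline duplicated to a 48 h fit window).

The epoch table is TSV with columns
`epoch_index, state{W,N,R,BA}, artifact{0,1}, phase{L,D}, swa_<derivation>…`.

## Package layout

| module | contents |
| --- | --- |
| `somno.epoch_data` | `EpochSeries`, TSV I/O, Hann-FFT band power, SWA extraction, baseline normalisation |
| `somno.episodes` | NREMS episode / long-wake-bout detection, per-episode SWA means |
| `somno.triggers` | binary REMT/WT trigger construction |
| `somno.model` | `ModelParams`, the coupled ODEs, RK4 (numba) and adaptive (LSODA) integrators |
| `somno.objective` | moving-median smoothing, per-episode deviations, light/dark-balanced squared error, window error diagnostics |
| `somno.optimizer` | initial conditions, protocol fit windows, two-stage multi-start simplex estimation |
| `somno.synthetic` | seeded hypnogram + SWA generator with calibrated ground truth |
| `somno.cli` | `somno` command-line entry point |
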