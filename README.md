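# clampkit

Analysis pipeline for whole-cell patch-clamp electrophysiology of cultured
neurons, with a ground-truth synthetic-cell generator for validation.

The package implements the complete analysis battery of a four-group
neuronal excitability study (wild-type and tangle-bearing "Tau" neurons,
each with and without a pharmacological treatment, "AR"):

- **Current clamp** — spike detection by a slope-pair criterion
  (upstroke ≥ 30 mV/ms followed within 10 ms by a downstroke ≤ −15 mV/ms,
  peak above 0 mV), evoked/spontaneous/rebound classification against the
  step window, F-I curves, rheobase and first-spike features (threshold at
  the second-derivative maximum, latency, amplitude, full width at half
  amplitude).
- **Voltage clamp** — −10 mV ohmic leak subtraction, baseline zeroing,
  early transient extrema (first 10 ms of each step) and late persistent
  currents (final third), per-cell IV summaries.
- **Passive properties** — input resistance, series resistance and
  capacitance from a single-exponential fit to the −5 mV membrane-test
  transient.
- **Group statistics** — ROUT (Q = 0.05) outlier removal, Kruskal–Wallis
  with Dunn post-hocs, Mann–Whitney, Greenhouse–Geisser-corrected mixed
  ANOVA with Tukey post-hocs, and origin-constrained curve comparisons by
  extra-sum-of-squares F-tests.
- **Synthetic cells** — a leaky integrate-and-fire generator with a
  triangular spike template and a gated voltage-clamp model, logging exact
  ground truth (spike times, thresholds, passive parameters, leak-free
  current components) so every estimator can be validated end to end.

## Quick start

```python
from clampkit import wt_params
from clampkit.spike_pipeline import fi_curve, rheobase_features
from clampkit.synthetic_cells import simulate_cell

recordings, truth = simulate_cell(
    wt_params(), cell_id="demo", genotype="WT", treatment="vehicle", seed=7
)
from_rest = recordings[0]

rb = rheobase_features(from_rest)
fs = rb.first_spike
print(f"rheobase {rb.rheobase_current:.0f} pA; first spike: "
      f"threshold {fs.threshold_voltage:.1f} mV, latency {fs.latency:.2f} ms, "
      f"amplitude {fs.amplitude:.1f} mV, width {fs.width:.2f} ms")
```

prints (exactly, the generator is seeded):

```
rheobase 140 pA; first spike: threshold -45.3 mV, latency 41.00 ms, amplitude 84.9 mV, width 1.53 ms
```

The full pipeline — simulate a cohort, extract every feature, run the
statistical battery, write figures and a report — is one call (or
`clampkit run-all` on the command line):

```python
from clampkit.pipeline import PipelineConfig, run_pipeline

run_pipeline(PipelineConfig(seed=123, out_dir="run", design_scale=0.1))
```

`run/` then contains the stored cohort (`cohort/`), `features.csv` (one
row per cell × condition), `stats.csv`, `report.txt`, `figures/` and
`provenance.json`. Identical seeds give byte-identical CSV output.

See `examples/` for narrative walkthroughs of each stage and
`docs/methods.md` for the definitions, units and numerical choices.

## Command line

```sh
clampkit run-all  --seed 123 --out run --scale 0.1
clampkit simulate --seed 123 --out run --scale 0.1  # cohort only
clampkit analyze  run/cohort --out run              # features from containers
clampkit stats    --out run                         # uses run/features.csv
clampkit report   --out run
```

## Testing and reproducing results

```sh
python -m pytest -q tests/                  # unit + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script computes, at runtime from the given seed: protocol
grid fidelity, spike-detection agreement with a brute-force oracle over
1000 sweeps, noiseless ground-truth recovery errors for a 20-cell cohort,
the leak-subtraction residual of a purely ohmic cell, type-I error rates
of each statistical test over 500 null simulations, and the group-median
contrasts of a full-size cohort. Everything in the test suite and the
script is deterministic given the seed.

## Data model

Recordings are `CellRecording` objects: per-protocol lists of `Sweep`s
(float64 samples, acquisition metadata, half-open step window
`[onset, offset)`) plus `StepProtocol` descriptions. Containers round-trip
losslessly through `write_recording`/`read_recording` in two layouts: a
portable CSV long table (`%.17g`, bit-exact float64) and a compact binary
layout (raw little-endian float64 stacks plus a CSV index) for large
cohorts.
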