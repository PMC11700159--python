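# Methods

Definitions, units, defaults and numerical choices for every stage of the
pipeline. All voltages are mV, currents pA, resistances MΩ, capacitances
pF, and times seconds in APIs (milliseconds where a field name says so).
Traces are float64 at 10 kHz by default.

## Data model

A `Sweep` is one digitized trace plus acquisition metadata: sampling rate,
command level (step amplitude relative to holding), holding level, and the
step window. The step window is **half-open**, `[onset, offset)`: the
offset sample belongs to the post-step epoch. A `StepProtocol` describes a
family of sweeps (mode, epoch durations, amplitude grid, repetitions); a
`CellRecording` groups the sweeps of one cell in one condition with its
protocols and labels (genotype, treatment → group labels `WT`, `WT+AR`,
`Tau`, `Tau+AR`).

Containers round-trip recordings losslessly. The portable layout is a
`meta.json` sidecar plus one CSV long table per protocol
(`sweep,time_s,command,response,repetition`) printed with `%.17g`, which
round-trips float64 bit-exactly (reading uses pandas
`float_precision="round_trip"`). The bulk layout stores each protocol as a
raw little-endian float64 stack (`sweeps_<name>.npy`) plus a CSV index;
it is used by the pipeline for full cohorts, where the CSV layout would be
two orders of magnitude larger and slower.

## Study protocols

- **Current steps**: −100 → 480 pA in 20 pA increments (30 amplitudes),
  5 repetitions, 100 ms pre / 500 ms step / 400 ms post.
- **Voltage steps**: holding −60 mV, injections −10 → +100 mV in 10 mV
  increments (absolute −70 → +40 mV), 50 ms pre / 300 ms step / 150 ms
  post. The −10 mV step is mandatory: it is the leak reference.
- **Membrane test**: −5 mV from holding (−65 mV absolute), 3 repetitions,
  50 ms pre / 100 ms step / 50 ms post.

## Spike detection

First-order finite differences of the raw trace (no smoothing),
`slope[i] = (v[i+1] − v[i]) · rate / 1000` in mV/ms. An event is an
up-crossing of **+30 mV/ms** paired with the first subsequent
down-crossing of **−15 mV/ms**; the pair must close within **10 ms** and
the voltage maximum across the paired span must exceed **0 mV**. Pairing
is greedy left-to-right; consumed crossings cannot seed another event.
Crossing times are sample-resolution (no sub-sample interpolation for
detection). The test suite proves equivalence with an exhaustive
brute-force scan on thousands of randomized sweeps.

Classification against the step window: up-cross before onset →
*spontaneous*; up-cross inside `[onset, offset)` of a **depolarizing**
step → *evoked*; everything else (including spikes during hyperpolarizing
steps and at/after offset) → *rebound*. Only evoked spikes enter F-I
curves and rheobase.

## Rheobase and first-spike features

Rheobase is the smallest positive step amplitude with ≥ 1 evoked spike in
any repetition (lowest repetition index supplies the measured spike).
For that first spike:

- **Threshold**: voltage at the maximum of the second finite difference
  within the 3 ms before the up-cross (earliest sample wins ties).
- **Latency**: step onset → threshold, ms.
- **Amplitude**: peak − threshold.
- **Width**: full width at the half-amplitude level
  (threshold + amplitude/2), with linear sub-sample interpolation —
  chords at half amplitude are tolerance-sensitive, so interpolation is
  used here although detection is sample-resolution.
- **Spike end**: first sample after the peak back **below** threshold;
  width and end are reported absent when the trace never re-crosses.

Cells that never fire an evoked spike are excluded from rheobase
statistics (no imputed value).

## Voltage-clamp measurements

Leak subtraction: the mean across repetitions of the −10 mV sweeps is the
leak trace; each sweep gets `I(t) − (ΔV/−10)·I_leak(t)`. Zeroing then
subtracts the mean pre-step current (≥ 10 ms of pre-step required).
Per injection, repetitions are averaged and three numbers are taken:
maximum transient inward (trace minimum, clipped at 0 from above) and
outward (maximum, clipped at 0 from below) over the **first 10 ms** of
the step, and the signed mean over the **final third** (late/persistent
current). Per-cell summaries are the most negative early inward and the
largest early outward across injections.

## Passive properties

From the averaged membrane-test trace, the transient is fit as
`I(t) = I_ss + (I_peak − I_ss)·exp(−t/τ)` (scipy `curve_fit`), starting
one sample after the step edge (the edge sample carries the command
discontinuity) and extrapolating the fitted curve back to the edge to
recover `I_peak`. With ΔV the pulse amplitude and `I_base` the pre-step
baseline:

```
R_s  = ΔV / (I_peak − I_base)          (mV/pA = GΩ, reported in MΩ)
R_in = ΔV / (I_ss  − I_base) − R_s
C_m  = τ · (R_in + R_s) / (R_in · R_s)  (µs/MΩ = pF)
```

If the transient decays within one sample (τ unidentifiable at the
sampling rate), resistances are still computed from the raw edge sample
and steady state, but the capacitance is flagged `capacitance_reliable =
False` with a warning. Non-physical fits raise instead of guessing.

## Synthetic cells

The current-clamp generator is a leaky RC integrator
(`dV/dt = (v_rest − V)/(R_in·C_m) + I/C_m`, pA/pF = mV/ms) stepped by
forward Euler at 0.1 ms on the acquisition grid (simulation rejects
τ < 4 samples as unstable). When V reaches the threshold a triangular
spike template is inserted: ~200 mV/ms rise to threshold + amplitude,
linear fall, both limbs snapped to grid multiples so the apex lies on a
sample and the analytic half-width `(t_rise + t_fall)/2` is exact under
linear interpolation. After the spike the voltage resets to threshold −
AHP with a refractory hold, and a per-spike exponentially-decaying
adaptation current accumulates. Spike insertion times, template
threshold/amplitude/width are logged as ground truth before noise is
added. The integration kernel is JIT-compiled with numba.

The voltage-clamp generator is closed-form: linear leak through
`R_s + R_in`, a capacitive edge transient with τ = (R_s‖R_in)·C_m, a
Boltzmann-gated fast inward transient and delayed outward current
(both normalized to their stated peak at 0 mV absolute), and a persistent
linear component applied only to depolarizing injections (so it survives
leak subtraction). Leak-free component traces and their early/late
summaries are logged as ground truth.

Group presets encode the study's *directions* only (magnitudes are
package choices): Tau cells have higher input resistance (250 vs 150 MΩ),
lower capacitance (55 vs 90 pF), depolarized rest (−58 vs −65 mV), higher
threshold, stronger adaptation, and smaller voltage-gated currents;
AR-treated Tau cells are drawn from the wild-type distribution. The
default design is 64/13/40/31 cells (WT/WT+AR/Tau/Tau+AR), scalable.
Cohorts use one `SeedSequence` split hierarchically per cell, so any
cohort is bit-exactly reproducible from its seed.

## Group statistics

- **ROUT (Q = 0.05)**, univariate: residuals from the median, robust SD =
  68.27th percentile of |residuals| × √(n/(n−1)); candidates (≤ 30% of
  the sample) tested outside-in with two-sided t-tails under thresholds
  `p_j ≤ Q·j/n`; everything at least as extreme as the innermost
  significant point is removed. Samples of n < 4 are passed through with
  a warning.
- **Kruskal–Wallis + Dunn**: scipy omnibus (tie-corrected); Dunn pairwise
  rank z-tests with tie-corrected pooled variance and Holm adjustment by
  default.
- **Mann–Whitney**: exact for n ≤ 8 per group without ties, otherwise the
  tie-corrected normal approximation.
- **Mixed ANOVA with Greenhouse–Geisser correction**: split-plot
  between (group) × within (level) decomposition; ε̂ from the pooled
  within-group covariance via `ε = tr(CSC)² / ((k−1)·tr((CSC)²))`
  (C the centering matrix), clipped to `[1/(k−1), 1]` and exactly 1 for
  k = 2. The within and interaction F-tests are reported both uncorrected
  and with ε̂-deflated degrees of freedom. Subjects missing any level are
  excluded listwise with a warning. Tukey HSD post-hocs act on subject
  means across levels (statsmodels).
- **Curve comparisons**: firing-probability curves are compared by
  origin-constrained fits — one-phase association
  `Y = Plateau·(1 − exp(−K·x))` for P(≥1 spike) and a line through the
  origin for P(exactly 1) — with shared-vs-per-group models tested by the
  extra-sum-of-squares F-test.

Type-I calibration of all four tests is asserted in the acceptance suite
(within [0.03, 0.07] at α = 0.05 over 500 null simulations at 10
cells/group, 3 groups or levels as applicable).

## Pipeline

`run_pipeline` chains simulate → analyze → stats → report. The feature
table has one row per cell × condition: passive properties, per-amplitude
spike counts and firing proportions, rheobase features, per-injection
early/late currents and per-cell maxima. Rows are sorted and CSVs are
written deterministically, so identical seeds give byte-identical output.
`provenance.json` records seed, configuration hash and package version;
`pipeline.log` records stage progress and any skipped endpoints.

## Limitations

- The synthetic neuron is a single-compartment caricature: triangular
  spikes, no channel kinetics in current clamp, no space clamp artifacts;
  it is a test oracle for the *analysis*, not a biophysical model.
- The voltage-clamp gates are steady-state Boltzmanns with fixed time
  constants; at −70 mV the outward gate is not exactly closed, so leak
  subtraction carries ≤ ~2% contamination into small early extrema
  (bounded by the 5 pA / 2% acceptance floor).
- ROUT here is the univariate special case (constant model), not robust
  nonlinear regression.
- The extra-sum-of-squares F-test is exact only for linear models; for
  the one-phase fit it is approximate, with calibration verified
  empirically.
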