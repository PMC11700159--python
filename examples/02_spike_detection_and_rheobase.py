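"""Detect spikes, build an F-I curve and extract rheobase spike features.

Spike detection uses the slope-pair criterion: an upstroke reaching
30 mV/ms followed within 10 ms by a downstroke reaching -15 mV/ms, with
the intervening peak above 0 mV.  The first spike at rheobase is measured
in full: threshold (second-derivative maximum), latency, amplitude and
full width at half amplitude.
"""

from clampkit import wt_params
from clampkit.spike_pipeline import classify_spikes, detect_spikes, fi_curve, rheobase_features
from clampkit.synthetic_cells import simulate_cell

recordings, truth = simulate_cell(
    wt_params(), cell_id="demo", genotype="WT", treatment="vehicle", seed=7
)
from_rest = recordings[0]

# Per-sweep detection and classification.
sweep = max(from_rest.sweeps["current_steps"], key=lambda s: s.command_level)
events = classify_spikes(detect_spikes(sweep), sweep)
print(f"{sweep.command_level:.0f} pA sweep: {len(events)} spikes "
      f"({sum(e.classification == 'evoked' for e in events)} evoked)")

# F-I curve: mean evoked count per amplitude across repetitions.
fi = fi_curve(from_rest)
for amp, count in zip(fi.amplitudes[::6], fi.spike_count[::6]):
    print(f"  {amp:6.0f} pA -> {count:.1f} spikes")

# Rheobase and the fully featured first spike.
rb = rheobase_features(from_rest)
fs = rb.first_spike
print(f"rheobase {rb.rheobase_current:.0f} pA; first spike: "
      f"threshold {fs.threshold_voltage:.1f} mV, "
      f"latency {fs.latency:.2f} ms, amplitude {fs.amplitude:.1f} mV, "
      f"width {fs.width:.2f} ms")
print(f"(generator truth: threshold {truth.params.spike_threshold:.1f} mV, "
      f"amplitude {truth.params.spike_amplitude:.1f} mV)")
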