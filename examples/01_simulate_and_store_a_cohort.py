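"""Simulate a small synthetic cohort and store it in the container format.

Each synthetic neuron is a leaky integrate-and-fire cell with a triangular
spike template plus a linear-leak, Boltzmann-gated voltage-clamp model.
Every cell is recorded twice (from rest and held at -60 mV) with the full
study battery: current steps, voltage steps and the -5 mV membrane test.
"""

from pathlib import Path

from clampkit import read_recording, write_recording
from clampkit.synthetic_cells import default_design, make_cohort

out = Path("example_out/cohort")
out.mkdir(parents=True, exist_ok=True)

# A scaled-down version of the study design (WT, WT+AR, Tau, Tau+AR).
design = default_design(scale=0.05)
for label, spec in design.items():
    print(f"{label}: {spec.n_cells} cells ({spec.genotype}, {spec.treatment})")

recordings, truths = make_cohort(design, seed=42)
print(f"simulated {len(recordings)} recordings from {len(truths)} cells")

# Store and re-load one recording to show the round trip.
rec = recordings[0]
path = write_recording(rec, out, fmt="csv")
back = read_recording(path)
assert back == rec
print(f"round-tripped {back.cell_id} ({back.condition}) through {path}")

# Ground truth is available per cell for validation work.
truth = truths[rec.cell_id]
print(f"true R_in = {truth.params.r_input:.1f} MOhm, "
      f"C_m = {truth.params.c_m:.1f} pF, "
      f"threshold = {truth.params.spike_threshold:.1f} mV")
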