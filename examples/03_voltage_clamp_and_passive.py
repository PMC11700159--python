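"""Leak subtraction, IV features and passive properties for one cell.

Voltage-clamp sweeps are leak-subtracted against the -10 mV step (scaled
linearly), zeroed to the pre-step baseline, and summarized per injection:
maximum transient inward/outward current in the first 10 ms of the step
and the mean persistent current over its final third.  Passive properties
come from a single-exponential fit to the -5 mV membrane-test transient.
"""

from clampkit import estimate_passive, wt_params
from clampkit.synthetic_cells import simulate_cell
from clampkit.trace_model import MEMBRANE_TEST
from clampkit.vclamp_pipeline import cell_vclamp_summary, vclamp_features

recordings, truth = simulate_cell(
    wt_params(), cell_id="demo", genotype="WT", treatment="vehicle", seed=11
)
held = recordings[1]  # the held -60 mV condition carries the VC battery

feats = vclamp_features(held.sweeps["voltage_steps"])
print("inj (mV)  early inward (pA)  early outward (pA)  late mean (pA)")
for inj, ei, eo, lm in zip(feats.injections, feats.early_max_inward,
                           feats.early_max_outward, feats.late_mean):
    print(f"{inj:8.0f}  {ei:17.1f}  {eo:18.1f}  {lm:14.1f}")

max_in, max_out = cell_vclamp_summary(feats)
print(f"cell summary: max inward {max_in:.0f} pA, max outward {max_out:.0f} pA")

pp = estimate_passive(held.sweeps[MEMBRANE_TEST],
                      resting_potential=held.resting_potential)
print(f"passive: R_in {pp.input_resistance:.1f} MOhm "
      f"(true {truth.params.r_input:.1f}), "
      f"R_s {pp.series_resistance:.1f} MOhm, C_m {pp.capacitance:.1f} pF")
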