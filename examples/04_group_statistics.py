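"""The statistical battery on a simulated cohort's feature table.

Scalar endpoints get per-group ROUT (Q = 0.05) outlier removal, then
Kruskal-Wallis with Dunn post-hocs; repeated-measures endpoints (spike
counts across current steps) get a Greenhouse-Geisser-corrected mixed
ANOVA with Tukey post-hocs; firing-proportion curves are compared by
origin-constrained fits and extra-sum-of-squares F-tests.
"""

from clampkit.group_stats import GroupSample, kruskal_dunn, rout_outliers
from clampkit.pipeline import feature_table, run_group_stats
from clampkit.synthetic_cells import default_design, make_cohort

recordings, _ = make_cohort(default_design(scale=0.1), seed=3)
features = feature_table(recordings)
held = features[features["condition"] == "held_minus60"]

# Low-level usage: one endpoint by hand.
groups = []
for label, sub in held.groupby("group"):
    vals = sub["r_input_MOhm"].dropna().to_numpy()
    kept, removed = rout_outliers(vals)
    print(f"{label}: n={kept.size} (ROUT removed {removed.size})")
    groups.append(GroupSample(label, kept))
res = kruskal_dunn(groups)
print(f"input resistance: Kruskal-Wallis H={res['H']:.2f}, p={res['p']:.4g}")
print(res["pairwise"].to_string(index=False))

# High-level usage: the full battery with a readable report.
stats, report = run_group_stats(features)
print(f"\n{len(stats)} statistical results; report:\n")
print(report)
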