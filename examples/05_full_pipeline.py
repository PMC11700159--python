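"""Run the whole pipeline end to end: simulate -> analyze -> stats -> report.

Equivalent to the command line:

    clampkit run-all --seed 123 --out example_out/run --scale 0.08

The output directory contains the stored cohort, the per-cell feature
table, the statistics table, a text report, figures and provenance
metadata.  Identical seeds give byte-identical CSV outputs.
"""

from pathlib import Path

from clampkit.pipeline import PipelineConfig, run_pipeline

out = run_pipeline(PipelineConfig(
    seed=123,
    out_dir="example_out/run",
    design_scale=0.08,
))

for p in sorted(Path(out).rglob("*")):
    if p.is_file():
        print(p)

print("\n--- report.txt ---")
print((Path(out) / "report.txt").read_text())
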