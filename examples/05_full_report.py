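"""One config-driven pipeline run: simulate, analyze, render, summarize.

Simulates a small male-intruder cohort, runs the full pipeline, and prints
the group feeding and divergence summary.  The output directory contains
per-subject rasters, per-condition heatmaps, the divergence and feeding
tables, threshold curves and summary.json.
"""

import json

from ethoseq import RunConfig, run_pipeline

cfg = RunConfig(
    outdir="scratch/example_report",
    scenario="male_intruder",
    n_subjects=4,
    duration_s=1200,
    seed=8,
    make_plots=True,
)
summary = run_pipeline(cfg)

print(json.dumps(summary["feeding"], indent=2))
print(json.dumps(summary["divergence"], indent=2))
print(
    "Mean intake rises with hunger while the cosine distance from the Fed\n"
    "baseline grows: feeding crowds out the social repertoire."
)
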