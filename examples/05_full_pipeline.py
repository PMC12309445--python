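"""End-to-end run: simulate control and stressed cohorts for one session
day, execute every analysis stage, and print the group-statistics table.

Equivalent shell invocation:  cuephys run --seed 7 --n-animals 2 \
    --n-repeats 10 --out outdir
"""

import pandas as pd

from cuephys import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    sessions=("day1",), n_animals=2, n_repeats=10, n_shuffles=5, seed=7
)
manifest = run_pipeline("pipeline_out", cfg)
print("tables written:", sorted(manifest["files"]))

stats = pd.read_csv("pipeline_out/stats.tsv", sep="\t")
print(stats.to_string(index=False))
# Rows compare control vs stress per area/epoch: proportions of responsive
# units (chi-square or Fisher), population activity (t tests on per-unit
# epoch-mean z) and decoding accuracy (t on per-repeat accuracies).  With
# the day-1 stress presets, expect dmPFC activity lower and VTA rapid-tone
# activity/decoding higher in the stressed cohort.
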