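"""Run the whole chain: simulate → funnel → ELISPOT calls → classify →
tumor efficacy, writing every stage output plus a run report to ./out.

The same run is available from the shell as
``th1select run --config cfg.json``.
"""

import json

from th1select.pipeline import RunConfig, run_pipeline

config = RunConfig(
    out_dir="out",
    seed=7,
    simulate_genes={"n_genes": 100, "n_true_candidates": 10},
    simulate_elispot={"n_donors": 10},
    simulate_tumor={"n_mice": 15, "noise_cv": 0.3},
)

report = run_pipeline(config)
print(json.dumps({s: v["counts"] for s, v in report.stages.items()}, indent=2))

# Stage counts summarize the run: genes surviving the funnel, epitopes per
# selectivity label, and the number of mice and termination events in the
# simulated challenge study.  Rerunning with the same config and seed
# reproduces byte-identical outputs (compare the checksums in
# out/run_report.json).
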