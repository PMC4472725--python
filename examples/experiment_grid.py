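"""Run a small scenario grid end to end and print the evaluation table.

Uses a reduced design (two trends x {constant phi 0, linear 0.2-0.7}, a few
replicates) so it finishes in about a minute; the full study grid is
3 trends x (4 constant levels + 3 patterns x 5 ranges) at 100 replicates.
Outputs land in ./example_results/ as CSV (per-fit rows, per-scenario
summaries, and OLS meta-regressions of bias on the design factors).
"""

import pandas as pd

from migtrend.evaluation import run_experiment

config = {
    "trends_pct": [0.0, -1.2],
    "constant_levels": [0.0],
    "patterns": ["linear"],
    "phi_ranges": [(0.2, 0.7)],
    "n_replicates": 4,
    "master_seed": 1,
}

paths = run_experiment(config, "example_results", progress=print)
summaries = pd.read_csv(paths["summaries"])
print()
print(summaries[["scenario_id", "mean_bias", "coverage", "power", "error"]].to_string(index=False))
print("\nconstant-phi scenarios stay unbiased; the linear-increase scenarios")
print("show the positive bias and error rate that motivate the study.")
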