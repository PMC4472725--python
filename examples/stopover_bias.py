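"""The core result: a systematic increase in stopover duration biases trends.

Simulates populations declining 1.2 %/yr whose daily survival probability
rises linearly from 0.2 to 0.7 over 20 years (mean stopover ~1.2 -> ~3.4
days, so each bird is detected on more and more days), and compares three
analyses on the same datasets:

  * untreated          — the plain trend model;
  * covariate-only     — adds the true annual phi as a covariate;
  * covariate + 5-day  — the covariate plus subsampling to every 5th day.

Mean bias (estimated - simulated trend) should be strongly positive
untreated (~+5 %/yr: counts inflate as stays lengthen), roughly halved by
the covariate (phi rises exactly linearly, so the likelihood cannot fully
separate it from the year trend), and the treated fits recover interval
coverage by honestly widening.
"""

import numpy as np

import migtrend as mt
from migtrend.evaluation import evaluate_scenario, run_scenario

N_REP = 8
phi = mt.make_phi_schedule("linear", 0.2, 0.7, nyears=20)
cache = {}

print(f"{'arm':<18}{'mean bias':>10}{'coverage':>10}{'error':>8}")
for name, cov, sub in [
    ("untreated", False, "none"),
    ("covariate-only", True, "none"),
    ("covariate+5-day", True, "every5"),
]:
    scen = mt.ScenarioSpec(trend_pct=-1.2, phi=phi, covariate_arm=cov, subsample_arm=sub)
    fits = run_scenario(scen, n_replicates=N_REP, master_seed=0, dataset_cache=cache)
    s = evaluate_scenario(fits, -1.2, name)
    print(f"{name:<18}{s.mean_bias:>+10.2f}{s.coverage:>10.2f}{s.error:>8.2f}")

print("\nbias is %/yr; positive bias means the decline is underestimated or")
print("even reported as an increase — the false-trend mechanism under study.")
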