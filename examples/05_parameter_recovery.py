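"""How reliably does the pipeline detect a true gene-cytoplasm interaction?

Each repeat draws a fresh synthetic experiment, so the frequencies below are
operating characteristics of the whole procedure: the false-positive rate at
beta3 = 0 and the detection power as the interaction grows to 5 sigma.
"""

from dataclasses import replace

import cytovar as cv

base = cv.SynthConfig(beta0=4.0, sigma=0.2, experiment_id="grid")
grid = [replace(base, beta3=k * 0.2) for k in range(6)]   # 0 .. 5 sigma

report = cv.recovery_suite(grid, repeats=100, master_seed=3,
                           methods=("linear", "lasso"))
print("interaction selection frequency vs interaction effect size:")
print(report.pivot(index="beta3", columns="method",
                   values="interaction_freq").round(2))
print("-> 'lasso' is the BIC support rate (its beta3=0 row is the type-I "
      "error); 'linear' is the test-MSE winner rate; both should rise to "
      "1.0 as the effect reaches several sigma")
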