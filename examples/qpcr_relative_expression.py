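"""Relative expression by the comparative-Ct method (2^-ddCt).

Per fish: replicate Ct values are averaged, dCt = Ct(target) - Ct(reference);
ddCt subtracts the control-group mean dCt, and fold change = 2^-ddCt, so
control fish centre on fold 1.
"""

import numpy as np

from scoliomorph.cohort import relative_expression
from scoliomorph.simulate import gen_ct_table

cts, true_fold = gen_ct_table(true_fold=3.5, n_per_group=7, n_control=5, noise_sd=0.1, seed=2)
results = relative_expression(cts, "target", "reference", control_group="control")

for r in results:
    print(f"{r.sample_id:10s} {r.group:8s} dCt={r.delta_ct:6.3f}  fold={r.fold_change:5.2f}")
mut = [r.fold_change for r in results if r.group == "mutant"]
print(f"\nmutant group mean fold: {np.mean(mut):.2f} (planted: {true_fold})")
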