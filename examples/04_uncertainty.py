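"""Bootstrap confidence intervals and permutation p-values for a gate.

The gate's sensitivity and specificity are re-estimated over bootstrap
resamples of the cells (thresholds held fixed), and compared against a
permutation null in which TM labels are shuffled within each resample.
A null that never reaches the observed value is reported as a bound.
"""

import pandas as pd

from tmgate.gates import GateEvalParams, evaluate_gate, parse_gate
from tmgate.resampling import ResamplingParams, bootstrap_ci, permutation_p
from tmgate.simulate import SimConfig, simulate_paired_sample
from tmgate.tcr import TM, NON_TM, assign_clonotypes, label_matching

sim = simulate_paired_sample(SimConfig(rng_seed=1))
clones = assign_clonotypes(sim.chains)
comp = sim.bundle.cell_meta["compartment"]
blood = {bc: clones.get(bc) for bc in comp.index[comp == "blood"]}
tumor = {bc: clones.get(bc) for bc in comp.index[comp == "tumor"]}
labels = label_matching(blood, tumor)
paired = labels[(labels["compartment"] == "blood")
                & labels["label"].isin([TM, NON_TM])]
sub = sim.bundle.subset_cells(sim.bundle.cell_meta.index.isin(paired.index))
tm = (paired["label"] == TM).reindex(sub.barcodes).to_numpy()
expr = pd.DataFrame(sub.counts.T, columns=sub.gene_ids)

gate = parse_gate("MARK1^low & (MARK2^low | MARK3^low)")
params = ResamplingParams(B=2000, rng_seed=1)
for stat_name in ("sensitivity", "specificity"):
    def stat(df, l, _n=stat_name):
        return getattr(evaluate_gate(gate, df, l, GateEvalParams()), _n)
    ci = bootstrap_ci(expr, tm, stat, params, name=stat_name)
    pp = permutation_p(expr, tm, stat, params, name=stat_name)
    print(f"{stat_name}: {ci.point:.3f}  "
          f"95% CI [{ci.ci_lo:.3f}, {ci.ci_hi:.3f}]  "
          f"empirical p {pp.p_display()}")
# "p <0.0005" means the permuted null never reached the observed value in
# B = 2,000 iterations; at B = 10,000 the bound becomes "<0.0001".
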