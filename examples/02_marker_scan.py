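"""Scan every gene for TM-discriminating power: XL-mHG test + grid AUC.

Each gene is tested in both directions — "marker" (high expression marks TM
cells) and "marker_negation" (low expression marks TM cells) — with an
exact XL-minimal-hypergeometric p-value, a Benjamini-Hochberg q-value
across all genes x directions, the selected expression cutoff, and the
39-threshold grid AUC.
"""

from tmgate.markers import marker_scan
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

table = marker_scan(sub.counts, list(sub.gene_ids), tm)
print(table.sort_values("q").head(8).to_string(index=False,
      float_format=lambda v: f"{v:.3g}"))
# The four planted negation markers (MARK1-4, log2FC = -1.5 in TM cells)
# surface with q << 0.05 in the marker_negation direction and AUC well
# above 0.5; background genes stay at q ~= 1.
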