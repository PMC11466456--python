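"""Differential-expression filtering, tissue overlap and target cross-reference.

Applies the strict deregulation criterion (adjusted p < 0.05 and
|log2FC| > 0.75) to emulated trunk and brain transcriptome tables, overlaps
the up-sets between tissues, and counts how many upregulated genes fall in a
curated target list.
"""

import pandas as pd

from scoliomorph.omics import FeatureStats, FilterCriteria, crossref_targets, filter_deg, overlap
from scoliomorph.simulate import gen_paired_deg_tables, gen_target_lists


def to_feats(df):
    return [
        FeatureStats(r.gene_id, r.log2FoldChange,
                     None if pd.isna(r.pvalue) else r.pvalue,
                     None if pd.isna(r.padj) else r.padj)
        for r in df.itertuples()
    ]


pair = gen_paired_deg_tables(seed=11)
crit = FilterCriteria(padj_max=0.05, lfc_min=0.75)
trunk = filter_deg(to_feats(pair["trunk"]), crit)
brain = filter_deg(to_feats(pair["brain"]), crit)

print(f"trunk: {trunk.n_up} up / {trunk.n_down} down of {trunk.n_input} genes")
print(f"brain: {brain.n_up} up / {brain.n_down} down of {brain.n_input} genes")
print(f"up-set overlap brain & trunk: {overlap(brain.up_ids, trunk.up_ids).n_both} genes")

targets, direct = gen_target_lists(trunk.up_ids, n_in_targets=106, n_direct=77, seed=11)
n_t, n_d = crossref_targets(trunk.up_ids, targets, direct)
print(f"trunk up-set in target list: {n_t}, of which direct targets: {n_d}")
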