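"""Cross-line Venn arithmetic and inverse-correlation candidates.

First the worked example with the published category sizes of a
two-cell-line knockdown screen, then the same arithmetic on simulated
gene sets.
"""
from episcreen import VennCounts, intersect_lines, inverse_correlation_candidates, rank_candidates

# published sizes: 104 and 125 hypermethylated genes sharing 33
a = {f"L1_{i}" for i in range(71)} | {f"SH_{i}" for i in range(33)}
b = {f"L4_{i}" for i in range(92)} | {f"SH_{i}" for i in range(33)}
v = VennCounts.from_sets(a, b)
print(f"hypermethylated: {v.n_a} vs {v.n_b}, shared {v.n_shared} "
      f"-> unique {v.unique_a} / {v.unique_b}, union {v.union}")

# inverse-correlation candidates = commonly hypo AND commonly up
hypo_common = {"SP5", "FOXP1", "ROBO1", "DPP4", "KEEP1"}
up_common = {"SP5", "FOXP1", "ROBO1", "DPP4", "OTHER"}
table = inverse_correlation_candidates(
    hypo_common, up_common,
    delta_beta={"line1": {g: 0.4 for g in hypo_common}},
    log2fc={"line1": {"SP5": 2.5, "FOXP1": 2.0, "ROBO1": 1.1, "DPP4": 1.5}})
shortlist = rank_candidates(table, fc_top_min=2.5)
print("candidates:", ", ".join(table["gene_id"]))
print("shortlist at fold >= 2.5 in every line:", ", ".join(shortlist["gene_id"]))
# ROBO1 (observed fold 2^1.1 = 2.1) drops below the 2.5-fold shortlist bar.
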