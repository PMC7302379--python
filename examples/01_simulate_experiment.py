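"""Simulate a two-line knockdown experiment with recorded ground truth.

Builds the probe manifest, the beta-value matrix (1 control + 2 knockdown
replicates per line) and the RNA-seq count matrix, and prints what was
planted where. Every output is a pure function of the seed.
"""
from episcreen import SimulationConfig, generate_manifest, simulate_beta_matrix, simulate_counts

cfg = SimulationConfig(seed=1, n_genes=300, cpgs_per_gene=3)
manifest = generate_manifest(cfg)
beta, truth = simulate_beta_matrix(manifest, cfg)
counts, de_truth = simulate_counts(cfg)

print(f"manifest: {len(manifest)} probes over {cfg.n_genes} genes")
print(f"beta matrix: {beta.values.shape[0]} probes x {beta.values.shape[1]} samples")
print(f"count matrix: {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples")
print(f"planted hypomethylated genes: {len(truth.hypo_genes['line1'])}")
print(f"planted hypermethylated genes: {len(truth.hyper_genes['line1'])}")
print(f"planted upregulated genes: {len(de_truth.de_up_genes['line1'])}")
overlap = truth.hypo_genes["line1"] & de_truth.de_up_genes["line1"]
print(f"planted hypomethylated AND upregulated (the candidate truth): {len(overlap)}")
# The planted hypo/up overlap is what the integration stage should recover.
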