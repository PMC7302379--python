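"""End-to-end run: simulate -> screen -> DE -> integrate, with a report.

Equivalent to ``episcreen pipeline demo --out <dir>``; writes all stage
outputs plus run_report.json and prints the integration summary.
"""
import json
import tempfile

from episcreen import DEParams, RunConfig, SimulationConfig, run_pipeline

with tempfile.TemporaryDirectory() as out:
    sim = SimulationConfig(seed=1, n_genes=300)
    report = run_pipeline(RunConfig(seed=1, out_dir=out, simulation=sim,
                                    de=DEParams(dispersion=sim.nb_dispersion)))
    print(json.dumps(report["stages"]["integrate"], indent=2))
# n_candidates counts genes commonly hypomethylated AND commonly
# upregulated across the two simulated lines; the Venn rows satisfy
# unique_a = n_a - shared and union = n_a + n_b - shared exactly.
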