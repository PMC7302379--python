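"""qPCR relative quantification: ddCt expression and ChIP percent input.

Expression: fold = 2^-ddCt relative to a calibrator sample, normalized to
a reference gene. ChIP: percent of (1% diluted) input recovered by the
pulldown, with fold-over-IgG where an IgG control exists.
"""
from episcreen import SimulationConfig, relative_expression, simulate_qpcr
from episcreen.qpcr import chip_table, expression_table

# hand-sized ddCt: target 24 vs ref 20 in test, 26 vs 20 in calibrator
print("worked ddCt fold:", relative_expression(24, 20, 26, 20))  # 4.0

cfg = SimulationConfig(seed=1, de_log2fc=2.0, chip_enrichment=4.0)
ct, _ = simulate_qpcr(["T1"], cfg, assay="expression")
print(expression_table(ct).to_string(index=False))

ct_chip, _ = simulate_qpcr(["P1"], cfg, assay="chip")
chip = chip_table(ct_chip, input_fraction=cfg.chip_input_fraction)
print(chip.to_string(index=False))
ratio = (chip.set_index("sample").loc["knockdown", "percent_input"]
         / chip.set_index("sample").loc["control", "percent_input"])
print(f"knockdown/control percent-input ratio: {ratio:.2f} (dis-enriched)")
# The planted 4-fold H3K9me2 enrichment at the control promoter vanishes
# after knockdown: the ratio is ~0.25.
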