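"""Relative quantification from qPCR Ct tables.

Expression assays use the delta-delta-Ct method: the target Ct is
normalized to an internal reference gene within each sample, and the test
sample is expressed relative to a calibrator, fold = 2^-ddCt. ChIP-qPCR
enrichment is reported as percent of input (the primary readout), with
fold-over-IgG when an IgG control was run; group comparisons report the
knockdown/control ratio of mean percent input and label a ratio < 1 as
dis-enriched.

Replicate Cts are averaged arithmetically before any transformation; the
reported spread is a delta-method approximation (ln2 * SD(Ct) relative
error), labeled approximate in the output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

LN2 = math.log(2.0)


def relative_expression(ct_target_test: float, ct_ref_test: float,
                        ct_target_cal: float, ct_ref_cal: float) -> float:
    """Fold change by delta-delta Ct: 2^-((t_t - r_t) - (t_c - r_c))."""
    for v in (ct_target_test, ct_ref_test, ct_target_cal, ct_ref_cal):
        if v is None or np.isnan(v):
            raise ValueError("all four Ct values are required")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_cal - ct_ref_cal)
    return 2.0 ** (-ddct)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 0.01) -> float:
    """ChIP enrichment as percent of input chromatin.

    The input Ct is first adjusted for its dilution (input_fraction of the
    chromatin), then %input = 100 * 2^(adjusted input Ct - IP Ct).
    """
    if input_fraction <= 0 or input_fraction > 1:
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def fold_over_igg(ct_ip: float, ct_igg: float) -> float:
    """Enrichment of the specific antibody over the IgG background."""
    return 2.0 ** (ct_igg - ct_ip)


@dataclass
class EnrichmentResult:
    """ChIP-qPCR enrichment for one (sample, target)."""

    sample: str
    target: str
    percent_input: float
    fold_over_igg: float | None = None
    percent_input_sd: float | None = None  # delta-method, approximate


def expression_table(ct_table: pd.DataFrame, reference_gene: str = "REF",
                     calibrator_sample: str | None = None) -> pd.DataFrame:
    """Per-(sample, target) fold changes from a long-format Ct table.

    Expected columns: sample, target, role, replicate, ct; only rows with
    role == 'expression' are used. The calibrator defaults to the first
    sample in table order. Replicates are averaged first; the reported
    ``fold_sd`` is the delta-method propagation of the replicate Ct SDs.
    """
    expr = ct_table[ct_table["role"] == "expression"]
    if expr.empty:
        raise ValueError("no expression rows in Ct table")
    mean_ct = expr.groupby(["sample", "target"])["ct"].mean()
    sd_ct = expr.groupby(["sample", "target"])["ct"].std().fillna(0.0)
    samples = list(dict.fromkeys(expr["sample"]))
    calibrator = calibrator_sample or samples[0]
    targets = [t for t in dict.fromkeys(expr["target"]) if t != reference_gene]
    if reference_gene not in set(expr["target"]):
        raise ValueError(f"reference gene {reference_gene!r} missing from table")

    rows = []
    for sample in samples:
        for target in targets:
            fold = relative_expression(
                mean_ct[(sample, target)], mean_ct[(sample, reference_gene)],
                mean_ct[(calibrator, target)], mean_ct[(calibrator, reference_gene)])
            var = (sd_ct[(sample, target)] ** 2 + sd_ct[(sample, reference_gene)] ** 2)
            rows.append((sample, target, fold, fold * LN2 * math.sqrt(var)))
    return pd.DataFrame(rows, columns=["sample", "target", "fold", "fold_sd"])


def chip_table(ct_table: pd.DataFrame, input_fraction: float = 0.01) -> pd.DataFrame:
    """Percent input (and fold over IgG where available) per sample/target.

    The default 1% input dilution is a convention; it is echoed in the
    output so downstream readers see which fraction was assumed.
    """
    rows = []
    for (sample, target), grp in ct_table.groupby(["sample", "target"], sort=False):
        by_role = grp.groupby("role")["ct"]
        mean = by_role.mean()
        sd = by_role.std().fillna(0.0)
        if "IP" not in mean.index or "input" not in mean.index:
            continue
        pi = percent_input(mean["IP"], mean["input"], input_fraction)
        pi_sd = pi * LN2 * math.sqrt(sd["IP"] ** 2 + sd["input"] ** 2)
        foi = fold_over_igg(mean["IP"], mean["IgG"]) if "IgG" in mean.index else np.nan
        rows.append((sample, target, pi, pi_sd, foi, input_fraction))
    if not rows:
        raise ValueError("no (IP, input) pairs found in Ct table")
    return pd.DataFrame(rows, columns=["sample", "target", "percent_input",
                                       "percent_input_sd_approx",
                                       "fold_over_igg", "input_fraction"])


def compare_enrichment(group_ctrl: list[EnrichmentResult],
                       group_kd: list[EnrichmentResult]) -> tuple[float, str | None]:
    """Knockdown/control ratio of mean percent input.

    Returns ``(ratio, label)`` with label 'dis-enriched' when the
    knockdown group lost enrichment (ratio < 1), 'enriched' when it gained
    (> 1), and None at exact parity.
    """
    if not group_ctrl or not group_kd:
        raise ValueError("both groups must be non-empty")
    mean_ctrl = float(np.mean([r.percent_input for r in group_ctrl]))
    mean_kd = float(np.mean([r.percent_input for r in group_kd]))
    ratio = mean_kd / mean_ctrl
    if ratio < 1.0:
        return ratio, "dis-enriched"
    if ratio > 1.0:
        return ratio, "enriched"
    return ratio, None
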