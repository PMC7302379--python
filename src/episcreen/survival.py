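"""Kaplan-Meier estimation and log-rank comparison of expression groups.

Patients are split into high and low groups on a single gene's expression
or on a combined multi-gene score (the unweighted mean of per-gene values,
by default after per-gene z-scaling since cross-gene scales differ), at
the median or a quartile cut. Patients exactly at the cut go to the low
group. Curves are product-limit estimates and groups are compared with
the one-degree-of-freedom log-rank test; both are computed with lifelines.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

CUTS = ("median", "lower-quartile", "upper-quartile")


@dataclass
class KMCurve:
    """Step-function survival estimate: S(0) = 1, non-increasing, steps at
    event times only."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def expression_score(table: pd.DataFrame, genes: str | list[str],
                     zscale: bool = True) -> pd.Series:
    """Single-gene expression, or the mean across a gene set (combined
    signature); ``zscale`` standardizes each gene before averaging."""
    if isinstance(genes, str):
        genes = [genes]
    missing = [g for g in genes if g not in table.columns]
    if missing:
        raise KeyError(f"genes absent from table: {missing}")
    expr = table[genes].astype(float)
    if zscale and len(genes) > 1:
        expr = (expr - expr.mean()) / expr.std(ddof=0).replace(0.0, 1.0)
    return expr.mean(axis=1)


def split_by_expression(table: pd.DataFrame, genes: str | list[str],
                        cut: str = "median", zscale: bool = True
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split patients into (low, high) groups at the chosen expression cut.

    high = score > cut, low = score <= cut (ties go low). Raises when a
    group would be empty or smaller than 2 patients.
    """
    if cut not in CUTS:
        raise ValueError(f"cut must be one of {CUTS}")
    score = expression_score(table, genes, zscale=zscale)
    q = {"median": 0.5, "lower-quartile": 0.25, "upper-quartile": 0.75}[cut]
    threshold = score.quantile(q)
    low = table[score <= threshold]
    high = table[score > threshold]
    if len(low) < 2 or len(high) < 2:
        raise ValueError(
            f"degenerate split at {cut}: {len(low)} low vs {len(high)} high")
    return low, high


def km_estimate(group: pd.DataFrame) -> KMCurve:
    """Product-limit survival estimate for one patient group."""
    if group.empty:
        raise ValueError("group is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(group["time"], group["event"])
    event_table = kmf.event_table
    observed = event_table[event_table["observed"] > 0]
    times = observed.index.to_numpy(dtype=float)
    at_risk = observed["at_risk"].to_numpy(dtype=int)
    surv = np.array([kmf.survival_function_at_times(t).iloc[0] for t in times])
    return KMCurve(times, at_risk, surv)


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Log-rank chi-square (1 df) and p-value for two patient groups.

    With no events in either group the comparison is vacuous: returns
    (0, 1) with a warning.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be non-empty")
    if group_a["event"].sum() == 0 and group_b["event"].sum() == 0:
        warnings.warn("no events in either group; log-rank undefined, p = 1")
        return 0.0, 1.0
    res = logrank_test(group_a["time"], group_b["time"],
                       event_observed_A=group_a["event"],
                       event_observed_B=group_b["event"])
    return float(res.test_statistic), float(res.p_value)


def km_analysis(table: pd.DataFrame, genes: str | list[str],
                cut: str = "median", zscale: bool = True) -> dict[str, object]:
    """Split, estimate both curves and test; the one-call convenience."""
    low, high = split_by_expression(table, genes, cut=cut, zscale=zscale)
    chi2, p = logrank(low, high)
    return {
        "low": km_estimate(low),
        "high": km_estimate(high),
        "n_low": len(low),
        "n_high": len(high),
        "chi_square": chi2,
        "p_value": p,
    }
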