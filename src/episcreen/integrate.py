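"""Cross-line set arithmetic and inverse-correlation candidate selection.

The screen produces per-line hypo-/hyper-methylated gene sets and the DE
stage per-line up-/down-regulated sets. This module intersects them across
cell lines (the Venn arithmetic of the study design), takes the genes both
commonly hypomethylated and commonly upregulated as inverse-correlation
candidates, and ranks a shortlist numerically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VennCounts:
    """Two-set Venn category sizes with derived identities."""

    n_a: int
    n_b: int
    n_shared: int

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_a, self.n_b):
            raise ValueError("shared count exceeds a set size")

    @property
    def unique_a(self) -> int:
        return self.n_a - self.n_shared

    @property
    def unique_b(self) -> int:
        return self.n_b - self.n_shared

    @property
    def union(self) -> int:
        return self.n_a + self.n_b - self.n_shared

    @classmethod
    def from_sets(cls, a: set[str], b: set[str]) -> "VennCounts":
        return cls(len(a), len(b), len(a & b))


def intersect_lines(set_line1: set[str], set_line2: set[str]
                    ) -> tuple[set[str], set[str], set[str]]:
    """Partition two gene sets into (shared, unique-to-1, unique-to-2)."""
    a = {str(g).upper() for g in set_line1}
    b = {str(g).upper() for g in set_line2}
    shared = a & b
    return shared, a - shared, b - shared


def inverse_correlation_candidates(hypo_common: set[str], up_common: set[str],
                                   delta_beta: dict[str, dict[str, float]] | None = None,
                                   log2fc: dict[str, dict[str, float]] | None = None
                                   ) -> pd.DataFrame:
    """Genes both commonly hypomethylated and commonly upregulated.

    ``delta_beta`` / ``log2fc`` are optional per-line annotation maps
    ``{line: {gene: value}}``; missing annotations become NaN. The result
    is symmetric in its two set arguments.
    """
    genes = sorted({str(g).upper() for g in hypo_common}
                   & {str(g).upper() for g in up_common})
    out = pd.DataFrame({"gene_id": genes})
    for name, ann in (("delta_beta", delta_beta), ("log2fc", log2fc)):
        for line in sorted(ann or {}):
            out[f"{name}_{line}"] = [ann[line].get(g, np.nan) for g in genes]
    return out


def rank_candidates(table: pd.DataFrame, fc_top_min: float = 2.5,
                    shortlist: int | None = 6) -> pd.DataFrame:
    """Numeric shortlist of annotated candidates.

    Keeps candidates whose fold change reaches ``fc_top_min`` in every
    line, then orders by descending mean delta-beta, then descending mean
    |log2FC|, with a stable alphabetical tie-break on gene ID.
    """
    if table.empty:
        return table.copy()
    fc_cols = [c for c in table.columns if c.startswith("log2fc_")]
    db_cols = [c for c in table.columns if c.startswith("delta_beta_")]
    out = table.copy()
    if fc_cols:
        min_fc = (2.0 ** out[fc_cols]).min(axis=1)
        out = out[min_fc >= fc_top_min].copy()
    out["_db"] = out[db_cols].mean(axis=1) if db_cols else 0.0
    out["_fc"] = out[fc_cols].abs().mean(axis=1) if fc_cols else 0.0
    out = out.sort_values(["_db", "_fc", "gene_id"],
                          ascending=[False, False, True], kind="stable")
    out = out.drop(columns=["_db", "_fc"]).reset_index(drop=True)
    if shortlist is not None:
        out = out.head(shortlist)
    return out


def venn_report(categories: dict[str, tuple[set[str], set[str]]]) -> pd.DataFrame:
    """Tabulate VennCounts per category ('hypo', 'hyper', 'up', 'down')."""
    rows = []
    for name, (a, b) in categories.items():
        v = VennCounts.from_sets(set(a), set(b))
        rows.append((name, v.n_a, v.n_b, v.n_shared, v.unique_a, v.unique_b, v.union))
    return pd.DataFrame(rows, columns=["category", "n_a", "n_b", "shared",
                                       "unique_a", "unique_b", "union"])
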