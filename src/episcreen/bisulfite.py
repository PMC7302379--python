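"""Methylation calling from clonal bisulfite-sequencing reads.

At each CpG of an unconverted reference amplicon, a read showing ``CG`` is
called methylated and ``TG`` unmethylated; anything else is ambiguous and
excluded from both counts. The methylation index (MI) of a read group is
the number of methylated calls over the total unambiguous calls, and
groups are compared with a two-sided Fisher's exact test on the
(methylated, unmethylated) x (group1, group2) table.

Synthetic reads are co-linear with the reference; real Sanger-derived
reads of different length are aligned end-to-end by edit distance (no
affine gaps) and CpG positions lifted through the alignment, with
indel-overlapping CpGs called ambiguous.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

METHYLATED, UNMETHYLATED, AMBIGUOUS = "M", "U", "."


@dataclass(frozen=True)
class ReferenceRegion:
    """Unconverted reference amplicon with 1-based CpG cytosine positions."""

    id: str
    sequence: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if re.search(r"[^ACGT]", seq):
            raise ValueError("reference sequence must be A/C/G/T only")
        for pos in self.cpg_positions:
            if not 1 <= pos < len(seq) or seq[pos - 1:pos + 1] != "CG":
                raise ValueError(f"position {pos} is not the C of a CpG")

    @classmethod
    def from_sequence(cls, region_id: str, sequence: str,
                      cpg_positions: list[int] | None = None) -> "ReferenceRegion":
        """Build a region; CpG positions are auto-detected when omitted."""
        seq = sequence.upper()
        if cpg_positions is None:
            cpg_positions = [m.start() + 1 for m in re.finditer("CG", seq)]
        return cls(region_id, seq, tuple(cpg_positions))


@dataclass
class MIResult:
    """Methylation index of one read group."""

    group: str
    n_methylated: int
    n_total: int

    @property
    def mi(self) -> float:
        return self.n_methylated / self.n_total

    @property
    def n_unmethylated(self) -> int:
        return self.n_total - self.n_methylated


def call_cpg_states(read: str, region: ReferenceRegion,
                    max_length_diff: int = 20) -> list[str]:
    """Per-CpG calls (M/U/ambiguous) for one read against the region.

    Equal-length reads are compared position by position; reads of a
    different length (within ``max_length_diff``) are aligned end-to-end by
    edit distance first. Longer mismatches reject the read.
    """
    read = read.upper()
    if len(read) == len(region.sequence):
        pairs = {p: read[p - 1:p + 1] for p in region.cpg_positions}
    elif abs(len(read) - len(region.sequence)) <= max_length_diff:
        pairs = _aligned_cpg_dinucleotides(read, region)
    else:
        raise ValueError(
            f"read length {len(read)} differs from reference "
            f"{len(region.sequence)} by more than {max_length_diff}")
    calls = []
    for pos in region.cpg_positions:
        dinuc = pairs.get(pos, "")
        if dinuc == "CG":
            calls.append(METHYLATED)
        elif dinuc == "TG":
            calls.append(UNMETHYLATED)
        else:
            calls.append(AMBIGUOUS)
    return calls


def _aligned_cpg_dinucleotides(read: str, region: ReferenceRegion) -> dict[int, str]:
    """Lift reference CpG positions through a global edit-distance alignment.

    Indel-overlapping CpGs yield no dinucleotide (ambiguous downstream).
    """
    import edlib

    aln = edlib.align(read, region.sequence, mode="NW", task="path")
    ref_to_read: dict[int, int | None] = {}
    ri = qi = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", aln["cigar"]):
        n = int(n)
        if op in "=XM":
            for _ in range(n):
                ref_to_read[ri] = qi
                ri += 1
                qi += 1
        elif op == "D":  # deletion from the read: reference bases unmatched
            for _ in range(n):
                ref_to_read[ri] = None
                ri += 1
        else:  # insertion in the read
            qi += n
    out = {}
    for pos in region.cpg_positions:
        c_idx = ref_to_read.get(pos - 1)
        g_idx = ref_to_read.get(pos)
        if c_idx is None or g_idx is None or g_idx != c_idx + 1:
            continue
        out[pos] = read[c_idx:g_idx + 1]
    return out


def call_matrix(reads: list[str], region: ReferenceRegion,
                names: list[str] | None = None) -> pd.DataFrame:
    """Reads x CpG matrix of M/U/. calls (the lollipop-plot matrix)."""
    names = names or [f"read{i + 1}" for i in range(len(reads))]
    rows = [call_cpg_states(r, region) for r in reads]
    cols = [f"CpG_{p}" for p in region.cpg_positions]
    return pd.DataFrame(rows, index=names, columns=cols)


def methylation_index(calls: pd.DataFrame, group: str = "") -> MIResult:
    """MI = methylated calls / total unambiguous calls, over all reads."""
    vals = calls.to_numpy()
    n_meth = int((vals == METHYLATED).sum())
    n_unmeth = int((vals == UNMETHYLATED).sum())
    total = n_meth + n_unmeth
    if total == 0:
        raise ValueError("no unambiguous CpG calls")
    return MIResult(group, n_meth, total)


def compare_mi(group1: MIResult, group2: MIResult) -> float:
    """Two-sided Fisher's exact p for the 2x2 methylated/unmethylated table.

    Two-sidedness follows the standard convention: the sum of all table
    probabilities not exceeding the observed table's hypergeometric
    probability.
    """
    if group1.n_total == 0 or group2.n_total == 0:
        raise ValueError("both groups need unambiguous calls")
    table = [[group1.n_methylated, group2.n_methylated],
             [group1.n_unmethylated, group2.n_unmethylated]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def conversion_qc(reads: list[str], region: ReferenceRegion) -> float:
    """Fraction of non-CpG reference cytosines retained as C across reads.

    A high retention rate signals incomplete bisulfite conversion; the
    rate is reported alongside MI comparisons as a QC metric.
    """
    non_cpg_c = [i for i, base in enumerate(region.sequence)
                 if base == "C" and (i + 1) not in region.cpg_positions]
    if not non_cpg_c:
        return float("nan")
    retained = total = 0
    for read in reads:
        if len(read) != len(region.sequence):
            continue
        for i in non_cpg_c:
            total += 1
            retained += read[i] == "C"
    return retained / total if total else float("nan")
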