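"""Readers and writers for the pipeline's plain-text formats.

Conventions: TSV for matrices (probe/gene ID in the first column, one
column per sample), CSV for Ct and survival tables, FASTA for reads, one
gene per line for gene-set files. Coordinates are 1-based in manifests;
writers prepend ``# seed=N`` provenance headers which readers skip.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import BetaMatrix, CountMatrix, GroundTruth, ReadSet

_EPIC_COLUMNS = {"IlmnID": "probe_id", "CHR": "chrom", "MAPINFO": "pos",
                 "UCSC_RefGene_Name": "gene"}


def _header(seed: int | None) -> str:
    return f"# seed={seed}\n" if seed is not None else ""


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------------------
# beta matrix + manifest

def write_beta_tsv(matrix: BetaMatrix, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        matrix.values.to_csv(fh, sep="\t", float_format="%.6f")


def read_beta_tsv(path: str | Path, samples: pd.DataFrame | None = None) -> BetaMatrix:
    """Read a beta TSV; sample roles are parsed from ``<line>_<role>``
    column names unless an explicit sample sheet is given."""
    values = _read_table(path, "\t").set_index("probe_id")
    if samples is None:
        rows = []
        for name in values.columns:
            line, _, role = name.rpartition("_")
            kind = "control" if role.startswith("control") else "knockdown"
            rows.append((name, line, kind, role))
        samples = pd.DataFrame(rows, columns=["sample", "line", "role", "replicate"])
    return BetaMatrix(values, samples)


def write_manifest_tsv(manifest: pd.DataFrame, path: str | Path,
                       seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        manifest.to_csv(fh, sep="\t", index=False)


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest; accepts the native columns or the minimal
    EPIC-manifest subset (IlmnID, CHR, MAPINFO, UCSC_RefGene_Name with
    semicolon-separated gene lists)."""
    df = _read_table(path, "\t")
    if "IlmnID" in df.columns:
        df = df.rename(columns=_EPIC_COLUMNS)[list(_EPIC_COLUMNS.values())]
        df["region"] = "unknown"
    required = {"probe_id", "chrom", "pos", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    if "region" not in df.columns:
        df["region"] = "unknown"
    return df


# ---------------------------------------------------------------------------
# counts

def write_counts_tsv(cm: CountMatrix, path: str | Path, seed: int | None = None) -> None:
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        out.to_csv(fh, sep="\t")


def read_counts_tsv(path: str | Path, samples: pd.DataFrame | None = None) -> CountMatrix:
    df = _read_table(path, "\t").set_index("gene_id")
    lengths = df.pop("length_bp")
    if samples is None:
        rows = []
        for name in df.columns:
            line, _, role = name.rpartition("_")
            kind = "control" if role.startswith("control") else "knockdown"
            rows.append((name, line, kind, role))
        samples = pd.DataFrame(rows, columns=["sample", "line", "role", "replicate"])
    return CountMatrix(df.astype(np.int64), lengths, samples)


# ---------------------------------------------------------------------------
# reads / regions

def write_reads_fasta(reads: ReadSet, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=n, description="")
               for n, s in zip(reads.names, reads.sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_region_fasta(region, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    desc = "cpg_positions=" + ",".join(map(str, region.cpg_positions))
    SeqIO.write([SeqRecord(Seq(region.sequence), id=region.id, description=desc)],
                str(path), "fasta")


def read_region_fasta(path: str | Path):
    """Read a reference region; CpG positions come from a
    ``cpg_positions=`` tag in the description or are auto-detected."""
    from Bio import SeqIO

    from .bisulfite import ReferenceRegion

    rec = next(SeqIO.parse(str(path), "fasta"))
    positions = None
    for token in rec.description.split():
        if token.startswith("cpg_positions="):
            positions = [int(x) for x in token.split("=", 1)[1].split(",") if x]
    return ReferenceRegion.from_sequence(rec.id, str(rec.seq), positions)


# ---------------------------------------------------------------------------
# small tables

def write_csv(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, index=False)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ",")
    required = {"sample", "target", "role", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    return df


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ",")
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table lacks columns: {sorted(missing)}")
    return df


def write_gene_set(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_set(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")}


def write_ground_truth(truth: GroundTruth, path: str | Path, seed: int | None = None) -> None:
    """Key-value sidecar: one ``key<TAB>comma-separated values`` per line."""
    lines = [_header(seed).rstrip()] if seed is not None else []
    for attr in ("hypo_cpgs", "hyper_cpgs", "hypo_genes", "hyper_genes",
                 "de_up_genes", "de_down_genes"):
        for line_name, items in getattr(truth, attr).items():
            lines.append(f"{attr}.{line_name}\t" + ",".join(sorted(items)))
    if truth.mi_true is not None:
        lines.append(f"mi_true\t{truth.mi_true}")
    if truth.enrichment_true:
        for k, v in truth.enrichment_true.items():
            lines.append(f"enrichment_true.{k}\t{v}")
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))
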