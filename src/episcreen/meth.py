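"""Differential-methylation screen on array beta values.

A CpG is methylated when its beta value reaches the methylation threshold
(default 0.35, boundary inclusive). After knockdown, a CpG is called

* ``hypo``  when the control beta is methylated (>= threshold), the mean
  knockdown beta is unmethylated (< threshold), and the drop
  (control - knockdown mean) reaches ``delta_beta_min`` (default 0.15);
* ``hyper`` under the mirrored conditions;
* ``none``  otherwise, including whenever any input beta is missing.

Probe-level calls are aggregated to genes through the probe manifest; a
gene enters the hypo (hyper) set when at least one supporting probe has
that verdict and no probe has the opposite verdict — genes with
conflicting probes are excluded and reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import pdist

from .config import ScreenParams
from .simulate import BetaMatrix

VERDICTS = ("hypo", "hyper", "none")


@dataclass(frozen=True)
class DifferentialCall:
    """Per-CpG verdict with the betas that produced it."""

    probe_id: str
    beta_control: float
    beta_kd_mean: float
    delta_beta: float  # beta_control - beta_kd_mean
    verdict: str
    missing: bool = False


@dataclass
class GeneCallSet:
    """Gene-level hypo/hyper sets for one cell line."""

    line: str
    hypo_genes: set[str]
    hyper_genes: set[str]
    supporting_probes: dict[str, list[str]] = field(default_factory=dict)
    conflicted_genes: set[str] = field(default_factory=set)


def classify_probe(beta: float, params: ScreenParams = ScreenParams()) -> str | None:
    """Classify one beta value as ``"methylated"`` / ``"unmethylated"``.

    Returns None for a missing beta (excluded downstream). The boundary is
    methylated at exactly the threshold.
    """
    if beta is None or (isinstance(beta, float) and np.isnan(beta)):
        return None
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta value {beta} outside [0, 1]")
    return "methylated" if beta >= params.beta_meth_threshold else "unmethylated"


def call_differential_cpg(beta_control: float, beta_kds: list[float],
                          params: ScreenParams = ScreenParams(),
                          probe_id: str = "") -> DifferentialCall:
    """Call one CpG from its control beta and knockdown replicate betas."""
    if len(beta_kds) == 0:
        raise ValueError("beta_kds must be non-empty")
    vals = [beta_control, *beta_kds]
    if any(v is None or np.isnan(v) for v in vals):
        return DifferentialCall(probe_id, np.nan, np.nan, np.nan, "none", missing=True)
    if any(not 0.0 <= v <= 1.0 for v in vals):
        raise ValueError("beta values must lie in [0, 1]")
    kd_mean = float(np.mean(beta_kds))
    delta = beta_control - kd_mean
    t = params.beta_meth_threshold
    if beta_control >= t and kd_mean < t and delta >= params.delta_beta_min:
        verdict = "hypo"
    elif beta_control < t and kd_mean >= t and -delta >= params.delta_beta_min:
        verdict = "hyper"
    else:
        verdict = "none"
    return DifferentialCall(probe_id, beta_control, kd_mean, delta, verdict)


def screen_line(matrix: BetaMatrix, line: str,
                params: ScreenParams = ScreenParams()) -> pd.DataFrame:
    """Vectorized differential calls for every probe of one cell line.

    Controls are averaged if there are several; knockdown replicates are
    averaged per the screen definition. Returns a frame with columns
    probe_id, beta_control, beta_kd_mean, delta_beta, verdict, missing.
    """
    info = matrix.line_samples(line)
    ctrl_cols = info.loc[info["role"] == "control", "sample"].tolist()
    kd_cols = info.loc[info["role"] == "knockdown", "sample"].tolist()
    if not ctrl_cols or not kd_cols:
        raise ValueError(f"line {line!r} lacks control or knockdown samples")
    ctrl = matrix.values[ctrl_cols].mean(axis=1, skipna=False).to_numpy()
    kd = matrix.values[kd_cols].mean(axis=1, skipna=False).to_numpy()
    missing = np.isnan(ctrl) | np.isnan(kd)
    delta = ctrl - kd
    t = params.beta_meth_threshold
    hypo = (ctrl >= t) & (kd < t) & (delta >= params.delta_beta_min)
    hyper = (ctrl < t) & (kd >= t) & (-delta >= params.delta_beta_min)
    verdict = np.where(missing, "none", np.where(hypo, "hypo",
                       np.where(hyper, "hyper", "none")))
    return pd.DataFrame({
        "probe_id": matrix.values.index,
        "beta_control": np.where(missing, np.nan, ctrl),
        "beta_kd_mean": np.where(missing, np.nan, kd),
        "delta_beta": np.where(missing, np.nan, delta),
        "verdict": verdict,
        "missing": missing,
    })


def aggregate_to_genes(calls: pd.DataFrame, manifest: pd.DataFrame,
                       line: str) -> GeneCallSet:
    """Aggregate probe verdicts to gene-level hypo/hyper sets.

    ``calls`` is the frame from :func:`screen_line` (or equivalent rows of
    :class:`DifferentialCall` fields). A probe mapping to several genes
    (semicolon-separated in the manifest) contributes to each of them.
    Raises if a called probe is absent from the manifest.
    """
    probe_to_genes = manifest.set_index("probe_id")["gene"]
    unknown = set(calls["probe_id"]) - set(probe_to_genes.index)
    if unknown:
        raise KeyError(f"probes missing from manifest: {sorted(unknown)[:10]}")

    votes: dict[str, dict[str, list[str]]] = {}
    for probe, verdict in zip(calls["probe_id"], calls["verdict"]):
        if verdict == "none":
            continue
        for gene in str(probe_to_genes[probe]).split(";"):
            gene = gene.strip()
            if gene:
                votes.setdefault(gene, {"hypo": [], "hyper": []})[verdict].append(probe)

    hypo, hyper, conflicts, support = set(), set(), set(), {}
    for gene, v in votes.items():
        if v["hypo"] and v["hyper"]:
            conflicts.add(gene)
        elif v["hypo"]:
            hypo.add(gene)
            support[gene] = v["hypo"]
        else:
            hyper.add(gene)
            support[gene] = v["hyper"]
    return GeneCallSet(line, hypo, hyper, support, conflicts)


def screen_gene_sets(matrix: BetaMatrix, manifest: pd.DataFrame,
                     params: ScreenParams = ScreenParams(),
                     promoter_only: bool = False) -> dict[str, GeneCallSet]:
    """Run the screen for every cell line; optionally restrict to promoter
    probes (region == 'promoter' in the manifest; off by default)."""
    use = manifest
    if promoter_only:
        use = manifest[manifest["region"] == "promoter"]
    keep = matrix.values.index.isin(use["probe_id"])
    sub = BetaMatrix(matrix.values.loc[keep], matrix.samples)
    return {line: aggregate_to_genes(screen_line(sub, line, params), use, line)
            for line in matrix.lines}


def cluster_probes(matrix: BetaMatrix, linkage: str = "average",
                   metric: str = "correlation") -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """QC hierarchical clustering of probes across samples.

    Defaults follow the Cluster 3.0 convention: average linkage on
    1 - Pearson correlation distance. Probes with missing values are
    dropped; under the correlation metric, constant rows (undefined
    correlation) are excluded with a warning. Returns ``(Z, leaf_order,
    kept_probe_ids)`` where ``Z`` is a scipy linkage matrix.
    """
    vals = matrix.values.dropna(axis=0)
    if metric == "correlation":
        const = vals.std(axis=1, ddof=0) == 0
        if const.any():
            warnings.warn(f"excluding {int(const.sum())} constant probe rows "
                          "from correlation clustering")
            vals = vals.loc[~const]
    if len(vals) < 2:
        raise ValueError("need at least 2 probes with complete values")
    dist = pdist(vals.to_numpy(), metric=metric)
    Z = _scipy_linkage(dist, method=linkage)
    return Z, leaves_list(Z), vals.index
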