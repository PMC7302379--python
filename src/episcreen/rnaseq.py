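"""Differential expression on gene-level count matrices.

Normalization uses the trimmed mean of M-values (TMM): for each sample
against a reference, gene-wise log ratios M and average abundances A are
computed on library-size-scaled counts, the extremes are trimmed (30% of
the M distribution, 5% of the A distribution, each side), and the scale
factor is the 2^(weighted mean of the surviving M values), with
inverse-asymptotic-variance (delta-method binomial) weights. Factors are
rescaled so their geometric mean over samples is one.

Testing uses a conditional negative-binomial exact test: the two group
sums (after scaling counts to a common effective library size) are NB with
size n_g/phi, and the two-sided p-value is the total conditional
probability of all splits of the observed total as or less likely than the
observed one. With dispersion 0 this degrades to the exact binomial
(Poisson) case. A fixed dispersion (default 0.16, i.e. a biological CV of
0.4) suits single-control designs; with replicates in both arms a common
dispersion can be estimated by conditional maximum likelihood.

The differential filter is: RPKM >= 1 in at least one sample, fold change
>= 2 on the normalized scale, and p <= 0.05, with direction from the sign
of the log2 fold change.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import binom, nbinom, rankdata

from .config import DEParams
from .simulate import CountMatrix

DEFAULT_DISPERSION = 0.16


# ---------------------------------------------------------------------------
# TMM

def _quantile_rate(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array([np.quantile(counts[:, j], p) for j in range(counts.shape[1])]) / lib


def tmm_factors(counts: pd.DataFrame | np.ndarray,
                lib_sizes: np.ndarray | None = None,
                reference: int | str | None = None,
                logratio_trim: float = 0.3,
                abundance_trim: float = 0.05,
                weighted: bool = True) -> np.ndarray:
    """TMM normalization factors, one per sample column.

    ``reference=None`` picks the sample whose upper-quartile count rate is
    closest to the mean of all samples' rates. The returned factors have
    geometric mean 1; effective library size = library size x factor.
    """
    if isinstance(counts, pd.DataFrame):
        columns = list(counts.columns)
        mat = counts.to_numpy(dtype=float)
    else:
        mat = np.asarray(counts, dtype=float)
        columns = list(range(mat.shape[1]))
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = mat.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    if reference is None:
        f75 = _quantile_rate(mat, lib)
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    elif isinstance(reference, str):
        ref = columns.index(reference)
    else:
        ref = int(reference)

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        factors[j] = _pair_tmm(mat[:, j], mat[:, ref], lib[j], lib[ref],
                               logratio_trim, abundance_trim, weighted)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _pair_tmm(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, abundance_trim: float, weighted: bool) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0:
        raise ValueError("no genes expressed in both sample and reference")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abundance_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    trimmed = ((rank_r >= lo_l) & (rank_r <= hi_l)
               & (rank_e >= lo_s) & (rank_e <= hi_s))
    if not trimmed.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
    else:
        f = np.mean(log_r[trimmed])
    return float(2.0 ** f)


# ---------------------------------------------------------------------------
# RPKM

def rpkm(counts: pd.DataFrame, lengths: pd.Series,
         lib_sizes: np.ndarray | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, from raw counts."""
    lib = counts.sum(axis=0).to_numpy(dtype=float) if lib_sizes is None \
        else np.asarray(lib_sizes, float)
    if (lib <= 0).any():
        raise ValueError("library size must be positive for RPKM")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    return counts / (kb * lib[None, :] / 1e6)


# ---------------------------------------------------------------------------
# exact test

def nb_exact_pvalue_sums(s1: int, s2: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided conditional exact p for group sums at equal library sizes.

    Conditions on s = s1 + s2; under the null both groups share a
    per-sample mean mu = s/(n1+n2), group sums are NB(size n_g/phi, mean
    n_g*mu), and the p-value sums the probabilities of every split of s as
    or less probable than the observed one.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    s = int(s1) + int(s2)
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    if dispersion == 0:
        logp = binom.logpmf(x, s, n1 / (n1 + n2))
    else:
        mu = s / (n1 + n2)
        r1, r2 = n1 / dispersion, n2 / dispersion
        logp = (nbinom.logpmf(x, r1, r1 / (r1 + n1 * mu))
                + nbinom.logpmf(s - x, r2, r2 / (r2 + n2 * mu)))
    logp -= logp.max()
    prob = np.exp(logp)
    obs = prob[int(s1)]
    return float(prob[prob <= obs * (1.0 + 1e-10)].sum() / prob.sum())


def nb_exact_test(gene_counts_ctrl: list[float], gene_counts_kd: list[float],
                  lib_factors: np.ndarray | None = None,
                  dispersion: float = DEFAULT_DISPERSION) -> float:
    """Exact NB test for one gene, scaling counts to a common library size.

    ``lib_factors`` are per-sample effective library sizes (or relative
    factors), control samples first then knockdown, matching the count
    order; counts are linearly rescaled to the geometric-mean library and
    rounded before the conditional test.
    """
    ctrl = np.asarray(gene_counts_ctrl, dtype=float)
    kd = np.asarray(gene_counts_kd, dtype=float)
    if ctrl.size == 0 or kd.size == 0:
        raise ValueError("both groups must be non-empty")
    if lib_factors is not None:
        f = np.asarray(lib_factors, dtype=float)
        if f.size != ctrl.size + kd.size:
            raise ValueError("lib_factors length must equal total sample count")
        common = np.exp(np.mean(np.log(f)))
        scale = common / f
        ctrl = np.rint(ctrl * scale[:ctrl.size])
        kd = np.rint(kd * scale[ctrl.size:])
    return nb_exact_pvalue_sums(int(ctrl.sum()), int(kd.sum()),
                                ctrl.size, kd.size, dispersion)


def estimate_common_dispersion(counts: np.ndarray, groups: np.ndarray) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Requires at least one group with >= 2 samples; the conditional
    likelihood of the within-group counts given their sum is free of the
    gene means (equal library sizes assumed — pass pre-equalized counts).
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    reps = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    reps = [idx for idx in reps if idx.size >= 2]
    if not reps:
        raise ValueError("dispersion estimation needs replicates in a group")

    def neg_cll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        total = 0.0
        for idx in reps:
            y = np.rint(counts[:, idx])
            s = y.sum(axis=1)
            n = idx.size
            total += np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)).item()
            total -= np.sum(gammaln(s + n * r) - gammaln(n * r) - gammaln(s + 1)).item()
        return -total

    res = minimize_scalar(neg_cll, bounds=(np.log(1e-4), np.log(10.0)),
                          method="bounded")
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# per-line DE analysis

@dataclass
class DEResultTable:
    """Per-gene DE results for one cell line."""

    line: str
    table: pd.DataFrame  # gene_id, max_rpkm, log2fc, p_value, fdr, verdict

    @property
    def up_genes(self) -> set[str]:
        return set(self.table.loc[self.table["verdict"] == "up", "gene_id"])

    @property
    def down_genes(self) -> set[str]:
        return set(self.table.loc[self.table["verdict"] == "down", "gene_id"])


def de_analyze_line(cm: CountMatrix, line: str,
                    params: DEParams = DEParams()) -> DEResultTable:
    """TMM-normalize, test and filter knockdown vs control for one line."""
    info = cm.samples[cm.samples["line"] == line]
    ctrl_cols = info.loc[info["role"] == "control", "sample"].tolist()
    kd_cols = info.loc[info["role"] == "knockdown", "sample"].tolist()
    if not ctrl_cols or not kd_cols:
        raise ValueError(f"line {line!r} lacks control or knockdown samples")
    cols = ctrl_cols + kd_cols
    sub = cm.counts[cols]
    lib = sub.sum(axis=0).to_numpy(dtype=float)
    if (lib == 0).any():
        raise ValueError("a sample has zero library size")
    factors = tmm_factors(sub, lib)
    eff_lib = lib * factors
    common = np.exp(np.mean(np.log(eff_lib)))
    scaled = sub.to_numpy(dtype=float) * (common / eff_lib)[None, :]

    if params.dispersion == "estimate":
        groups = np.array([0] * len(ctrl_cols) + [1] * len(kd_cols))
        if max(len(ctrl_cols), len(kd_cols)) < 2:
            warnings.warn("no replicated arm; falling back to fixed dispersion")
            phi = DEFAULT_DISPERSION
        else:
            phi = estimate_common_dispersion(scaled, groups)
    else:
        phi = float(params.dispersion)

    pseudo = np.rint(scaled)
    n1, n2 = len(ctrl_cols), len(kd_cols)
    s1 = pseudo[:, :n1].sum(axis=1).astype(int)
    s2 = pseudo[:, n1:].sum(axis=1).astype(int)
    pvals = np.array([nb_exact_pvalue_sums(a, b, n1, n2, phi)
                      for a, b in zip(s1, s2)])

    mean_ctrl = scaled[:, :n1].mean(axis=1)
    mean_kd = scaled[:, n1:].mean(axis=1)
    log2fc = np.log2((mean_kd + 0.5) / (mean_ctrl + 0.5))  # prior count 0.5

    sample_rpkm = rpkm(sub, cm.lengths, lib)
    max_rpkm = sample_rpkm.max(axis=1).to_numpy()

    fdr = _bh_fdr(pvals)
    fc = 2.0 ** np.abs(log2fc)
    passing = (max_rpkm >= params.rpkm_min) & (fc >= params.fc_min) & (pvals <= params.p_max)
    verdict = np.where(~passing, "none", np.where(log2fc > 0, "up", "down"))

    table = pd.DataFrame({
        "gene_id": sub.index,
        "max_rpkm": max_rpkm,
        "log2fc": log2fc,
        "p_value": pvals,
        "fdr": fdr,
        "verdict": verdict,
    })
    return DEResultTable(line, table)


def de_filter(table: pd.DataFrame, params: DEParams = DEParams()) -> pd.DataFrame:
    """(Re)apply the triple filter to a DE table, returning a copy with a
    fresh ``verdict`` column. Tightening any threshold can only shrink the
    up/down sets."""
    fc = 2.0 ** table["log2fc"].abs()
    passing = ((table["max_rpkm"] >= params.rpkm_min) & (fc >= params.fc_min)
               & (table["p_value"] <= params.p_max))
    out = table.copy()
    out["verdict"] = np.where(~passing, "none",
                              np.where(table["log2fc"] > 0, "up", "down"))
    return out


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
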