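"""Synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of its arguments and the
:class:`~episcreen.config.SimulationConfig` seed: repeated calls with the
same configuration return bit-identical outputs. Each generator draws from
its own seed stream, so the output of one stage never depends on whether
another stage was run.

The simulated experiment mirrors a shRNA-knockdown design: ``n_cell_lines``
cell lines, each with scrambled-shRNA control sample(s) and independent
knockdown replicates (two shRNA constructs by default), profiled on a
beta-value methylation array and by gene-level RNA-seq counts. Effects are
planted per gene with recorded ground truth so downstream recovery is
measurable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

# seed-stream tags, one per generator
_STREAM_EFFECTS = 2
_STREAM_BETA = 20
_STREAM_COUNTS = 3
_STREAM_READS = 4
_STREAM_QPCR = 5
_STREAM_SURVIVAL = 6


# ---------------------------------------------------------------------------
# containers

@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    ``samples`` carries one row per column of ``values`` with the sample
    name, its cell line, and its role (``control`` or ``knockdown``).
    Missing beta values are NaN.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples["sample"]):
            raise ValueError("sample sheet does not match matrix columns")
        inside = ((self.values >= 0) & (self.values <= 1)) | self.values.isna()
        if not inside.all().all():
            raise ValueError("beta values must lie in [0, 1] or be missing")

    def line_samples(self, line: str) -> pd.DataFrame:
        return self.samples[self.samples["line"] == line]

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.samples["line"]))


@dataclass
class CountMatrix:
    """Gene-level RNA-seq counts with gene lengths and a sample sheet."""

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples["sample"]):
            raise ValueError("sample sheet does not match count columns")
        if not self.lengths.index.equals(self.counts.index):
            raise ValueError("lengths index must match count rows")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.samples["line"]))


@dataclass
class GroundTruth:
    """Planted effects recorded by the generators.

    Gene/probe sets are keyed by cell line; lines share the same planted
    sets (one perturbation applied to both), so cross-line differences in
    the *calls* reflect detection noise only.
    """

    hypo_cpgs: dict[str, frozenset[str]] = field(default_factory=dict)
    hyper_cpgs: dict[str, frozenset[str]] = field(default_factory=dict)
    hypo_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    hyper_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    de_up_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    de_down_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    mi_true: float | None = None
    enrichment_true: dict[str, float] | None = None
    survival_groups: pd.Series | None = None


@dataclass
class ReadSet:
    """Simulated bisulfite reads over one reference region."""

    region_id: str
    names: list[str]
    sequences: list[str]
    truth_methylation: np.ndarray  # reads x CpGs, bool


# ---------------------------------------------------------------------------
# manifest

def gene_ids(config: SimulationConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Probe manifest: ``cpgs_per_gene`` CpG probes per synthetic gene.

    Columns: probe_id, chrom, pos (1-based), gene, region. Positions are
    strictly increasing within a gene; the mapping is 1:1 probe-to-gene.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = gene_ids(config)
    rows = []
    pos = 10_000
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi % 22 + 1}"
        start = pos + gi * 50_000
        offsets = np.sort(rng.choice(np.arange(1, 2000), size=config.cpgs_per_gene,
                                     replace=False))
        for ci, off in enumerate(offsets):
            region = "promoter" if ci < max(1, config.cpgs_per_gene // 2) else "body"
            rows.append((f"cg{gi:05d}{ci:02d}", chrom, int(start + off), gene, region))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene", "region"])


# ---------------------------------------------------------------------------
# planted effects (shared between the beta and count generators)

def _mode_beta_params(mode: float, concentration: float) -> tuple[float, float]:
    # Beta(a, b) with given mode; concentration = a + b
    a = mode * (concentration - 2.0) + 1.0
    b = (1.0 - mode) * (concentration - 2.0) + 1.0
    return a, b


def plant_effects(config: SimulationConfig) -> dict[str, object]:
    """Choose, deterministically from the seed, which genes carry effects.

    Hypomethylation is planted on baseline-methylated genes and
    hypermethylation on baseline-unmethylated genes (an effect must have
    somewhere to go). A configurable fraction of the hypomethylated genes
    is also planted as upregulated, so the inverse-correlation candidate
    set has a known size.
    """
    rng = np.random.default_rng([config.seed, _STREAM_EFFECTS])
    genes = np.array(gene_ids(config))
    methylated = rng.random(config.n_genes) < config.meth_fraction
    meth_genes = genes[methylated]
    unmeth_genes = genes[~methylated]

    n_hypo = min(round(config.effect_fraction_hypo * config.n_genes), len(meth_genes))
    hypo = rng.choice(meth_genes, size=n_hypo, replace=False) if n_hypo else np.array([], dtype=object)
    n_hyper = min(round(config.effect_fraction_hyper * config.n_genes), len(unmeth_genes))
    hyper = rng.choice(unmeth_genes, size=n_hyper, replace=False) if n_hyper else np.array([], dtype=object)

    n_up = round(config.de_fraction_up * config.n_genes)
    k_overlap = min(round(config.inverse_overlap_fraction * len(hypo)), n_up)
    up_from_hypo = rng.choice(hypo, size=k_overlap, replace=False) if k_overlap else np.array([], dtype=object)
    pool = np.array(sorted(set(genes) - set(hypo)))
    n_extra = min(n_up - k_overlap, len(pool))
    up_extra = rng.choice(pool, size=n_extra, replace=False) if n_extra else np.array([], dtype=object)
    up = set(up_from_hypo) | set(up_extra)

    pool_down = np.array(sorted(set(genes) - up - set(hypo)))
    n_down = min(round(config.de_fraction_down * config.n_genes), len(pool_down))
    down = set(rng.choice(pool_down, size=n_down, replace=False)) if n_down else set()

    return {
        "methylated_baseline": pd.Series(methylated, index=genes),
        "hypo_genes": frozenset(map(str, hypo)),
        "hyper_genes": frozenset(map(str, hyper)),
        "de_up_genes": frozenset(map(str, up)),
        "de_down_genes": frozenset(map(str, down)),
    }


# ---------------------------------------------------------------------------
# beta matrix

def simulate_beta_matrix(manifest: pd.DataFrame,
                         config: SimulationConfig) -> tuple[BetaMatrix, GroundTruth]:
    """Simulate an array beta-value matrix with planted knockdown effects.

    Baseline betas are bimodal: each gene's probes sit at the methylated or
    the unmethylated mode, with Beta(mode, concentration) replicate noise.
    At planted hypo (hyper) CpGs the knockdown samples' expected beta is
    the control expectation minus (plus) ``delta_beta_effect``, clipped
    into (0, 1); controls and null probes are draws from the baseline.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    effects = plant_effects(config)
    rng = np.random.default_rng([config.seed, _STREAM_BETA])

    probe_gene = manifest.set_index("probe_id")["gene"]
    gene_meth = effects["methylated_baseline"]
    probe_meth = gene_meth.reindex(probe_gene.values).to_numpy()
    modes = np.where(probe_meth, config.beta_meth_mode, config.beta_unmeth_mode)
    c = config.beta_concentration
    a0 = modes * (c - 2.0) + 1.0
    b0 = (1.0 - modes) * (c - 2.0) + 1.0
    mu0 = a0 / (a0 + b0)

    hypo_probes = probe_gene.index[probe_gene.isin(effects["hypo_genes"])].to_numpy()
    hyper_probes = probe_gene.index[probe_gene.isin(effects["hyper_genes"])].to_numpy()
    is_hypo = probe_gene.isin(effects["hypo_genes"]).to_numpy()
    is_hyper = probe_gene.isin(effects["hyper_genes"]).to_numpy()

    eps = 1e-3
    mu_kd = mu0.copy()
    mu_kd[is_hypo] = np.clip(mu0[is_hypo] - config.delta_beta_effect, eps, 1 - eps)
    mu_kd[is_hyper] = np.clip(mu0[is_hyper] + config.delta_beta_effect, eps, 1 - eps)
    # knockdown draws are mean-parameterized at the shifted expectation
    a_kd = mu_kd * c
    b_kd = (1.0 - mu_kd) * c

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for line in config.cell_lines:
        for role in config.roles:
            name = f"{line}_{role}"
            if role.startswith("control"):
                col = rng.beta(a0, b0)
                kind = "control"
            else:
                col = rng.beta(a_kd, b_kd)
                kind = "knockdown"
            columns[name] = col
            sample_rows.append((name, line, kind, role))

    values = pd.DataFrame(columns, index=pd.Index(manifest["probe_id"], name="probe_id"))
    samples = pd.DataFrame(sample_rows, columns=["sample", "line", "role", "replicate"])
    truth = GroundTruth(
        hypo_cpgs={line: frozenset(hypo_probes) for line in config.cell_lines},
        hyper_cpgs={line: frozenset(hyper_probes) for line in config.cell_lines},
        hypo_genes={line: effects["hypo_genes"] for line in config.cell_lines},
        hyper_genes={line: effects["hyper_genes"] for line in config.cell_lines},
        de_up_genes={line: effects["de_up_genes"] for line in config.cell_lines},
        de_down_genes={line: effects["de_down_genes"] for line in config.cell_lines},
    )
    return BetaMatrix(values, samples), truth


# ---------------------------------------------------------------------------
# RNA-seq counts

def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate NB-distributed gene counts with planted fold changes.

    Per-gene relative abundances are log-normal; knockdown samples have the
    planted up (down) genes' expected counts multiplied (divided) by
    ``2**de_log2fc``. Counts are NB with dispersion ``nb_dispersion``
    (variance mu + phi*mu^2); dispersion handling degrades to Poisson as
    phi -> 0. Gene lengths are emitted for RPKM.
    """
    effects = plant_effects(config)
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS])
    genes = np.array(gene_ids(config))
    theta = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    theta /= theta.sum()
    lengths = pd.Series(rng.integers(500, 5001, size=config.n_genes),
                        index=genes, name="length_bp")

    fc = np.ones(config.n_genes)
    up = np.isin(genes, list(effects["de_up_genes"]))
    down = np.isin(genes, list(effects["de_down_genes"]))
    fc[up] = 2.0 ** config.de_log2fc
    fc[down] = 2.0 ** (-config.de_log2fc)

    phi = config.nb_dispersion

    def draw(mu: np.ndarray) -> np.ndarray:
        if config.count_lib_size == 0:
            return np.zeros_like(mu, dtype=np.int64)
        if phi == 0:
            return rng.poisson(mu)
        r = 1.0 / phi
        return rng.negative_binomial(r, r / (r + mu))

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for line in config.cell_lines:
        for role in config.roles:
            name = f"{line}_{role}"
            if role.startswith("control"):
                mu = config.count_lib_size * theta
                kind = "control"
            else:
                mu = config.count_lib_size * theta * fc
                kind = "knockdown"
            columns[name] = draw(mu)
            sample_rows.append((name, line, kind, role))

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(sample_rows, columns=["sample", "line", "role", "replicate"])
    truth = GroundTruth(
        de_up_genes={line: effects["de_up_genes"] for line in config.cell_lines},
        de_down_genes={line: effects["de_down_genes"] for line in config.cell_lines},
        hypo_genes={line: effects["hypo_genes"] for line in config.cell_lines},
        hyper_genes={line: effects["hyper_genes"] for line in config.cell_lines},
    )
    return CountMatrix(counts, lengths, samples), truth


# ---------------------------------------------------------------------------
# bisulfite reads

def random_region(config: SimulationConfig, length: int = 240,
                  region_id: str = "amplicon") -> "ReferenceRegion":
    """A random unconverted amplicon sequence containing CpG dinucleotides."""
    from .bisulfite import ReferenceRegion

    rng = np.random.default_rng([config.seed, _STREAM_READS, 99])
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=[0.3, 0.25, 0.25, 0.2])
    # guarantee a handful of CpGs
    for i in range(10, length - 2, max(20, length // 10)):
        seq[i], seq[i + 1] = "C", "G"
    return ReferenceRegion.from_sequence(region_id, "".join(seq))


def simulate_bisulfite_reads(region, mi_true: float, n_reads: int,
                             config: SimulationConfig) -> ReadSet:
    """Simulate clonal bisulfite-sequencing reads over ``region``.

    Each read methylates every CpG independently with probability
    ``mi_true``, then undergoes deterministic conversion: unmethylated CpG
    C -> T, methylated CpG C retained, all other C -> T except that each
    non-CpG C is retained (conversion failure) with probability
    ``conversion_failure_rate``.
    """
    if not region.cpg_positions:
        raise ValueError(f"region {region.id!r} contains no CpG sites")
    if not 0.0 <= mi_true <= 1.0:
        raise ValueError("mi_true must be a fraction in [0, 1]")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng([config.seed, _STREAM_READS, n_reads,
                                 int(round(mi_true * 1_000_000))])
    cpg_idx = np.array([p - 1 for p in region.cpg_positions])
    seq = np.array(list(region.sequence))
    is_c = seq == "C"
    non_cpg_c = np.flatnonzero(is_c & ~np.isin(np.arange(len(seq)), cpg_idx))

    names, reads = [], []
    truth = rng.random((n_reads, len(cpg_idx))) < mi_true
    for i in range(n_reads):
        out = seq.copy()
        out[non_cpg_c] = np.where(
            rng.random(len(non_cpg_c)) < config.conversion_failure_rate, "C", "T")
        out[cpg_idx] = np.where(truth[i], "C", "T")
        names.append(f"{region.id}_read{i + 1:04d}")
        reads.append("".join(out))
    return ReadSet(region.id, names, reads, truth)


# ---------------------------------------------------------------------------
# qPCR Ct tables

def simulate_qpcr(targets: list[str], config: SimulationConfig,
                  assay: str = "expression",
                  replicates: int = 3) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a Ct table for expression qRT-PCR or ChIP-qPCR.

    The Ct model is ``Ct = baseline - log2(template quantity) + noise``
    with Gaussian cycle noise (multiplicative efficiency noise on the
    template scale). Expression assays include a stable reference gene
    ``REF`` and a calibrator sample; ChIP assays emit IP, input (diluted to
    ``chip_input_fraction``) and IgG rows for control and knockdown
    samples, with H3K9me2 enrichment planted in the control only
    (dis-enrichment after knockdown).
    """
    if not targets:
        raise ValueError("no targets given")
    if assay not in ("expression", "chip"):
        raise ValueError("assay must be 'expression' or 'chip'")
    rng = np.random.default_rng([config.seed, _STREAM_QPCR, len(targets),
                                 0 if assay == "expression" else 1])

    def ct(quantity: float) -> float:
        return config.ct_baseline - math.log2(quantity) + rng.normal(0.0, config.ct_noise_sd)

    rows = []
    if assay == "expression":
        fold = 2.0 ** config.de_log2fc
        for sample, is_cal in (("calibrator", True), ("knockdown", False)):
            for rep in range(1, replicates + 1):
                rows.append((sample, "REF", "expression", rep, ct(1.0)))
                for t in targets:
                    q = 1.0 if is_cal else fold
                    rows.append((sample, t, "expression", rep, ct(q)))
        truth = GroundTruth(enrichment_true={t: fold for t in targets})
    else:
        igg_frac = 1e-3  # nonspecific background pulldown fraction
        for sample, enriched in (("control", True), ("knockdown", False)):
            for t in targets:
                ip_frac = igg_frac * (config.chip_enrichment if enriched else 1.0)
                for rep in range(1, replicates + 1):
                    rows.append((sample, t, "input", rep, ct(config.chip_input_fraction)))
                    rows.append((sample, t, "IP", rep, ct(ip_frac)))
                    rows.append((sample, t, "IgG", rep, ct(igg_frac)))
        truth = GroundTruth(enrichment_true={t: config.chip_enrichment for t in targets})
    table = pd.DataFrame(rows, columns=["sample", "target", "role", "replicate", "ct"])
    return table, truth


# ---------------------------------------------------------------------------
# survival

def simulate_survival(n_patients: int, config: SimulationConfig,
                      genes: list[str] | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a patient expression + survival table.

    Patients belong to a latent high- or low-expression group; survival
    times are exponential with the low group's hazard multiplied by
    ``survival_hr`` (hazard ratio > 1 means high expression is protective).
    Censoring is independent uniform over the follow-up horizon. Each
    signature gene's expression is the latent group shift plus unit
    Gaussian noise.
    """
    if n_patients < 4:
        raise ValueError("need at least 2 patients per latent group")
    genes = genes or [f"SIG{i + 1}" for i in range(6)]
    rng = np.random.default_rng([config.seed, _STREAM_SURVIVAL, n_patients])
    n_high = n_patients // 2
    group = np.array(["high"] * n_high + ["low"] * (n_patients - n_high))
    hazard = np.where(group == "high", config.survival_base_hazard,
                      config.survival_base_hazard * config.survival_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, config.survival_horizon, size=n_patients)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-6)
    event = (t_event <= t_cens).astype(int)

    table = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n_patients)],
        "time": time,
        "event": event,
    })
    shift = np.where(group == "high", config.survival_expr_shift, 0.0)
    for g in genes:
        table[g] = shift + rng.normal(0.0, 1.0, size=n_patients)
    truth = GroundTruth(survival_groups=pd.Series(group, index=table["patient_id"].values))
    return table, truth
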