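"""Parameter containers for the simulation and analysis stages.

All thresholds that gate a biological call are surfaced here; nothing is
hard-coded in the stage implementations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of the simulated knockdown experiment.

    The defaults emulate the study design the pipeline targets: two
    patient-derived tumour-initiating cell lines, each profiled once for the
    scrambled-shRNA control and once per knockdown shRNA construct (two
    independent constructs), on a beta-value methylation array and by
    RNA-seq.

    Parameters
    ----------
    beta_meth_mode, beta_unmeth_mode:
        Modes of the methylated / unmethylated beta components. Array beta
        values are bimodal; 0.70 and 0.15 are typical component modes.
    beta_concentration:
        Beta-distribution concentration (a+b) of replicate noise around a
        probe's expected level. 100 corresponds to a replicate s.d. of
        ~0.03-0.05, the scale seen between array replicates of cultured
        isogenic lines.
    delta_beta_effect:
        Expected beta drop (hypo) or gain (hyper) planted at effect CpGs.
        Default 0.5: an effect locus moves from the methylated mode (~0.7)
        into the unmethylated band (~0.2), the contrast seen when a silenced
        promoter is demethylated.
    effect_fraction_hypo, effect_fraction_hyper:
        Fractions of genes planted as hypo-/hyper-methylated on knockdown.
    nb_dispersion:
        Negative-binomial dispersion phi of simulated counts (variance
        mu + phi*mu^2).
    de_log2fc:
        Planted log2 fold change for differentially expressed genes.
    inverse_overlap_fraction:
        Fraction of planted hypomethylated genes that are also planted as
        upregulated, giving the inverse-correlation intersection a known
        ground truth.
    conversion_failure_rate:
        Probability that a non-CpG cytosine escapes bisulfite conversion in
        a simulated read.
    survival_hr:
        Hazard ratio of the low-expression patient group relative to the
        high-expression group (>1 means high expression is protective).
    """

    seed: int = 0
    n_genes: int = 500
    cpgs_per_gene: int = 3
    n_cell_lines: int = 2
    n_controls: int = 1
    n_kd_replicates: int = 2
    beta_meth_mode: float = 0.70
    beta_unmeth_mode: float = 0.15
    beta_concentration: float = 100.0
    meth_fraction: float = 0.5
    effect_fraction_hypo: float = 0.10
    effect_fraction_hyper: float = 0.02
    delta_beta_effect: float = 0.5
    count_lib_size: int = 1_000_000
    nb_dispersion: float = 0.1
    de_log2fc: float = 2.0
    de_fraction_up: float = 0.08
    de_fraction_down: float = 0.05
    inverse_overlap_fraction: float = 0.5
    conversion_failure_rate: float = 0.005
    ct_baseline: float = 25.0
    ct_noise_sd: float = 0.15
    chip_enrichment: float = 4.0
    chip_input_fraction: float = 0.01
    survival_hr: float = 2.0
    survival_base_hazard: float = 0.02
    survival_horizon: float = 120.0
    survival_expr_shift: float = 1.5

    def __post_init__(self) -> None:
        fractions = {
            "beta_meth_mode": self.beta_meth_mode,
            "beta_unmeth_mode": self.beta_unmeth_mode,
            "meth_fraction": self.meth_fraction,
            "effect_fraction_hypo": self.effect_fraction_hypo,
            "effect_fraction_hyper": self.effect_fraction_hyper,
            "inverse_overlap_fraction": self.inverse_overlap_fraction,
            "conversion_failure_rate": self.conversion_failure_rate,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not self.beta_meth_mode > self.beta_unmeth_mode:
            raise ValueError("beta_meth_mode must exceed beta_unmeth_mode")
        if not 0.0 <= self.delta_beta_effect <= 1.0:
            raise ValueError("delta_beta_effect must be in [0, 1]")
        for name in ("n_genes", "cpgs_per_gene", "n_cell_lines",
                     "n_controls", "n_kd_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("beta_concentration", "nb_dispersion", "survival_hr",
                     "survival_base_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.count_lib_size < 0:
            raise ValueError("count_lib_size must be non-negative")
        if not 0 < self.chip_input_fraction <= 1:
            raise ValueError("chip_input_fraction must be in (0, 1]")

    @property
    def cell_lines(self) -> list[str]:
        return [f"line{i + 1}" for i in range(self.n_cell_lines)]

    @property
    def roles(self) -> list[str]:
        """Sample roles within one cell line, controls first."""
        return ([f"control{i + 1}" if self.n_controls > 1 else "control"
                 for i in range(self.n_controls)]
                + [f"kd{i + 1}" for i in range(self.n_kd_replicates)])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds of the differential-methylation screen.

    A CpG is "methylated" at beta >= ``beta_meth_threshold`` (the boundary
    convention is >=; with the ``delta_beta_min`` requirement the boundary
    itself never decides a differential call). A differential call further
    requires the control-vs-knockdown beta difference to reach
    ``delta_beta_min``.
    """

    beta_meth_threshold: float = 0.35
    delta_beta_min: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.beta_meth_threshold < 1:
            raise ValueError("beta_meth_threshold must be in (0, 1)")
        if not 0 < self.delta_beta_min < 1:
            raise ValueError("delta_beta_min must be in (0, 1)")


@dataclass(frozen=True)
class DEParams:
    """Differential-expression filter: RPKM >= rpkm_min in at least one
    sample, |fold change| >= fc_min, and p <= p_max; ``dispersion`` is the
    fixed NB dispersion of the exact test or "estimate" for conditional-ML
    estimation (requires replicates in both arms)."""

    rpkm_min: float = 1.0
    fc_min: float = 2.0
    p_max: float = 0.05
    dispersion: float | str = 0.16

    def __post_init__(self) -> None:
        if self.rpkm_min <= 0 or self.fc_min <= 0:
            raise ValueError("rpkm_min and fc_min must be positive")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")
        if isinstance(self.dispersion, str):
            if self.dispersion != "estimate":
                raise ValueError("dispersion must be a number or 'estimate'")
        elif self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
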