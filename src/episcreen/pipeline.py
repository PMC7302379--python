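"""End-to-end orchestration: simulate (or load) -> methylation screen ->
differential expression -> cross-line integration, with a structured run
report. Identical configuration and seed give byte-identical outputs."""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as eio
from .config import DEParams, ScreenParams, SimulationConfig
from .integrate import inverse_correlation_candidates, rank_candidates, venn_report
from .meth import screen_gene_sets, screen_line
from .rnaseq import de_analyze_line
from .simulate import generate_manifest, simulate_beta_matrix, simulate_counts


@dataclass
class RunConfig:
    """One config for the whole pipeline; all thresholds surfaced."""

    seed: int = 0
    out_dir: str = "episcreen_run"
    simulation: SimulationConfig | None = None
    beta_path: str | None = None        # load instead of simulate
    manifest_path: str | None = None
    counts_path: str | None = None
    screen: ScreenParams = field(default_factory=ScreenParams)
    de: DEParams = field(default_factory=DEParams)
    fc_top_min: float = 2.5
    shortlist: int = 6
    promoter_only: bool = False
    run_screen: bool = True
    run_de: bool = True
    run_integrate: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        screen = raw.pop("screen", None)
        de = raw.pop("de", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if screen is not None:
            cfg.screen = ScreenParams(**screen)
        if de is not None:
            cfg.de = DEParams(**de)
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and write outputs + a JSON run report.

    The report records the seed, all parameters, and per-stage counts
    (probes called, genes per Venn category, candidates); its Venn rows
    satisfy the set-arithmetic identities by construction.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "parameters": _param_dict(config), "stages": {}}

    sim = config.simulation
    if config.beta_path and config.manifest_path:
        matrix = eio.read_beta_tsv(config.beta_path)
        manifest = eio.read_manifest_tsv(config.manifest_path)
    else:
        sim = sim or SimulationConfig(seed=config.seed)
        manifest = generate_manifest(sim)
        matrix, truth = simulate_beta_matrix(manifest, sim)
        eio.write_manifest_tsv(manifest, out / "manifest.tsv", sim.seed)
        eio.write_beta_tsv(matrix, out / "beta.tsv", sim.seed)
        eio.write_ground_truth(truth, out / "ground_truth.txt", sim.seed)
        report["stages"]["simulate"] = {
            "n_probes": len(manifest),
            "n_planted_hypo_genes": len(next(iter(truth.hypo_genes.values()), [])),
            "n_planted_hyper_genes": len(next(iter(truth.hyper_genes.values()), [])),
        }

    gene_sets = {}
    if config.run_screen:
        try:
            gene_sets = screen_gene_sets(matrix, manifest, config.screen,
                                         promoter_only=config.promoter_only)
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise RuntimeError(f"stage 'meth_screen' failed: {exc}") from exc
        stage = {}
        for line, gcs in gene_sets.items():
            calls = screen_line(matrix, line, config.screen)
            calls.to_csv(out / f"calls_{line}.tsv", sep="\t", index=False)
            eio.write_gene_set(gcs.hypo_genes, out / f"hypo_genes_{line}.txt")
            eio.write_gene_set(gcs.hyper_genes, out / f"hyper_genes_{line}.txt")
            stage[line] = {
                "n_probes_called": int((calls["verdict"] != "none").sum()),
                "n_hypo_genes": len(gcs.hypo_genes),
                "n_hyper_genes": len(gcs.hyper_genes),
                "n_conflicted_genes": len(gcs.conflicted_genes),
            }
        report["stages"]["meth_screen"] = stage

    de_results = {}
    if config.run_de:
        if config.counts_path:
            cm = eio.read_counts_tsv(config.counts_path)
        else:
            cm, _ = simulate_counts(sim or SimulationConfig(seed=config.seed))
            eio.write_counts_tsv(cm, out / "counts.tsv",
                                 (sim or SimulationConfig()).seed)
        stage = {}
        for line in cm.lines:
            try:
                res = de_analyze_line(cm, line, config.de)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"stage 'rnaseq_de' failed on {line}: {exc}") from exc
            res.table.to_csv(out / f"de_{line}.tsv", sep="\t", index=False)
            eio.write_gene_set(res.up_genes, out / f"up_genes_{line}.txt")
            eio.write_gene_set(res.down_genes, out / f"down_genes_{line}.txt")
            de_results[line] = res
            stage[line] = {"n_up": len(res.up_genes), "n_down": len(res.down_genes)}
        report["stages"]["rnaseq_de"] = stage

    if config.run_integrate and gene_sets and de_results:
        lines = sorted(gene_sets)
        if len(lines) < 2:
            raise RuntimeError("stage 'integrate' needs two cell lines")
        l1, l2 = lines[:2]
        categories = {
            "hypo": (gene_sets[l1].hypo_genes, gene_sets[l2].hypo_genes),
            "hyper": (gene_sets[l1].hyper_genes, gene_sets[l2].hyper_genes),
            "up": (de_results[l1].up_genes, de_results[l2].up_genes),
            "down": (de_results[l1].down_genes, de_results[l2].down_genes),
        }
        venn = venn_report(categories)
        venn.to_csv(out / "venn_report.tsv", sep="\t", index=False)

        hypo_common = gene_sets[l1].hypo_genes & gene_sets[l2].hypo_genes
        up_common = de_results[l1].up_genes & de_results[l2].up_genes
        delta_by_line, fc_by_line = {}, {}
        for line in (l1, l2):
            calls = screen_line(matrix, line, config.screen)
            hypo_calls = calls[calls["verdict"] == "hypo"]
            probe_gene = manifest.set_index("probe_id")["gene"]
            genes = hypo_calls["probe_id"].map(probe_gene).str.upper()
            delta_by_line[line] = hypo_calls.groupby(genes)["delta_beta"].mean().to_dict()
            t = de_results[line].table
            fc_by_line[line] = dict(zip(t["gene_id"].str.upper(), t["log2fc"]))
        candidates = inverse_correlation_candidates(
            hypo_common, up_common, delta_beta=delta_by_line, log2fc=fc_by_line)
        shortlist = rank_candidates(candidates, config.fc_top_min, config.shortlist)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        shortlist.to_csv(out / "shortlist.tsv", sep="\t", index=False)
        report["stages"]["integrate"] = {
            "venn": venn.to_dict(orient="records"),
            "n_hypo_common": len(hypo_common),
            "n_up_common": len(up_common),
            "n_candidates": len(candidates),
            "n_shortlisted": len(shortlist),
        }

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def demo(out_dir: str | Path, seed: int = 0) -> dict:
    """Small bundled synthetic run: simulate -> screen -> DE -> integrate."""
    cfg = RunConfig(seed=seed, out_dir=str(out_dir),
                    simulation=SimulationConfig(seed=seed, n_genes=200))
    return run_pipeline(cfg)


def _param_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
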