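"""End-to-end orchestration: expression -> flux -> differential testing,
plus the clustering/ORA networks arm, with a machine-readable run report.

A run is fully determined by its config and seed: output TSVs carry a header
comment with the run id (derived from the config hash and seed, never a
timestamp) and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import expression as expr_mod
from . import flux_diff as fd_mod
from . import flux_sim as fs_mod
from . import networks as net_mod
from . import synthetic_data as syn_mod
from .model_io import MetabolicModel, build_toy_model, read_model_json, validate_model

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("lentiflux")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds driving a pipeline run."""

    model: str = "toy"
    counts: str | None = None
    samples: str | None = None
    lengths: str | None = None
    gmt: str | None = None
    ppi: str | None = None
    outdir: str = "results/run"
    seed: int = 0
    fdr_alpha: float = 0.05
    lfc_min: float = 0.01
    pseudocount: float = 1.0
    flux_percentile: float = 95.0
    k_min: int = 2
    k_max: int = 10
    consensus_reps: int = 30
    consensus_subsample: float = 0.8
    consensus_threshold: float = 0.5
    cluster_genes: str = "model"
    ppi_score_min: float = 0.4
    synthetic_n_pairs: int = 7
    synthetic_n_genes: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.cluster_genes not in ("model", "de"):
            raise ValueError("cluster_genes must be 'model' or 'de'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict[str, Any] = {}
        for key, value in raw.items():
            if key == "thresholds":
                flat["fdr_alpha"] = value.get("fdr_alpha", 0.05)
                flat["lfc_min"] = value.get("lfc_min", 0.01)
            elif key == "flux":
                flat["flux_percentile"] = value.get("percentile", 95.0)
            elif key == "consensus":
                flat["k_min"] = value.get("k_min", 2)
                flat["k_max"] = value.get("k_max", 10)
                flat["consensus_reps"] = value.get("reps", 30)
                flat["consensus_subsample"] = value.get("subsample", 0.8)
                flat["consensus_threshold"] = value.get("threshold", 0.5)
            elif key == "synthetic":
                flat["synthetic_n_pairs"] = value.get("n_pairs", 7)
                flat["synthetic_n_genes"] = value.get("n_genes", 200)
            else:
                flat[key] = value
        return cls(**flat)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _write_tsv(frame: pd.DataFrame, path: Path, run_header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {run_header}\n")
        frame.to_csv(fh, sep="\t")


def _load_model(config: PipelineConfig) -> MetabolicModel:
    if config.model == "toy":
        return build_toy_model()
    model = read_model_json(config.model)
    violations = validate_model(model)
    if violations:
        raise PipelineError(
            f"stage model: {len(violations)} validation violation(s); "
            f"first: {violations[0]}"
        )
    return model


def _load_expression(
    config: PipelineConfig, model: MetabolicModel, outdir: Path, header: str
) -> expr_mod.ExpressionMatrix:
    if config.counts is not None:
        if config.samples is None:
            raise PipelineError("stage expression: counts given without a sample sheet")
        return expr_mod.read_counts_tsv(config.counts, config.samples, config.lengths)
    design = syn_mod.make_demo_design(
        model,
        seed=config.seed,
        n_pairs=config.synthetic_n_pairs,
        n_genes=config.synthetic_n_genes,
    )
    counts = syn_mod.generate_counts(design)
    gold = syn_mod.make_gold_standard(design, model)
    syn_mod.write_cohort(counts, outdir, gold)
    return counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order and return the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_id = hashlib.sha256(
        f"{config.config_hash()}:{config.seed}".encode()
    ).hexdigest()[:12]
    header = f"run_id={run_id} config_hash={config.config_hash()} seed={config.seed}"
    report: dict[str, Any] = {
        "run_id": run_id,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "input_hashes": {
            k: _file_hash(v)
            for k, v in {
                "counts": config.counts,
                "samples": config.samples,
                "lengths": config.lengths,
                "gmt": config.gmt,
                "ppi": config.ppi,
            }.items()
            if v is not None
        },
    }
    stage = "init"
    try:
        stage = "model"
        t0 = time.perf_counter()
        model = _load_model(config)
        report["n_reactions"] = len(model.reactions)
        report["n_metabolites"] = len(model.metabolites)
        log.info("stage=model reactions=%d (%.2fs)", len(model.reactions), time.perf_counter() - t0)

        stage = "expression"
        t0 = time.perf_counter()
        counts = _load_expression(config, model, outdir, header)
        tpm = (
            expr_mod.counts_to_tpm(counts) if counts.kind == "counts" else counts
        )
        _write_tsv(tpm.values.rename_axis("gene"), outdir / "tpm.tsv", header)
        de_table = expr_mod.differential_expression(
            tpm,
            alpha=config.fdr_alpha,
            lfc_min=config.lfc_min,
            pseudocount=config.pseudocount,
        )
        _write_tsv(de_table.rename_axis("gene"), outdir / "de_table.tsv", header)
        de_genes = expr_mod.de_filter(de_table, config.fdr_alpha, config.lfc_min)
        report["n_genes"] = int(tpm.values.shape[0])
        report["n_samples"] = int(tpm.values.shape[1])
        report["genes_tested"] = int(len(de_table))
        report["genes_passing_filter"] = int(len(de_genes))
        log.info(
            "stage=expression genes=%d passing=%d (%.2fs)",
            len(de_table), len(de_genes), time.perf_counter() - t0,
        )

        stage = "flux_sim"
        t0 = time.perf_counter()
        cohort = fs_mod.simulate_cohort(
            model, tpm.values, percentile=config.flux_percentile
        )
        _write_tsv(
            cohort.flux_table.rename_axis("reaction"), outdir / "flux_table.tsv", header
        )
        report["flux_samples_solved"] = int((cohort.statuses == "optimal").sum())
        log.info(
            "stage=flux_sim samples=%d (%.2fs)",
            cohort.flux_table.shape[1], time.perf_counter() - t0,
        )

        stage = "flux_diff"
        t0 = time.perf_counter()
        dft = fd_mod.differential_flux_table(
            cohort.flux_table,
            tpm.groups,
            alpha=config.fdr_alpha,
            model=model,
        )
        _write_tsv(dft, outdir / "differential_flux.tsv", header)
        significant = sorted(dft.index[dft["significant"]])
        report["reactions_tested"] = int(dft["tested"].sum())
        report["reactions_significant"] = len(significant)
        report["significant_reactions"] = significant
        log.info(
            "stage=flux_diff tested=%d significant=%d (%.2fs)",
            report["reactions_tested"], len(significant), time.perf_counter() - t0,
        )

        stage = "networks"
        t0 = time.perf_counter()
        if config.cluster_genes == "model":
            cluster_genes = [g for g in sorted(model.genes) if g in tpm.values.index]
        else:
            cluster_genes = list(de_genes)
        profiles = expr_mod.paired_log2fc(tpm, config.pseudocount).loc[cluster_genes]
        k_max = min(config.k_max, len(cluster_genes) - 1)
        if k_max >= max(2, config.k_min):
            consensus = net_mod.consensus_cluster(
                profiles,
                k_range=range(config.k_min, k_max + 1),
                reps=config.consensus_reps,
                subsample_frac=config.consensus_subsample,
                seed=config.seed,
            )
            report["chosen_k"] = int(consensus.chosen_k)
            graph = net_mod.consensus_network(
                consensus, threshold=config.consensus_threshold
            )
            report["consensus_edges"] = graph.number_of_edges()
            net_mod.write_edge_list(
                graph, outdir / "consensus_network.tsv", header
            )
            _write_tsv(
                consensus.assignment.rename_axis("gene").to_frame(),
                outdir / "consensus_clusters.tsv",
                header,
            )
        else:
            report["chosen_k"] = None
            report["consensus_edges"] = 0
        if config.ppi is not None:
            ppi = net_mod.ppi_ingest(config.ppi, config.ppi_score_min)
            topo = net_mod.network_topology(ppi)
            report["ppi_edges"] = ppi.number_of_edges()
            report["ppi_density"] = topo["density"]
            net_mod.write_edge_list(ppi, outdir / "ppi_network.tsv", header)
        if config.gmt is not None:
            collection = net_mod.read_gmt(
                config.gmt, universe=list(tpm.values.index)
            )
            ora = net_mod.hypergeom_ora(list(de_genes), collection)
            _write_tsv(ora, outdir / "ora.tsv", header)
            report["ora_sets_tested"] = int(len(ora))
            report["ora_sets_significant"] = int((ora["fdr"] < config.fdr_alpha).sum())
        log.info("stage=networks (%.2fs)", time.perf_counter() - t0)

        stage = "report"
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        summary = pd.DataFrame(
            sorted(
                (k, json.dumps(v) if isinstance(v, (list, dict)) else v)
                for k, v in report.items()
            ),
            columns=["key", "value"],
        ).set_index("key")
        _write_tsv(summary, outdir / "summary.tsv", header)
    except Exception as exc:
        marker = outdir / f"FAILED_{stage}"
        marker.write_text(f"{type(exc).__name__}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    return report
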