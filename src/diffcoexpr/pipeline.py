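"""End-to-end orchestration: simulate/load -> network -> modules -> diffcorr
-> switching -> enrichment -> survival, with a JSON run manifest.

Differential correlation is computed only within the modules most associated
with the trait (quadratic pair growth makes the all-genes run an explicit
opt-in), mirroring the analysis design the pipeline implements: module
discovery first, then pair-level statistics inside the trait-linked modules.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import data_io, diffcorr, network, stats
from .data_io import ExpressionMatrix, PhenotypeTable
from .simulate import SimulationConfig, simulate as run_simulation
from .palette import GREY

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "select_trait_modules", "run_pipeline"]

PACKAGE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Every stage's parameters plus either input paths or a simulation recipe."""

    # inputs: either paths ...
    expression_path: str | None = None
    phenotype_path: str | None = None
    gmt_path: str | None = None
    log2_transform: bool = False
    # ... or a simulation
    simulation: SimulationConfig | None = None
    # network stage
    power: int | str = "auto"  # integer or "auto"
    candidate_powers: list[int] = field(default_factory=lambda: list(range(1, 13)))
    r2_floor: float = 0.8
    min_module_size: int = 30
    cut_height: float = 0.995
    tom_edge_threshold: float = 0.1
    # differential correlation stage
    scaling: str | None = None
    r_cutoff: float = 0.6
    alpha_lfdr: float = 0.05
    alpha_de: float = 0.05
    min_abs_r: float = 0.0
    de_rule: str = "both"
    all_pairs: bool = False  # opt-in: diffcorr across all genes, not per module
    # survival stage
    n_cutoffs: int = 90
    # module selection
    top_k_modules: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None and self.expression_path is None:
            raise ValueError("config needs either input paths or a simulation block")
        if self.simulation is not None and self.expression_path is not None:
            raise ValueError("give either input paths or a simulation block, not both")
        if self.simulation is None and self.phenotype_path is None:
            raise ValueError("expression input requires a phenotype table")
        if self.top_k_modules < 1:
            raise ValueError("top_k_modules must be >= 1")
        if isinstance(self.power, str) and self.power != "auto":
            raise ValueError("power must be an integer or 'auto'")
        if self.scaling is not None and self.scaling not in diffcorr.SCALING_METHODS:
            raise ValueError(f"unknown scaling method {self.scaling!r}")
        if self.de_rule not in ("both", "either"):
            raise ValueError("de_rule must be 'both' or 'either'")
        if self.simulation is not None:
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value YAML config; simulation keys live under ``simulation:``."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_block = raw.pop("simulation", None)
        config = cls(**raw)
        if sim_block is not None:
            if "survival_genes" in sim_block:
                sim_block["survival_genes"] = [
                    (int(g), float(b)) for g, b in sim_block["survival_genes"]
                ]
            config.simulation = SimulationConfig(**sim_block)
        config.validate()
        return config

    def echo(self) -> dict[str, Any]:
        d = asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str
    seed: int
    stages: list[dict[str, Any]]
    warnings: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str) + "\n")


def select_trait_modules(mt: network.ModuleTraitResult, top_k: int) -> list[str]:
    """Modules most associated with the trait, ranked by |r_mt| descending.

    Ties break by smaller p-value, then label.  Asking for more modules than
    exist returns them all with a warning.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    table = mt.module_stats[mt.module_stats.index != GREY]
    ranked = table.assign(abs_r=table["r_mt"].abs()).sort_values(
        ["abs_r", "p_value", "module"], ascending=[False, True, True],
        kind="mergesort",
    )
    if top_k > len(ranked):
        logger.warning(
            "top_k=%d exceeds the %d detected modules; returning all", top_k, len(ranked)
        )
        return list(ranked.index)
    return list(ranked.index[:top_k])


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(self.format(record))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute the full analysis and write every intermediate to ``outdir``.

    Identical config and seed give byte-identical result tables.  Any stage
    error aborts with the stage name attached.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict[str, Any]] = []
    collector = _WarningCollector()
    logging.getLogger("diffcoexpr").addHandler(collector)
    stage_name = "setup"

    def _record(name: str, n_in: int, n_out: int, t0: float) -> None:
        stages.append(
            {"stage": name, "n_in": n_in, "n_out": n_out,
             "seconds": round(time.perf_counter() - t0, 3)}
        )

    try:
        # ---- inputs -------------------------------------------------------
        stage_name = "input"
        t0 = time.perf_counter()
        truth = None
        if config.simulation is not None:
            X, pheno, truth = run_simulation(config.simulation)
            data_io.write_expression(X, outdir / "expression.tsv")
            data_io.write_phenotype(pheno, outdir / "phenotype.tsv")
            truth.to_json(outdir / "truth.json")
        else:
            X = data_io.read_expression(
                config.expression_path, log2_transform=config.log2_transform
            )
            pheno = data_io.read_phenotype(config.phenotype_path)
        pheno.validate_against(X)
        gene_sets = data_io.read_gmt(config.gmt_path) if config.gmt_path else None
        _record("input", X.n_genes, X.n_genes, t0)

        # ---- filtering ----------------------------------------------------
        stage_name = "filter"
        t0 = time.perf_counter()
        n_in = X.n_genes
        X, removed = network.filter_invariant_genes(X, pheno)
        _record("filter", n_in, X.n_genes, t0)

        # ---- optional scaling --------------------------------------------
        if config.scaling is not None:
            stage_name = "scaling"
            t0 = time.perf_counter()
            X = diffcorr.scale(X, config.scaling)
            _record(f"scaling[{config.scaling}]", X.n_genes, X.n_genes, t0)

        # ---- network ------------------------------------------------------
        stage_name = "network"
        t0 = time.perf_counter()
        if config.power == "auto":
            report = network.select_soft_threshold(
                X, config.candidate_powers, config.r2_floor
            )
            beta = report.chosen_power
            report.table.to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False)
        else:
            beta = int(config.power)
        adj = network.adjacency(X, beta)
        tom = network.topological_overlap(adj)
        modules = network.detect_modules(
            tom, min_module_size=config.min_module_size, cut_height=config.cut_height
        )
        modules.module_of_gene.rename("module").to_csv(
            outdir / "modules.tsv", sep="\t", index_label="gene"
        )
        _record("network", X.n_genes, len(modules.labels), t0)

        # ---- eigengenes and trait association -----------------------------
        stage_name = "module_trait"
        t0 = time.perf_counter()
        if not modules.labels:
            raise RuntimeError("no modules detected; cannot continue")
        eigen = network.module_eigengenes(X, modules)
        eigen.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="sample")
        mt = network.module_trait(eigen, pheno, X, modules)
        mt.module_stats.to_csv(outdir / "module_trait.tsv", sep="\t")
        selected = select_trait_modules(mt, config.top_k_modules)
        _record("module_trait", len(modules.labels), len(selected), t0)

        # ---- TOM edge export for the selected modules ---------------------
        stage_name = "network_export"
        t0 = time.perf_counter()
        edges = _tom_edges(tom, modules, selected, config.tom_edge_threshold)
        data_io.write_network(edges, outdir / "tom_edges.tsv", dialect="TSV")
        data_io.write_network(edges, outdir / "tom_edges.sif", dialect="SIF")
        _record("network_export", len(selected), len(edges), t0)

        # ---- differential expression --------------------------------------
        stage_name = "differential_expression"
        t0 = time.perf_counter()
        de = stats.differential_expression(X, pheno)
        de.table.to_csv(outdir / "de.tsv", sep="\t", index_label="gene")
        _record("differential_expression", X.n_genes, len(de.significant(config.alpha_de)), t0)

        # ---- differential correlation within selected modules -------------
        stage_name = "diffcorr"
        t0 = time.perf_counter()
        groups = (
            {"all": list(X.gene_ids)}
            if config.all_pairs
            else {m: modules.genes_in(m) for m in selected}
        )
        all_records = []
        all_switching = []
        for label, genes in groups.items():
            if len(genes) < 2:
                logger.warning("module %s has <2 genes; skipping diffcorr", label)
                continue
            records = diffcorr.condition_correlation_tests(X, pheno, genes)
            records = diffcorr.attach_lfdr(records)
            records.insert(0, "module", label)
            all_records.append(records)
            sw = diffcorr.detect_switching(
                records,
                de_table=de.table,
                alpha_lfdr=config.alpha_lfdr,
                alpha_de=config.alpha_de,
                min_abs_r=config.min_abs_r,
                de_rule=config.de_rule,
            )
            all_switching.append(sw)
        records = pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame()
        switching = pd.concat(all_switching, ignore_index=True) if all_switching else pd.DataFrame()
        # Table layout: molecule X, molecule Y, r1 (normal), r2 (tumor), lfdr
        records.to_csv(outdir / "diffcorr.tsv", sep="\t", index=False)
        switching.to_csv(outdir / "switching.tsv", sep="\t", index=False)
        _record("diffcorr", sum(len(g) for g in groups.values()), len(switching), t0)

        # ---- eigen-module networks ----------------------------------------
        stage_name = "eigen_modules"
        t0 = time.perf_counter()
        n_eigen_edges = 0
        for label, genes in groups.items():
            if len(genes) < 4:
                continue
            Xm = X.subset_genes(genes)
            net = diffcorr.cluster_molecules(Xm, pheno, r_cutoff=config.r_cutoff)
            if net.clusters["normal"].nunique() < 2:
                logger.warning("module %s clusters into one block; no module network", label)
                continue
            eigen_records = diffcorr.eigen_module_diffcorr(net, Xm, pheno)
            eigen_records.to_csv(
                outdir / f"eigen_module_diffcorr_{label}.tsv", sep="\t", index=False
            )
            eedges = diffcorr.eigen_network_edges(eigen_records)
            data_io.write_network(
                eedges, outdir / f"eigen_module_network_{label}.graphml", dialect="GraphML"
            )
            n_eigen_edges += len(eedges)
        _record("eigen_modules", len(groups), n_eigen_edges, t0)

        # ---- enrichment ----------------------------------------------------
        if gene_sets is not None:
            stage_name = "enrichment"
            t0 = time.perf_counter()
            frames = []
            for label in groups:
                genes = groups[label]
                enr = stats.hypergeom_enrichment(genes, gene_sets, list(X.gene_ids))
                frame = enr.table.reset_index()
                frame.insert(0, "module", label)
                frames.append(frame)
            enrichment = pd.concat(frames, ignore_index=True)
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            _record("enrichment", len(groups), len(enrichment), t0)

        # ---- survival scan of switching genes ------------------------------
        if pheno.has_survival and len(switching):
            stage_name = "survival"
            t0 = time.perf_counter()
            key_genes = sorted(set(switching["gene_a"]) | set(switching["gene_b"]))
            rows = []
            for gene in key_genes:
                x = X.subset_genes([gene]).values[0]
                try:
                    res = stats.survival_cutoff_scan(
                        x, pheno, n_cutoffs=config.n_cutoffs, gene=gene,
                        sample_ids=X.sample_ids,
                    )
                except ValueError as err:
                    logger.warning("survival scan skipped for %s: %s", gene, err)
                    continue
                rows.append(
                    (gene, res.best_cutoff_quantile, res.best_cutoff_value,
                     res.min_p, res.significant, res.hazard_ratio)
                )
                km = pd.concat(
                    [res.km_low.assign(group="low"), res.km_high.assign(group="high")],
                    ignore_index=True,
                )
                km.to_csv(outdir / f"km_{gene}.tsv", sep="\t", index=False)
            scan_table = pd.DataFrame(
                rows,
                columns=["gene", "best_cutoff_quantile", "best_cutoff_value",
                         "min_p", "significant", "hazard_ratio"],
            )
            scan_table.to_csv(outdir / "survival_scan.tsv", sep="\t", index=False)
            _record("survival", len(key_genes), len(scan_table), t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {err}") from err
    finally:
        logging.getLogger("diffcoexpr").removeHandler(collector)

    manifest = RunManifest(
        config=config.echo(),
        version=PACKAGE_VERSION,
        seed=config.seed,
        stages=stages,
        warnings=collector.messages,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _tom_edges(
    tom: network.TOMMatrix,
    modules: network.ModuleAssignment,
    selected: list[str],
    threshold: float,
) -> data_io.NetworkEdgeTable:
    """TOM-thresholded edge list restricted to the selected modules."""
    edges = []
    for label in selected:
        genes = modules.genes_in(label)
        idx = [tom.gene_ids.index(g) for g in genes]
        for a_pos in range(len(idx)):
            for b_pos in range(a_pos + 1, len(idx)):
                w = float(tom.values[idx[a_pos], idx[b_pos]])
                if w >= threshold:
                    edges.append((genes[a_pos], genes[b_pos], w, "+", label))
    return data_io.make_edge_table(edges)
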