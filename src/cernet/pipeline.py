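"""End-to-end orchestration: simulate/load -> DE -> coexpression -> ceRNA.

``run_pipeline`` executes the stages in order, writes per-stage TSV/SIF/
GraphML outputs plus the resolved configuration and a log into the output
directory, and is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cerna as cr
from . import coexpression as cx
from . import diffexpr as de
from . import io as cio
from .simulate import (ExpressionStudy, SimulationConfig, simulate_study,
                       simulate_target_table)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("cernet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run.

    When the count paths are absent a study is simulated from
    ``simulation`` instead (seeded by ``seed``).
    """

    counts_mrna: Optional[str] = None
    counts_lncrna: Optional[str] = None
    counts_mirna: Optional[str] = None
    sample_sheet: Optional[str] = None
    targets: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    out_dir: str = "cernet_out"
    # DE thresholds
    fc_up: float = 1.2
    fc_down: float = 0.83
    alpha: float = 0.05
    # co-expression
    beta: int | str = "auto"
    r2_target: float = 0.8
    min_mean_k: float = 1.0
    cut_height: float = 0.95
    min_module_size: int = 5
    hub_min_degree: int = 5
    # ceRNA
    pcc_min: float = 0.8
    pcc_alpha: float = 0.05
    min_shared: int = 2
    hyper_alpha: float = 0.05
    universe: Optional[int] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.fc_down < 1.0 < self.fc_up:
            raise ValueError("fc thresholds must satisfy fc_down < 1 < fc_up")
        for name in ("alpha", "pcc_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.hyper_alpha <= 1:
            raise ValueError("hyper_alpha must be in (0, 1]")
        if not -1 <= self.pcc_min <= 1:
            raise ValueError("pcc_min must be in [-1, 1]")
        if self.min_shared < 0:
            raise ValueError("min_shared must be >= 0")
        if self.beta != "auto":
            self.beta = int(self.beta)
            if self.beta < 1:
                raise ValueError("beta must be 'auto' or a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("base_mean_log2_range", "library_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        if self.simulation is not None:
            payload["simulation"] = dataclasses.asdict(self.simulation)
            for key in ("base_mean_log2_range", "library_size_range"):
                payload["simulation"][key] = list(payload["simulation"][key])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return decorate


@_stage("load_inputs")
def _load_inputs(cfg: PipelineConfig) -> tuple[ExpressionStudy, pd.DataFrame]:
    paths = (cfg.counts_mrna, cfg.counts_lncrna, cfg.counts_mirna,
             cfg.sample_sheet)
    if all(p is not None for p in paths):
        log.info("reading counts and sample sheet from disk")
        study = ExpressionStudy(
            counts={"mrna": cio.read_counts(cfg.counts_mrna),
                    "lncrna": cio.read_counts(cfg.counts_lncrna),
                    "mirna": cio.read_counts(cfg.counts_mirna)},
            sample_sheet=cio.read_sample_sheet(cfg.sample_sheet))
        if cfg.targets is None:
            raise ValueError("a target table path is required with real counts")
        targets = cio.read_target_table(cfg.targets)
        return study, targets
    sim = cfg.simulation or SimulationConfig()
    sim = dataclasses.replace(sim, seed=cfg.seed)
    log.info("simulating study (seed=%d)", sim.seed)
    study = simulate_study(sim)
    targets = (cio.read_target_table(cfg.targets) if cfg.targets is not None
               else simulate_target_table(study.truth, sim))
    return study, targets


@_stage("diffexpr")
def _run_de(cfg: PipelineConfig, study: ExpressionStudy,
            out: Path) -> dict[str, pd.DataFrame]:
    tables = {}
    for cls in ("mrna", "lncrna", "mirna"):
        if study.counts[cls].empty:
            tables[cls] = pd.DataFrame(columns=de.DE_COLUMNS)
            continue
        table = de.de_test(study, cls, up=cfg.fc_up, down=cfg.fc_down,
                           alpha=cfg.alpha)
        cio.write_de_table(table, out / f"de_{cls}.tsv")
        n_up = int((table["call"] == "up").sum())
        n_down = int((table["call"] == "down").sum())
        log.info("DE %s: %d up, %d down of %d (fc > %g or < %g, p < %g)",
                 cls, n_up, n_down, len(table), cfg.fc_up, cfg.fc_down,
                 cfg.alpha)
        tables[cls] = table
    return tables


@_stage("coexpression")
def _run_coexpression(cfg: PipelineConfig, expr_lnc: pd.DataFrame,
                      expr_mrna: pd.DataFrame, out: Path):
    expr = pd.concat([expr_lnc, expr_mrna])
    if cfg.beta == "auto":
        sweep = cx.pick_beta(expr, r2_target=cfg.r2_target,
                             min_mean_k=cfg.min_mean_k)
        beta = sweep.chosen_beta
        sweep.fits.to_csv(out / "beta_sweep.tsv", sep="\t", index=False,
                          float_format="%.10g")
        log.info("beta sweep: chose beta=%d (scale_free=%s)", beta,
                 sweep.scale_free)
    else:
        beta = int(cfg.beta)
        log.info("using fixed beta=%d", beta)
    S = cx.similarity(expr)
    A = cx.soft_adjacency(S, beta)
    modules = cx.cluster_modules(1.0 - cx.tom(A), cut_height=cfg.cut_height,
                                 min_module_size=cfg.min_module_size)
    modules.rename_axis("feature").reset_index().to_csv(
        out / "modules.tsv", sep="\t", index=False)
    log.info("modules: %d assigned across %d module(s)",
             int((modules > 0).sum()), int(modules.max()))

    network = cx.build_lnc_mrna_network(expr_lnc, expr_mrna,
                                        pcc_min=cfg.pcc_min,
                                        alpha=cfg.pcc_alpha)
    cio.write_network(network, out / "lnc_mrna_network.tsv", "tsv")
    cio.write_network(network, out / "lnc_mrna_network.sif", "sif")
    hubs = cx.extract_hub_subnetwork(network, cfg.hub_min_degree)
    cio.write_network(hubs, out / "hub_subnetwork.sif", "sif")
    log.info("lncRNA-mRNA network: %d nodes, %d edges (hub sub-network: "
             "%d nodes at degree >= %d)", network.number_of_nodes(),
             network.number_of_edges(), hubs.number_of_nodes(),
             cfg.hub_min_degree)
    return beta, modules, network


@_stage("cerna")
def _run_cerna(cfg: PipelineConfig, tables: dict[str, pd.DataFrame],
               expr_lnc: pd.DataFrame, expr_mrna: pd.DataFrame,
               targets: pd.DataFrame, out: Path) -> cr.CeRNANetwork:
    pairs = cr.candidate_pairs(expr_lnc, expr_mrna,
                               pcc_min=cfg.pcc_min, alpha=cfg.pcc_alpha)
    log.info("candidate lncRNA-mRNA pairs (PCC > %g, p < %g): %d",
             cfg.pcc_min, cfg.pcc_alpha, len(pairs))
    net = cr.assemble_cerna(tables, pairs, targets, alpha=cfg.hyper_alpha,
                            min_shared=cfg.min_shared, universe=cfg.universe)
    net.pairs.to_csv(out / "cerna_pairs.tsv", sep="\t", index=False,
                     float_format="%.10g")
    cio.write_network(net.graph, out / "cerna_network.sif", "sif")
    cio.write_network(net.graph, out / "cerna_network.graphml", "graphml")
    cio.write_node_table(net.graph, out / "cerna_nodes.tsv")
    cr.degree_report(net).to_csv(out / "cerna_degree_report.tsv", sep="\t",
                                 index=False)
    log.info("ceRNA network: %d nodes, %d edges, %d retained pairs "
             "(shared >= %d, hypergeometric p < %g)",
             net.graph.number_of_nodes(), net.graph.number_of_edges(),
             len(net.pairs), cfg.min_shared, cfg.hyper_alpha)
    return net


def _log_expression(counts: pd.DataFrame) -> pd.DataFrame:
    norm = de.normalize_counts(counts)
    return np.log2(norm + 1.0)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages and return the artifact directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.log_level)
    try:
        cfg.to_yaml(out / "resolved_config.yaml")
        study, targets = _load_inputs(cfg)
        cio.write_target_table(targets, out / "targets.tsv")
        tables = _run_de(cfg, study, out)

        de_lnc = de.de_feature_ids(tables["lncrna"])
        de_mrna = de.de_feature_ids(tables["mrna"])
        expr_lnc = _log_expression(study.counts["lncrna"]).loc[de_lnc]
        expr_mrna = _log_expression(study.counts["mrna"]).loc[de_mrna]

        if len(de_lnc) + len(de_mrna) >= 10:
            _run_coexpression(cfg, expr_lnc, expr_mrna, out)
        else:
            log.warning("only %d DE features; skipping co-expression stage",
                        len(de_lnc) + len(de_mrna))
        _run_cerna(cfg, tables, expr_lnc, expr_mrna, targets, out)
        log.info("pipeline complete: %s", out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
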