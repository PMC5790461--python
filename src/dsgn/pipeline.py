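"""End-to-end pipeline: simulate/load → screen → build → project → test.

`run_pipeline` chains every stage on either user-supplied files or a
self-contained synthetic study, and writes a JSON run report with the
counts and statistics of each stage. Reports are byte-identical for a
fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as dio
from . import network, proximity, sharing, synthetic
from .genesets import enrich, localization_breakdown
from .screen import ScreenConfig, screen_pairs, top_decile_filter

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class SimulationConfig:
    """Synthetic-study design: an NCI-60-like panel with planted structure.

    Defaults: a 60-cell-line panel, 30 drugs with two sensitivity genes each
    planted at correlation 0.8, genes drawn from a shared per-module pool so
    that drugs of the same module tend to share genes, a 6-module planted
    partition interactome over 300 genes, and annotation sharing at 0.8 on
    planted-gene-sharing drug pairs.
    """

    n_drugs: int = 30
    n_genes: int = 300
    n_cells: int = 60
    rho: float = 0.8
    genes_per_drug: int = 2
    pool_per_module: int = 6
    n_modules: int = 6
    p_in: float = 0.3
    p_out: float = 0.02
    n_classes: int = 6
    share_prob: float = 0.8


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full run.

    Any input path left as None is generated synthetically under ``workdir``
    according to ``sim``. The seed is mandatory: it drives the simulation,
    the permutation nulls, and the sampled background.
    """

    workdir: str = "dsgn_run"
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    R: int = 1000
    proximity_threshold: float = 4.0
    background_exact_cap: int = proximity.EXACT_BACKGROUND_CAP
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    expr_path: str | None = None
    act_path: str | None = None
    ppi_path: str | None = None
    drug_class_path: str | None = None
    side_effect_path: str | None = None
    pathways_path: str | None = None
    localization_path: str | None = None
    targets_path: str | None = None


def simulate_study(sim: SimulationConfig, seed: int):
    """Generate a coherent synthetic study with planted ground truth.

    Each drug is assigned to an interactome module and draws its planted
    sensitivity genes from a small per-module pool (so same-module drugs
    share genes); its target gene is another gene of the same module.
    Returns (expr, act, truth, ppi, annotations).
    """
    import numpy as np

    expr = synthetic.gen_expression(sim.n_genes, sim.n_cells, seed)
    ppi = synthetic.gen_ppi(sim.n_genes, sim.n_modules, sim.p_in, sim.p_out, seed + 1)
    module_of = synthetic.module_map(ppi)
    genes_by_module: dict[int, list[str]] = {}
    for g in sorted(module_of):
        genes_by_module.setdefault(module_of[g], []).append(g)

    rng = np.random.default_rng(seed + 2)
    planted: dict[str, set[str]] = {}
    targets: dict[str, set[str]] = {}
    for i, drug in enumerate(synthetic.drug_ids(sim.n_drugs)):
        m = i % sim.n_modules
        pool = genes_by_module[m][: sim.pool_per_module]
        k = min(sim.genes_per_drug, len(pool))
        planted[drug] = set(rng.choice(pool, size=k, replace=False))
        rest = [g for g in genes_by_module[m] if g not in planted[drug]]
        targets[drug] = {rest[int(rng.integers(len(rest)))]} if rest else set(planted[drug])

    act, truth = synthetic.gen_drug_activity(expr, planted, sim.rho, seed + 3, targets=targets)
    truth.module_of_gene = module_of
    ann = synthetic.gen_annotations(truth, sim.n_classes, sim.share_prob, seed + 4)
    return expr, act, truth, ppi, ann


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute screen → filter → build → project → sharing tests → proximity
    → overlap/enrichment, writing per-stage outputs and a JSON report under
    ``cfg.workdir``. Idempotent for a fixed config and seed."""
    workdir = Path(cfg.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config": {"R": cfg.R, "threshold": cfg.proximity_threshold}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return deco

    # --- inputs -----------------------------------------------------------
    @stage("inputs")
    def inputs():
        if cfg.expr_path and cfg.act_path:
            expr = dio.read_matrix(cfg.expr_path)
            act = dio.read_matrix(cfg.act_path)
            truth = None
            ppi = dio.read_edge_list(cfg.ppi_path) if cfg.ppi_path else None
            ann = None
        else:
            expr, act, truth, ppi, ann = simulate_study(cfg.sim, cfg.seed)
            dio.write_matrix(expr, workdir / "expression.tsv", "gene")
            dio.write_matrix(act, workdir / "activity.tsv", "drug")
            dio.write_edge_list(ppi, workdir / "ppi.tsv")
            dio.write_gmt(ann.pathways, workdir / "pathways.gmt")
            dio.write_labels(ann.drug_classes, workdir / "drug_classes.tsv", ("drug", "class"))
            dio.write_labels(ann.side_effects, workdir / "side_effects.tsv", ("drug", "term"))
            dio.write_labels({g: {c} for g, c in ann.localization.items()}, workdir / "localization.tsv", ("gene", "class"))
            dio.write_bipartite_pairs(truth.planted_pairs, workdir / "planted_pairs.tsv")
        return expr, act, truth, ppi, ann

    expr, act, truth, ppi, ann = inputs

    drug_classes = dio.read_labels(cfg.drug_class_path) if cfg.drug_class_path else (ann.drug_classes if ann else {})
    side_effects = dio.read_labels(cfg.side_effect_path) if cfg.side_effect_path else (ann.side_effects if ann else {})
    pathways = dio.read_gmt(cfg.pathways_path) if cfg.pathways_path else (ann.pathways if ann else {})
    localization = (
        {g: next(iter(s)) for g, s in dio.read_labels(cfg.localization_path).items()}
        if cfg.localization_path
        else (ann.localization if ann else {})
    )
    targets = (
        {d: set(v) for d, v in dio.read_labels(cfg.targets_path).items()}
        if cfg.targets_path
        else (truth.targets_of_drug if truth else {})
    )
    report["inputs"] = {
        "n_genes": int(expr.shape[0]),
        "n_drugs": int(act.shape[0]),
        "n_cells": int(expr.shape[1]),
        "synthetic": truth is not None,
    }

    # --- screen -----------------------------------------------------------
    @stage("screen")
    def screened():
        gated = screen_pairs(expr, act, cfg.screen)
        retained = top_decile_filter(gated, cfg.screen)
        dio.write_records(gated, workdir / "gated_pairs.tsv")
        dio.write_records(retained, workdir / "retained_pairs.tsv")
        return gated, retained

    gated, retained = screened
    report["screen"] = {"gated_pairs": len(gated), "retained_pairs": len(retained)}
    if not retained:
        report["screen"]["note"] = "no pairs passed the gate; downstream stages skipped"
        _write_report(report, workdir)
        return report

    # --- build ------------------------------------------------------------
    @stage("build")
    def built():
        bip = network.build_bipartite(retained)
        stats = {
            "nodes": bip.n_nodes,
            "drugs": len(bip.drug_nodes),
            "genes": len(bip.gene_nodes),
            "edges": len(bip.edges),
        }
        for side in ("drug", "gene"):
            hist = network.degree_histogram(bip, side)
            try:
                fit = network.powerlaw_fit(hist)
                stats[f"{side}_powerlaw"] = {"slope": fit.slope, "r_squared": fit.r_squared}
            except ValueError:
                stats[f"{side}_powerlaw"] = None
        return bip, stats

    bip, build_stats = built
    report["build"] = build_stats

    # --- project ----------------------------------------------------------
    @stage("project")
    def projected():
        ddn = network.project(bip, "drug")
        sgn = network.project(bip, "gene")
        return ddn, sgn

    ddn, sgn = projected
    report["project"] = {
        "ddn_nodes": len(ddn.nodes),
        "ddn_edges": len(ddn.edges),
        "sgn_nodes": len(sgn.nodes),
        "sgn_edges": len(sgn.edges),
    }

    # --- sharing tests ----------------------------------------------------
    @stage("sharing")
    def shared():
        out = {}
        if drug_classes and len(ddn.edges) and len(drug_classes) >= 3:
            res = sharing.label_sharing_test(
                ddn.edge_set, sharing.atc_top_level(drug_classes), R=cfg.R, seed=cfg.seed + 10
            )
            out["atc"] = res.summary()
        if side_effects and len(ddn.edges):
            connected = sharing.shared_label_counts(ddn.edge_set, side_effects)
            import itertools

            background = sharing.shared_label_counts(
                set(itertools.combinations(sorted(side_effects), 2)), side_effects
            )
            out["side_effects"] = {
                "rank_sum_p": sharing.rank_sum_compare(connected, background),
                "connected_pairs": len(connected),
                "background_pairs": len(background),
            }
        if pathways and len(sgn.edges):
            res = sharing.same_pathway_pair_test(sgn.edge_set, pathways, R=cfg.R, seed=cfg.seed + 11)
            out["pathway_pairs"] = res.summary()
        return out

    report["sharing"] = shared

    # --- proximity --------------------------------------------------------
    @stage("proximity")
    def proximal():
        out = {}
        if ppi is None:
            return out
        background = proximity.background_distances(
            ppi, exact_cap=cfg.background_exact_cap, seed=cfg.seed + 12
        )
        out["background"] = background.summary()
        sens_by_drug: dict[str, set[str]] = {}
        for r in retained:
            sens_by_drug.setdefault(r.drug_id, set()).add(r.gene_id)
        within_means = []
        for drug, genes in sorted(sens_by_drug.items()):
            if len(genes & set(ppi.nodes)) >= 2:
                dist = proximity.within_set_distances(ppi, genes)
                if dist.n_pairs:
                    within_means.append(dist.mean)
            else:
                logger.info("drug %s: fewer than 2 sensitivity genes in the interactome", drug)
        out["within_drug"] = {
            "n_drugs": len(within_means),
            "mean_of_means": (sum(within_means) / len(within_means)) if within_means else None,
        }
        if targets:
            per_drug = proximity.cross_set_distance_per_drug(ppi, sens_by_drug, targets)
            below = proximity.drugs_below_threshold(per_drug, cfg.proximity_threshold)
            means = [d.mean for d in per_drug.values() if d.n_pairs]
            out["sens_to_target"] = {
                "n_drugs": len(per_drug),
                "mean_path": (sum(means) / len(means)) if means else None,
                "drugs_below_threshold": len(below),
            }
        return out

    report["proximity"] = proximal

    # --- gene-set statistics ----------------------------------------------
    @stage("genesets")
    def genesets_stage():
        out = {}
        sens_genes = set(bip.gene_nodes)
        if localization:
            breakdown = localization_breakdown(sens_genes, localization)
            out["localization"] = {c: {"count": n, "percent": p} for c, (n, p) in breakdown.items()}
        if pathways:
            universe = set(expr.index)
            rows = enrich(sens_genes & universe, pathways, universe)
            out["enrichment"] = [
                {"term": r.term, "overlap": r.overlap, "p": r.p_value, "fdr": r.fdr} for r in rows[:10]
            ]
        return out

    report["genesets"] = genesets_stage
    _write_report(report, workdir)
    return report


def _write_report(report: dict, workdir: Path) -> None:
    with open(workdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
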