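"""Synthetic cell-line panels, drug activities, modular interactomes and annotations.

Every downstream stage of the pipeline (screen, network build, sharing tests,
proximity) is exercised on data generated here, with the planted structure
recorded in :class:`PanelTruth` so that recovery can be measured against a
known ground truth.

The generators emulate an NCI-60-style design: a panel of cell lines (default
60) profiled for gene expression, drug activities constructed so that each
planted (drug, gene) pair has a target Pearson correlation ``rho``, a
planted-partition protein-interaction graph whose modules stand in for
pathways, and annotation tables (drug classes, side effects, pathways,
subcellular localization) in which drugs that share planted sensitivity genes
preferentially share labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: The six fixed subcellular-localization classes. "unknown" is a real label,
#: not a missing value.
LOCALIZATION_CLASSES = (
    "membrane",
    "cytoplasm",
    "organelles",
    "nucleus",
    "exterior",
    "unknown",
)


@dataclass
class PanelTruth:
    """Ground truth of a synthetic drug-activity panel.

    Attributes
    ----------
    planted_pairs : set of (drug_id, gene_id)
        The drug–gene associations built into the activity matrix.
    target_rho : float
        Correlation planted for each pair, strictly in (0, 1). Realized
        per-pair correlation equals ``rho`` in expectation only for drugs
        with a single planted gene; it shrinks as the planted set grows.
    n_cells : int
        Panel size (number of cell lines), at least 4.
    module_of_gene : dict
        gene_id -> module id, filled in by :func:`gen_ppi` callers.
    targets_of_drug : dict
        drug_id -> set of target gene ids (for proximity analyses).
    """

    planted_pairs: set[tuple[str, str]]
    target_rho: float
    n_cells: int
    module_of_gene: dict[str, int] = field(default_factory=dict)
    targets_of_drug: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.target_rho < 1.0):
            raise ValueError(f"target_rho must be in (0, 1), got {self.target_rho}")
        if self.n_cells < 4:
            raise ValueError(f"n_cells must be >= 4, got {self.n_cells}")

    def genes_of_drug(self) -> dict[str, set[str]]:
        """Planted sensitivity genes grouped by drug."""
        out: dict[str, set[str]] = {}
        for d, g in self.planted_pairs:
            out.setdefault(d, set()).add(g)
        return out


def gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def drug_ids(n: int) -> list[str]:
    return [f"d{i:03d}" for i in range(n)]


def cell_ids(n: int) -> list[str]:
    return [f"cell{i:02d}" for i in range(n)]


def gen_expression(n_genes: int, n_cells: int, seed: int) -> pd.DataFrame:
    """Independent standard-normal expression, rows = genes, columns = cell lines.

    Reproducible for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if n_cells < 4:
        raise ValueError(f"n_cells must be >= 4, got {n_cells}")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_genes, n_cells))
    return pd.DataFrame(data, index=gene_ids(n_genes), columns=cell_ids(n_cells))


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def gen_drug_activity(
    expr: pd.DataFrame,
    planted: dict[str, set[str]],
    rho: float,
    seed: int,
    targets: dict[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, PanelTruth]:
    """Drug activities with planted gene correlations.

    For each drug the activity across cell lines is
    ``rho * s + sqrt(1 - rho^2) * noise`` where ``s`` is the standardized
    mean of the drug's planted genes' standardized expression. With one
    planted gene the expected Pearson correlation between activity and that
    gene is ``rho``; drugs with an empty planted set get pure noise.

    Parameters
    ----------
    expr : DataFrame
        Gene-expression matrix (genes x cells) as from :func:`gen_expression`.
    planted : dict
        drug_id -> set of gene ids to plant; the set may be empty.
    rho : float
        Target correlation, strictly in (0, 1).
    seed : int
        Seed for the noise draws.
    targets : dict, optional
        drug_id -> target gene set, recorded verbatim in the returned truth.

    Returns
    -------
    (activity, truth) : (DataFrame, PanelTruth)
        Activity matrix (drugs x cells) and the construction record.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must be in the open interval (0, 1), got {rho}")
    for drug, genes in planted.items():
        unknown = set(genes) - set(expr.index)
        if unknown:
            raise KeyError(f"planted genes not in expression matrix for {drug}: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n_cells = expr.shape[1]
    rows = []
    drugs = sorted(planted)
    for drug in drugs:
        genes = sorted(planted[drug])
        noise = rng.standard_normal(n_cells)
        if genes:
            z = np.vstack([_standardize(expr.loc[g].to_numpy()) for g in genes])
            signal = _standardize(z.mean(axis=0))
            act = rho * signal + np.sqrt(1.0 - rho**2) * noise
        else:
            act = noise
        rows.append(act)

    activity = pd.DataFrame(np.vstack(rows), index=drugs, columns=expr.columns)
    truth = PanelTruth(
        planted_pairs={(d, g) for d in drugs for g in planted[d]},
        target_rho=rho,
        n_cells=n_cells,
        targets_of_drug={d: set(v) for d, v in (targets or {}).items()},
    )
    return activity, truth


def gen_ppi(
    n_genes: int,
    n_modules: int,
    p_in: float,
    p_out: float,
    seed: int,
    genes: list[str] | None = None,
) -> nx.Graph:
    """Planted-partition undirected simple graph.

    Genes are split evenly into ``n_modules`` modules (remainder genes go to
    the last module); within-module edges appear with probability ``p_in``,
    between-module edges with probability ``p_out``. Each node carries a
    ``module`` attribute. No self-loops or parallel edges.
    """
    if n_modules < 1:
        raise ValueError(f"n_modules must be >= 1, got {n_modules}")
    if not (p_in > p_out):
        raise ValueError(f"p_in ({p_in}) must exceed p_out ({p_out}); planted structure unrecoverable")
    if genes is None:
        genes = gene_ids(n_genes)
    elif len(genes) != n_genes:
        raise ValueError("len(genes) must equal n_genes")

    per = n_genes // n_modules
    module_of: dict[str, int] = {}
    for i, g in enumerate(genes):
        module_of[g] = min(i // per, n_modules - 1) if per > 0 else n_modules - 1

    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    graph.add_nodes_from((g, {"module": module_of[g]}) for g in genes)
    for u, v in itertools.combinations(genes, 2):
        p = p_in if module_of[u] == module_of[v] else p_out
        if p >= 1.0 or rng.random() < p:
            graph.add_edge(u, v)
    return graph


def module_map(graph: nx.Graph) -> dict[str, int]:
    """gene -> module id from a graph produced by :func:`gen_ppi`."""
    return {g: int(d["module"]) for g, d in graph.nodes(data=True) if "module" in d}


@dataclass
class AnnotationTables:
    """Synthetic annotation bundle.

    drug_classes and side_effects map drug -> label set; pathways is a
    GMT-style dict of pathway name -> gene set; localization maps every gene
    to one of the six fixed classes.
    """

    drug_classes: dict[str, set[str]]
    side_effects: dict[str, set[str]]
    pathways: dict[str, set[str]]
    localization: dict[str, str]


def _sharing_drug_pairs(truth: PanelTruth) -> set[tuple[str, str]]:
    by_drug = truth.genes_of_drug()
    pairs = set()
    for a, b in itertools.combinations(sorted(by_drug), 2):
        if by_drug[a] & by_drug[b]:
            pairs.add((a, b))
    return pairs


def gen_annotations(
    truth: PanelTruth,
    n_classes: int,
    share_prob: float,
    seed: int,
    n_side_effects: int = 30,
) -> AnnotationTables:
    """Annotation tables with sharing planted on planted-gene-sharing drugs.

    Drugs sharing at least one planted gene are assigned the same class label
    with probability ``share_prob`` (via a union of sharing components);
    otherwise labels are uniform over ``n_classes`` classes. The pathway
    table exposes each interactome module (when ``truth.module_of_gene`` is
    populated) as a pathway containing its genes. The side-effect table gives
    each drug a random subset of terms plus extra shared terms between
    planted-gene-sharing drugs at rate ``share_prob``. Localization assigns
    each gene one of the six fixed classes uniformly.
    """
    if n_classes < 1:
        raise ValueError(f"n_classes must be >= 1, got {n_classes}")
    if not (0.0 <= share_prob <= 1.0):
        raise ValueError(f"share_prob must be in [0, 1], got {share_prob}")

    rng = np.random.default_rng(seed)
    drugs = sorted({d for d, _ in truth.planted_pairs} | set(truth.targets_of_drug))
    genes = sorted({g for _, g in truth.planted_pairs} | set(truth.module_of_gene))
    classes = [f"C{i:02d}" for i in range(n_classes)]

    # Base: uniform class per drug; then merge planted-sharing pairs (kept
    # with prob share_prob) into components so every kept pair shares a label.
    drug_classes = {d: {classes[rng.integers(n_classes)]} for d in drugs}
    kept = nx.Graph()
    for a, b in sorted(_sharing_drug_pairs(truth)):
        if rng.random() < share_prob:
            kept.add_edge(a, b)
    for comp in nx.connected_components(kept):
        label = classes[rng.integers(n_classes)]
        for d in comp:
            drug_classes[d] = {label}

    terms = [f"SE{i:03d}" for i in range(n_side_effects)]
    side_effects: dict[str, set[str]] = {}
    for d in drugs:
        k = int(rng.integers(1, max(2, n_side_effects // 5)))
        side_effects[d] = set(rng.choice(terms, size=k, replace=False))
    for a, b in sorted(_sharing_drug_pairs(truth)):
        if rng.random() < share_prob:
            extra = terms[int(rng.integers(n_side_effects))]
            side_effects[a].add(extra)
            side_effects[b].add(extra)

    pathways: dict[str, set[str]] = {}
    for g, m in truth.module_of_gene.items():
        pathways.setdefault(f"module{m:02d}", set()).add(g)

    localization = {g: LOCALIZATION_CLASSES[rng.integers(len(LOCALIZATION_CLASSES))] for g in genes}
    return AnnotationTables(drug_classes, side_effects, pathways, localization)
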