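"""Bipartite drug–gene network, one-mode projections, degree statistics.

The drug-sensitivity gene network (DSGN) is a bipartite graph: drugs on one
side, sensitivity genes on the other, an edge wherever the screen retained
the pair. Projecting onto one side yields the drug–drug network (DDN) or the
sensitivity-gene network (SGN): two same-side nodes are connected iff they
share at least one neighbor on the other side, with the shared-neighbor
count as edge weight. Nodes without any projected edge are excluded from the
projection's node set.

Degree distributions are summarized by an ordinary least-squares fit of
log10(count) on log10(degree) — a reporting device for approximate power-law
behaviour, not a rigorous tail estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .screen import CorrelationRecord


@dataclass(frozen=True)
class BipartiteNetwork:
    """Two disjoint node sets plus drug–gene edges."""

    drug_nodes: frozenset[str]
    gene_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        overlap = self.drug_nodes & self.gene_nodes
        if overlap:
            raise ValueError(f"node sets not disjoint: {sorted(overlap)[:5]}")
        for d, g in self.edges:
            if d not in self.drug_nodes or g not in self.gene_nodes:
                raise ValueError(f"edge ({d}, {g}) references undeclared node")

    @property
    def n_nodes(self) -> int:
        return len(self.drug_nodes) + len(self.gene_nodes)

    def neighbors_of_drug(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {d: set() for d in self.drug_nodes}
        for d, g in self.edges:
            out[d].add(g)
        return out

    def neighbors_of_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {g: set() for g in self.gene_nodes}
        for d, g in self.edges:
            out[g].add(d)
        return out


@dataclass(frozen=True)
class ProjectionNetwork:
    """One-mode projection: unordered same-side pairs weighted by shared neighbors."""

    nodes: frozenset[str]
    edges: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-edge on {u}")
            if w < 1:
                raise ValueError(f"edge ({u}, {v}) has weight {w} < 1")

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("power-law fit needs >= 2 distinct degrees")


def build_bipartite(records: list[CorrelationRecord]) -> BipartiteNetwork:
    """One node per distinct drug and gene, one edge per distinct pair.

    Duplicate records collapse to a single edge; an identifier appearing on
    both sides violates bipartiteness and is an error.
    """
    if not records:
        raise ValueError("cannot build a network from zero records")
    drugs = frozenset(r.drug_id for r in records)
    genes = frozenset(r.gene_id for r in records)
    return BipartiteNetwork(drugs, genes, frozenset((r.drug_id, r.gene_id) for r in records))


def project(bip: BipartiteNetwork, side: str) -> ProjectionNetwork:
    """One-mode projection onto ``side`` ("drug" or "gene").

    Two nodes are connected iff they share >= 1 neighbor on the other side;
    weight = shared-neighbor count. Nodes with no projected edge are
    excluded (the paper-style DDN keeps only sharing drugs).
    """
    if side not in ("drug", "gene"):
        raise ValueError(f"side must be 'drug' or 'gene', got {side!r}")
    nbrs = bip.neighbors_of_drug() if side == "drug" else bip.neighbors_of_gene()
    edges: dict[tuple[str, str], int] = {}
    for u, v in itertools.combinations(sorted(nbrs), 2):
        shared = len(nbrs[u] & nbrs[v])
        if shared:
            edges[(u, v)] = shared
    nodes = frozenset(itertools.chain.from_iterable(edges))
    return ProjectionNetwork(nodes, edges)


def degree_histogram(
    net: BipartiteNetwork | ProjectionNetwork,
    side: str | None = None,
) -> dict[int, int]:
    """Counts over observed degrees >= 1; sums to the number of nodes tallied.

    For a bipartite network ``side`` restricts to one node set; a projection
    ignores ``side``.
    """
    if isinstance(net, BipartiteNetwork):
        if side == "drug":
            deg = {d: len(v) for d, v in net.neighbors_of_drug().items()}
        elif side == "gene":
            deg = {g: len(v) for g, v in net.neighbors_of_gene().items()}
        else:
            deg = {d: len(v) for d, v in net.neighbors_of_drug().items()}
            deg.update({g: len(v) for g, v in net.neighbors_of_gene().items()})
    else:
        deg = net.degree()
    if not deg:
        raise ValueError("empty network")
    hist: dict[int, int] = {}
    for d in deg.values():
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def powerlaw_fit(hist: dict[int, int]) -> PowerLawFit:
    """OLS of log10(count) on log10(degree) over degrees with count >= 1."""
    pts = [(k, c) for k, c in hist.items() if c >= 1 and k >= 1]
    if len(pts) < 2:
        raise ValueError(f"fit undefined: need >= 2 distinct degrees, got {len(pts)}")
    x = np.log10([k for k, _ in pts])
    y = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(float(slope), max(0.0, min(1.0, r2)), len(pts))
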