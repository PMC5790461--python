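"""Shortest-path proximity statistics over an unweighted interactome.

Hop distances (BFS; equivalent to Dijkstra on unit weights) drive four
analyses: distance distributions within a drug's sensitivity-gene set,
the all-pairs background distribution, per-drug sensitivity-to-target
distance distributions with threshold sets, and first-neighbor ego
subnetwork extraction. Unreachable pairs are excluded from means and
counted separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: Graphs up to this many nodes get an exact all-pairs background; larger
#: graphs are estimated by seeded uniform pair sampling.
EXACT_BACKGROUND_CAP = 2000
#: Sample size for the sampled background.
BACKGROUND_SAMPLES = 1_000_000


@dataclass
class DistanceDistribution:
    """Histogram of hop distances over a pair population."""

    counts: dict[int, int]
    excluded_infinite: int = 0
    sampled: bool = False
    n_sampled_pairs: int = 0

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def mean(self) -> float:
        if self.n_pairs == 0:
            return float("nan")
        return sum(d * c for d, c in self.counts.items()) / self.n_pairs

    def proportion_at_most(self, d_max: int) -> float:
        if self.n_pairs == 0:
            return float("nan")
        return sum(c for d, c in self.counts.items() if d <= d_max) / self.n_pairs

    def summary(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mean": self.mean,
            "excluded_infinite": self.excluded_infinite,
            "sampled": self.sampled,
        }


def shortest_paths_from(g: nx.Graph, source: str) -> dict[str, int]:
    """Hop distances from ``source``; unreachable nodes are absent."""
    if source not in g:
        raise KeyError(f"source {source!r} not in graph")
    return dict(nx.single_source_shortest_path_length(g, source))


def within_set_distances(g: nx.Graph, genes: set[str]) -> DistanceDistribution:
    """Distance distribution over all unordered pairs of mapped set members.

    Members absent from the graph are dropped (and logged); at least two
    must map. Unreachable pairs go to ``excluded_infinite``.
    """
    mapped = sorted(set(genes) & set(g.nodes))
    dropped = len(set(genes)) - len(mapped)
    if dropped:
        logger.info("within_set_distances: %d of %d genes not in graph, dropped", dropped, len(set(genes)))
    if len(mapped) < 2:
        raise ValueError(f"need >= 2 genes mapped into the graph, got {len(mapped)} (dropped {dropped})")
    counts: dict[int, int] = {}
    infinite = 0
    for i, src in enumerate(mapped):
        dist = shortest_paths_from(g, src)
        for tgt in mapped[i + 1 :]:
            if tgt in dist:
                counts[dist[tgt]] = counts.get(dist[tgt], 0) + 1
            else:
                infinite += 1
    return DistanceDistribution(dict(sorted(counts.items())), excluded_infinite=infinite)


def background_distances(
    g: nx.Graph,
    exact_cap: int = EXACT_BACKGROUND_CAP,
    n_samples: int = BACKGROUND_SAMPLES,
    seed: int = 0,
) -> DistanceDistribution:
    """Distribution over all unordered node pairs.

    Exact all-pairs BFS up to ``exact_cap`` nodes; above that, uniform
    random pair sampling (seeded), with the sample size reported.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    counts: dict[int, int] = {}
    infinite = 0
    if n <= exact_cap:
        for i, src in enumerate(nodes):
            dist = shortest_paths_from(g, src)
            for tgt in nodes[i + 1 :]:
                if tgt in dist:
                    counts[dist[tgt]] = counts.get(dist[tgt], 0) + 1
                else:
                    infinite += 1
        return DistanceDistribution(dict(sorted(counts.items())), excluded_infinite=infinite)

    rng = np.random.default_rng(seed)
    cache: dict[str, dict[str, int]] = {}
    drawn = 0
    while drawn < n_samples:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        drawn += 1
        u, v = nodes[i], nodes[j]
        if u not in cache:
            cache[u] = shortest_paths_from(g, u)
        d = cache[u].get(v)
        if d is None:
            infinite += 1
        else:
            counts[d] = counts.get(d, 0) + 1
    return DistanceDistribution(
        dict(sorted(counts.items())),
        excluded_infinite=infinite,
        sampled=True,
        n_sampled_pairs=n_samples,
    )


def cross_set_distance_per_drug(
    g: nx.Graph,
    sens: dict[str, set[str]],
    targ: dict[str, set[str]],
) -> dict[str, DistanceDistribution]:
    """Per drug, distances over all (sensitivity gene, target gene) pairs.

    A gene in both sets contributes distance 0 (the sensitivity gene and the
    target gene are the same). Drugs missing from either map, or with no
    gene mapping into the graph on either side, are skipped with a warning.
    """
    out: dict[str, DistanceDistribution] = {}
    for drug in sorted(set(sens) | set(targ)):
        if drug not in sens or drug not in targ:
            logger.warning("drug %s missing from %s map; skipped", drug, "sensitivity" if drug not in sens else "target")
            continue
        s = sorted(set(sens[drug]) & set(g.nodes))
        t = sorted(set(targ[drug]) & set(g.nodes))
        if not s or not t:
            logger.warning("drug %s: no mapped %s genes; skipped", drug, "sensitivity" if not s else "target")
            continue
        counts: dict[int, int] = {}
        infinite = 0
        for sg in s:
            dist = shortest_paths_from(g, sg)
            for tg in t:
                d = 0 if tg == sg else dist.get(tg)
                if d is None:
                    infinite += 1
                else:
                    counts[d] = counts.get(d, 0) + 1
        out[drug] = DistanceDistribution(dict(sorted(counts.items())), excluded_infinite=infinite)
    return out


def drugs_below_threshold(per_drug: dict[str, DistanceDistribution], t: float) -> set[str]:
    """Drugs whose mean sensitivity-to-target distance is strictly below t."""
    if t <= 0:
        raise ValueError(f"threshold must be > 0, got {t}")
    return {d for d, dist in per_drug.items() if dist.n_pairs > 0 and dist.mean < t}


def ego_subgraph(g: nx.Graph, center: str) -> nx.Graph:
    """Induced subgraph on a node and its first neighbors.

    Includes neighbor–neighbor edges (the subgraph is induced).
    """
    if center not in g:
        raise KeyError(f"center {center!r} not in graph")
    return nx.Graph(nx.ego_graph(g, center, radius=1))
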