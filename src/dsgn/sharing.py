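"""Permutation and rank-sum tests for annotation sharing on projected pairs.

Connected drug pairs in the drug–drug projection are asked whether they
share an ATC-style class label more often than the same number of random
drug pairs (1000 permutations by default, empirical p with the add-one
convention (b+1)/(R+1)); connected gene pairs in the gene projection are
asked the same about pathway co-membership. Side-effect sharing is compared
as counts per pair between connected pairs and all pairs via a one-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

# Below this many candidate pairs the null enumerates them all and samples
# indices without replacement; above, it rejection-samples distinct pairs.
_ENUMERATE_CAP = 200_000

Pair = tuple[str, str]


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its permutation null sample, and the empirical p."""

    observed: int
    null_values: tuple[int, ...]
    empirical_p: float

    @property
    def R(self) -> int:
        return len(self.null_values)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if self.R > 1 else 0.0

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "R": self.R,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "empirical_p": self.empirical_p,
        }


def _share(labels: dict[str, set[str]], a: str, b: str) -> bool:
    la = labels.get(a)
    lb = labels.get(b)
    return bool(la and lb and not set(la).isdisjoint(lb))


def count_label_sharing_pairs(pairs: set[Pair], labels: dict[str, set[str]]) -> int:
    """Number of pairs whose two members have >= 1 label in common.

    Unlabeled members never share.
    """
    return sum(1 for a, b in pairs if _share(labels, a, b))


def permutation_null(
    universe: set[str],
    n_pairs: int,
    labels: dict[str, set[str]],
    R: int = 1000,
    seed: int = 0,
) -> list[int]:
    """R replicates of the sharing count over random distinct unordered pairs.

    Each replicate draws ``n_pairs`` distinct unordered pairs uniformly from
    ``universe`` (no self-pairs) and counts label-sharing pairs. Seeded and
    reproducible.
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    ids = sorted(universe)
    m = len(ids)
    total = m * (m - 1) // 2
    if n_pairs > total:
        raise ValueError(f"cannot draw {n_pairs} distinct pairs from a universe of {m} ids ({total} possible)")
    rng = np.random.default_rng(seed)

    if total <= _ENUMERATE_CAP:
        all_pairs = list(itertools.combinations(ids, 2))
        flags = np.fromiter((_share(labels, a, b) for a, b in all_pairs), dtype=bool, count=total)
        return [int(flags[rng.choice(total, size=n_pairs, replace=False)].sum()) for _ in range(R)]

    memo: dict[tuple[int, int], bool] = {}
    out = []
    for _ in range(R):
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_pairs:
            i, j = rng.integers(m), rng.integers(m)
            if i != j:
                chosen.add((min(i, j), max(i, j)))
        c = 0
        for key in chosen:
            if key not in memo:
                memo[key] = _share(labels, ids[key[0]], ids[key[1]])
            c += memo[key]
        out.append(c)
    return out


def empirical_p(observed: int, null_values: list[int]) -> float:
    """Add-one empirical p: (#{null >= observed} + 1) / (R + 1)."""
    if not len(null_values):
        raise ValueError("null sample is empty")
    b = int(np.sum(np.asarray(null_values) >= observed))
    return (b + 1) / (len(null_values) + 1)


def label_sharing_test(
    pairs: set[Pair],
    labels: dict[str, set[str]],
    universe: set[str] | None = None,
    R: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Full permutation test: observed sharing vs the uniform-pair null.

    ``universe`` defaults to all labeled ids.
    """
    if universe is None:
        universe = set(labels)
    observed = count_label_sharing_pairs(pairs, labels)
    null = permutation_null(universe, len(pairs), labels, R=R, seed=seed)
    return PermutationResult(observed, tuple(null), empirical_p(observed, null))


def shared_label_counts(pairs: set[Pair], labels: dict[str, set[str]]) -> list[int]:
    """Per pair, the size of the members' label-set intersection (pair-id order)."""
    out = []
    for a, b in sorted(pairs):
        la = set(labels.get(a, ()))
        lb = set(labels.get(b, ()))
        out.append(len(la & lb))
    return out


def rank_sum_compare(connected_counts: list[int], background_counts: list[int]) -> float:
    """One-sided Wilcoxon rank-sum p for connected > background.

    Normal approximation with tie correction (the counts are small integers
    with heavy ties).
    """
    if not len(connected_counts) or not len(background_counts):
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        connected_counts, background_counts, alternative="greater", method="asymptotic"
    )
    return float(res.pvalue)


def atc_top_level(labels: dict[str, set[str]], level: int = 1) -> dict[str, set[str]]:
    """Truncate ATC-style codes to their leading ``level`` characters."""
    return {d: {c[:level] for c in cs} for d, cs in labels.items()}


def invert_collection(collection: dict[str, set[str]]) -> dict[str, set[str]]:
    """set-name -> members becomes member -> set of set-names."""
    out: dict[str, set[str]] = {}
    for name, members in collection.items():
        for g in members:
            out.setdefault(g, set()).add(name)
    return out


def same_pathway_pair_test(
    sgn_edges: set[Pair],
    pathways: dict[str, set[str]],
    universe: set[str] | None = None,
    R: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Do connected gene pairs co-occur in a pathway more than random pairs?

    Observed = count of edges whose two genes share >= 1 pathway; the null
    redraws that many random gene pairs R times from ``universe`` (default:
    all pathway-annotated genes).
    """
    labels = invert_collection(pathways)
    return label_sharing_test(sgn_edges, labels, universe=universe, R=R, seed=seed)
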