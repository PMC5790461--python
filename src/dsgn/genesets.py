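"""Hypergeometric overlap tests, gene-set enrichment with BH FDR, localization.

The overlap between the sensitivity-gene set and a reference gene set (e.g.
cancer genes, essential genes) is tested with the hypergeometric upper tail
P(X >= k). Enrichment against a GMT-style collection applies the same test
per term with Benjamini–Hochberg FDR control; an optional EASE mode
(overlap - 1 in the tail) gives the more conservative score some enrichment
tools report. The localization breakdown tallies genes over the six fixed
subcellular classes, reporting percentages rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import LOCALIZATION_CLASSES


@dataclass(frozen=True)
class OverlapTest:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_value: float


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    overlap: int
    term_size: int
    p_value: float
    fdr: float


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = universe size, K = reference-set size, n = query-set size,
    k = observed overlap. k = 0 gives p = 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent sizes: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K, n)={min(K, n)}]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_test(query: set[str], reference: set[str], universe: set[str]) -> OverlapTest:
    """Hypergeometric upper-tail test of |query ∩ reference| in ``universe``.

    Both sets are intersected with the universe before testing.
    """
    if not universe:
        raise ValueError("empty universe")
    q = query & universe
    r = reference & universe
    k = len(q & r)
    p = hypergeom_upper_tail(len(universe), len(r), len(q), k)
    return OverlapTest(len(universe), len(r), len(q), k, p)


def enrich(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
    ease: bool = False,
) -> list[EnrichmentRow]:
    """Per-term hypergeometric enrichment with Benjamini–Hochberg FDR.

    Terms are intersected with the universe; only terms overlapping the
    query appear, sorted by (p ascending, term name). ``ease`` subtracts one
    from the overlap in the tail (EASE-style conservative score).
    """
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    rows = []
    for term in sorted(collection):
        members = collection[term] & universe
        k = len(query & members)
        if k == 0 or not members:
            continue
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(len(universe), len(members), len(query), k_eff)
        rows.append((term, k, len(members), p))
    if not rows:
        return []
    _, fdrs, _, _ = multipletests([p for *_, p in rows], method="fdr_bh")
    out = [
        EnrichmentRow(term, k, size, p, float(q))
        for (term, k, size, p), q in zip(rows, fdrs)
    ]
    out.sort(key=lambda r: (r.p_value, r.term))
    return out


def _percent(count: int, total: int) -> float:
    pct = Decimal(count * 100) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def localization_breakdown(
    genes: set[str],
    loc: dict[str, str],
) -> dict[str, tuple[int, float]]:
    """Counts and percentages over the six fixed localization classes.

    Genes with no mapping (or a label outside the enumeration) fall into
    "unknown". Percentages are count/|genes| rounded half-up to 2 decimals;
    counts partition the input.
    """
    if not genes:
        return {c: (0, 0.0) for c in LOCALIZATION_CLASSES}
    counts = {c: 0 for c in LOCALIZATION_CLASSES}
    for g in genes:
        cls = loc.get(g, "unknown")
        if cls not in counts:
            cls = "unknown"
        counts[cls] += 1
    return {c: (n, _percent(n, len(genes))) for c, n in counts.items()}
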