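# Methods

## The screen

For drug d with activity vector a_d and gene g with expression vector x_g
over the same ordered cell-line panel, the association statistic is the
Pearson product-moment correlation r(a_d, x_g). Significance uses the exact
null distribution of t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom,
two-sided. The screen gate is |r| ≥ r_min and p < p_max with defaults
r_min = 0.5, p_max = 0.01; at n = 60 the correlation gate dominates (|r| =
0.5 has p ≈ 4.6·10⁻⁵), so the p threshold mainly matters for smaller or
missing-data panels. Missing values are handled per pair on the
complete-case intersection, with n_obs recording the count actually used; a
pair whose complete cases leave a constant vector is skipped because its
correlation is undefined (never silently zero).

The per-drug filter ranks a drug's gated pairs by |r| descending (ties
broken by p ascending, then gene id, for determinism), rounds the gated
count k up to r_d = 10·⌈k/10⌉, and retains min(k, r_d/10) pairs. The min
guard covers k ≤ 10, where the rule would otherwise retain one pair that
may not exist; every drug that enters keeps at least one pair. Note the
filter is *not* idempotent in general: a drug with k ∈ [11, 20] retains 2
pairs, and re-filtering those 2 retains 1. This is a property of the
ceiling-of-a-tenth rule itself; callers should apply the filter exactly
once, to the gated list.

## Networks

Retained pairs define a bipartite graph; duplicate pairs collapse, and an
identifier appearing on both sides is rejected. The one-mode projections
connect two same-side nodes iff they share at least one neighbor, with the
shared-neighbor count as weight; nodes with no projected edge are excluded
from the projection's node set (a drug whose sensitivity genes are private
to it has no place in a shared-gene network). Degree distributions are
summarized by ordinary least squares of log₁₀(count) on log₁₀(degree) over
degrees with count ≥ 1. This is a deliberate reporting device — simple,
reproducible, and comparable to slope/R² summaries in the literature — not
a maximum-likelihood tail estimator; with few distinct degrees R² is
expected to be low and the slope sensitive to the largest degrees.

## Permutation tests for annotation sharing

Given a set of connected pairs (DDN edges or SGN edges) and a label map
(drug → class labels, or gene → pathway memberships), the observed
statistic is the number of pairs whose members share ≥ 1 label. The null
redraws the same number of distinct unordered pairs uniformly from the
labeled universe, R = 1000 times, and the empirical p is (b+1)/(R+1) with
b = #{null ≥ observed}. The add-one convention avoids p = 0 and makes the
smallest attainable p equal 1/(R+1) ≈ 0.001 at R = 1000. Uniform pair
redrawing (rather than degree-preserving rewiring) is the design choice
here: it matches the plain reading of "randomized drug pairs" and asks the
weaker but well-defined question "do connected pairs share labels more
than arbitrary pairs?". Because the statistic is a small integer with
heavy ties, the test is mildly conservative: the realized type-I rate at
α = 0.05 sits slightly below 0.05.

Class labels are compared at the top level (first character) for ATC-style
codes, configurable. Side-effect sharing uses counts per pair (the size of
the two drugs' term-set intersection) compared between connected pairs and
all pairs over the annotated drugs with a one-sided Wilcoxon rank-sum test
(normal approximation with tie correction — the counts are small tied
integers, where the exact distribution is unavailable anyway).

## Interactome proximity

All distances are hop counts on a simple undirected graph (BFS, which on
unit weights is Dijkstra). Within-set distributions cover all unordered
pairs of set members mapped into the graph; unreachable pairs are excluded
from the mean and reported as a separate count; genes absent from the
interactome are dropped and logged. The all-pairs background is exact up to
2000 nodes; larger graphs are estimated from 10⁶ seeded uniform pair
samples, with the sampling flagged in the result. Per-drug
sensitivity-to-target distributions treat a gene in both sets as distance
0. The threshold set "drugs with mean distance < t" uses the per-drug
mean (strict inequality); an alternative reading — every pair below t —
would be stricter and is not implemented.

## Gene-set statistics

Overlap significance is the hypergeometric upper tail P(X ≥ k) with
universe N, reference size K, query size n, overlap k (scipy's stable
survival function; cross-checked against exhaustive enumeration for all
N ≤ 25 in the tests). Enrichment applies the same test per GMT term after
intersecting terms with the universe, then Benjamini–Hochberg FDR across
tested terms. An optional EASE mode subtracts one from the overlap in the
tail, reproducing the conservative variant some enrichment services use;
it is off by default. The default universe is the set of genes present in
the expression input. Localization percentages are reported rounded
half-up to two decimals (472 of 1057 → 44.65%).

## Synthetic data: what it emulates and what it cannot

`gen_expression` draws independent standard normals per gene and cell line
(default panel: 60 cell lines, mirroring an NCI-60-style design).
`gen_drug_activity` builds each drug's activity as ρ·s + √(1−ρ²)·ε, where
s is the standardized mean of the drug's planted genes' standardized
expression and ε is independent noise; with one planted gene the expected
sample correlation is ρ. With m planted genes the per-pair realized
correlation shrinks to roughly ρ/√m, because the planted genes are
independent — recall of the screen is therefore measured against planted,
not realized, correlation only in the single-gene design.

A structural consequence worth stating plainly: against independent genes,
a drug's squared correlations sum to at most 1, so at most ⌊1/r_min²⌋ = 4
genes can ever pass |r| ≥ 0.5 for one drug. After the top-10%·r_d filter,
every synthetic drug retains exactly one gene, and a gene-side projection
built from a filtered screen has no edges. Real expression panels are
heavily co-expressed, which is how real drugs acquire dozens of strong
correlates. The gene-network analyses (same-pathway pair test, within-drug
distance distributions) are therefore exercised on planted bipartite
structure directly; passing tests show the machinery is correct, not that
independent-noise panels produce rich gene networks — they provably
cannot.

`gen_ppi` is a planted-partition graph: genes split evenly into modules
(remainder to the last module), within-module edge probability p_in,
between-module p_out, p_in > p_out required. Defaults in the pipeline are
6 modules, p_in = 0.3, p_out = 0.02 — dense enough that modules are
connected, sparse enough that module membership dominates distances.
`gen_annotations` plants label sharing by merging drugs that share planted
genes into components (each kept with probability share_prob) and giving a
component one label; pathway sets mirror the interactome modules;
localization assigns each gene one of the six fixed classes uniformly
("unknown" is a real class, not missingness). Fixed seeds make every
generator bit-reproducible.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| r_min | 0.5 | correlation gate on |r| (dimensionless) |
| p_max | 0.01 | two-sided p gate |
| decile | 0.10 | fraction of r_d retained per drug |
| n_cells | 60 | panel size (cell lines) |
| ρ | 0.8 | planted drug–gene correlation |
| R | 1000 | permutation replicates |
| t | 4 | proximity threshold (hops) on the per-drug mean |
| exact background cap | 2000 nodes | above this, sample 10⁶ pairs |

Problem sizes in the test-suite and acceptance runs (50 drugs × 500 genes
for screen recall; 30 drugs, 200 calibration runs and 50 power runs at
R = 1000 for the sharing test; 10 × 50 planted-partition graph with 100
sampled sets for proximity) are the package's chosen study conditions:
large enough for stable rates, small enough to rerun anywhere.

## Known limitations

- No dose–response modelling, batch effects, or co-expression structure in
  the synthetic panels; see above for what that implies about gene-side
  projections.
- The power-law summary is descriptive OLS, not a Clauset-style estimator.
- Permutation nulls are uniform-pair, not degree-preserving.
- Identifiers are opaque strings; no symbol normalization or registry
  (DrugBank/ATC) lookups.
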