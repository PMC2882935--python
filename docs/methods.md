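# Methods

`funsimnet` turns a GO ontology plus protein annotations into a
quantitative picture of a proteome's functional space: pairwise
functional similarity scores, thresholded similarity networks and
their topology, connectivity-significant PPI subnetworks, functionally
coherent genome windows, GO-term overrepresentation, and a raw-score
implementation of homology-transfer function prediction (PFP-style).
This note records the models, the defaults and why, the numerical
choices, and what the synthetic data does and does not emulate.

## Ontology model and information content

The GO hierarchy is a directed acyclic graph with child→parent edges;
`is_a` and `part_of` are both treated as ancestor relations by default
(the relation whitelist is configurable), cross-namespace links and
obsolete terms are dropped at parse time, and each of the three
namespaces (BP, CC, MF) must have exactly one root.  Annotation corpora
follow the true path rule: every protein's term set is closed under
ancestors before any counting.  The information content of a term `c`
is its annotation frequency relative to the namespace root,
`p(c) = count(c) / count(root)`, with `p(root) = 1` exactly and `p`
monotone non-decreasing from child to parent.  Terms with zero
annotations have no defined `p`; any similarity involving them is an
error rather than a silent zero, because `ln p` is undefined.  Natural
logarithms are used throughout — ratios of logarithms are
base-invariant, and a single convention avoids drift between the
similarity and prediction components.

## Term and protein similarity

Term similarity is Schlicker's relevance measure: over the common
ancestors `c` of two terms, maximize

    sim(c1, c2) = max_c  (1 − p(c)) · 2 ln p(c) / (ln p(c1) + ln p(c2))

The `1 − p(c)` relevance weight discounts similarity inherited through
frequent (uninformative) ancestors.  A plain-Lin mode drops the weight;
only in that mode is a term's self-similarity exactly 1, which matters
for the exact identities below.  Two terms whose only common ancestor
is the root score 0 (the numerator vanishes); the root-vs-root 0/0 case
is defined as 0.  Values are clamped to [0, 1].

Protein-level category scores build the all-by-all term-similarity
matrix between the two proteins' annotation sets in one namespace.
The matrix rows and columns are the proteins' *direct* annotations —
ancestors enter only through the common-ancestor search.  Including the
closed sets as matrix rows (available via `use_closed=True`) inflates
the matrix with redundant near-duplicate rows and double-counts
ancestral agreement.  The row score is the mean of row maxima, the
column score the mean of column maxima, and the category GOscore
combines the two.  The combiner defaults to `max` (the funSim
convention); `mean` is available by configuration, and both are
symmetric under exchanging the two proteins.

The combined score over the three categories is the mean of squared
GOscores, each normalized by its maximum of 1:

    funSim = (BP² + CC² + MF²) / 3  ∈ [0, 1]

A category score exists only when both proteins carry annotations in
that namespace; funSim exists only when all three categories do.
Absent scores propagate as `NA` in the scored-pair table, never as 0.

## Functional similarity networks and topology

A similarity network connects two proteins when the selected score
(BP, CC, MF or funSim) is present and at or above a threshold; the
default threshold set is {0.80, 0.95, 0.99}.  Proteins whose scores
all fall below the threshold are kept as isolates so component
fractions are computed over the full protein set.

Topology statistics:

- **Clustering coefficient** of a node with `k ≥ 2` neighbors and `n`
  edges among them: `C = n / (k(k−1)/2)`; undefined below degree 2 and
  excluded from averages there.  The network's average clustering is
  the modularity measure.
- **Degree exponent γ**: ordinary least squares of `log P(k)` on
  `log k`, where `P(k)` is the fraction of degree-≥1 nodes with degree
  exactly `k`, raw (un-binned) frequencies, zero-count degrees
  excluded.  The fit's R² is always reported so a poor power-law fit is
  visible, and `γ = −slope`.
- **Clustering degree exponent β**: same fit on `C(k)`, the mean
  clustering per degree (`k ≥ 2`), over degrees with `C(k) > 0`.
  `β ≈ 1` is the signature of hierarchical modularity.

Degenerate inputs (a single distinct degree, an all-zero clustering
spectrum) raise errors at the fitting level and surface as absent
fields with a recorded reason in network summaries.  Maximum-likelihood
power-law fitting is deliberately out of scope; the straight-line
log-log fit is the estimator whose behavior the topology tables
describe.

Two deterministic constructions serve as fixtures with known
exponents: a Havel–Hakimi graph whose degree histogram is exactly
proportional to `k^−2` over degrees {1, 2, 4, 8} (the smallest integer
counts 64/16/4/1 realizing the law exactly, so the four-point log-log
fit is perfectly linear), and the replication-style hierarchical
network (complete 5-module, four copies per level, copied peripheral
nodes wired to the original hub) whose clustering spectrum follows
`C(k) ~ 1/k`; numerically the two-level construction fits β ≈ 1.14.

## PPI subnetworks and the randomization test

A centroid subnetwork is a protein, its interaction partners, and all
edges among them; its connectivity coefficient is `c_i = g_i / n_i`
(edges per node).  Self-interactions are tracked but excluded from
degrees, subnetwork edge counts and randomization — the statistics are
defined on simple-graph neighborhoods.

Significance is assessed against a degree-preserving null model:
the network is rewired by double edge swaps (10 attempted swaps per
edge, via igraph's C implementation, seeded and reproducible; the
graph stays simple and every node keeps its exact degree), the same
centroid's subnetwork is re-extracted from each of R randomized
networks (default R = 100), and

    t = (c_i − ν) / sqrt(s / R)

where ν and s are the mean and sample variance (divisor R − 1) of the
randomized coefficients.  The test is one-sided for enriched
connectivity with R − 1 degrees of freedom and α = 0.05; a two-sided
variant and population variance are config-exposed, since the exact
form of the published statistic is not recoverable.  Zero randomized
variance with `c_i` above ν is reported as significant with p = 0 and
a degeneracy flag rather than a division error.

## Genome windows

Chromosomes are scanned with fixed windows advanced by exactly one
fifth of the window size, so an interior gene falls in exactly five
windows.  Coordinates are 0-based half-open internally; the readers
accept 1-based inclusive TSV and GFF3 and convert.  A gene belongs to
a window when its start lies in the half-open interval — the simplest
deterministic rule; midpoint/overlap membership would change counts
only at window edges.  Windows are enumerated separately for plus,
minus and both strands.  Window sizes in the 10–30 kb range are
calibrated (in 5 kb steps) so both-strand windows average 8–10 genes.

A window's coherence is the mean pairwise score among its member genes
per score kind, over the pairs whose score is present; a window is
selected when any category mean exceeds 0.7 or the funSim mean exceeds
0.49 (strict inequalities).  Selected windows are tested for term
overrepresentation under the known and the known-plus-predicted
annotation states, and the annotation gain is the percentage increase
in unique overrepresented terms, with previously unannotated windows
(no overrepresented term before) counted separately instead of
dividing by zero.

## Overrepresentation and FDR

For a term carried by `m` of the `N` annotated proteins of the
proteome and `k` of the `n` annotated proteins of a cluster, the raw p
value is the hypergeometric upper tail `P(X ≥ k)` (computed by scipy
in log space).  "Annotated" is always per the tested term's namespace.
Terms are counted on ancestor-closed sets, so parents of enriched
children are tested too.  Multiple testing over the `q` unique terms
annotated to cluster proteins is controlled with Benjamini–Hochberg
step-up FDR (sort ascending, `p_adj(i) = min_{j≥i} p(j)·q/j`, capped
at 1); Bonferroni-style `p·q` is available by configuration.  BH is
the standard FDR procedure and the package default; the two differ
only in conservatism, not in the test itself.

## PFP raw scoring

For a query with homology hits `i` (E-values from a precomputed
search), every GO term `f_a` receives

    s(f_a) = Σ_i Σ_{f_j ∈ terms(i)}  max(0, −ln E_i + b) · P(f_a | f_j)

with `b = ln 125`, so hits up to E-value 125 contribute and a hit at
exactly 125 contributes zero; weaker hits are clipped to zero rather
than allowed to penalize.  The conditional probability

    P(f_a | f_j) = (c(f_a, f_j) + ε) / (c(f_j) + μ·ε),   ε = 0.05

uses co-assignment counts over a reference corpus.  The counts default
to *direct* assignments — annotation databases assert specific terms,
and counting closed sets would make every ancestor co-occur at least
as often as its descendants, so ancestors would dominate every ranking
by construction.  Closed counting is available via `closed=True`.
Candidate terms per hit are those actually co-assigned with an
observed `f_j` (including `f_j` itself); under the pseudo-count every
one of the μ terms technically has positive probability, and
`all_terms=True` restores that exhaustive reading at μ-fold cost.

Ancestral propagation follows the true path rule: each parent receives
`s(child) · c(child) / c(parent)` from its scored children, with the
counts from the ancestor-closed corpus so the ratio is at most 1.  By
default propagation is single-level — a parent's receipt is computed
from its children's *direct* scores.  A cascading variant
(`cascade=True`) compounds receipts toward the root; it concentrates
the whole subtree's mass on the namespace roots, which is why it is
not the default.  The final raw score is direct plus propagated.
P-value and expected-accuracy calibration against a benchmark score
distribution is a separate concern and is not implemented; outputs are
ranked by final raw score.

## Synthetic data: what it emulates

The generators produce standard flat files (OBO 1.2, GAF-style TSV,
edge lists, 1-based coordinate tables, BLAST-tabular hits) so the real
readers are exercised.  One RNG stream per generator is derived from
the scenario seed; identical seeds give byte-identical files.

- **Ontology**: three rooted trees (default depth 5, branching 3 in
  the study-scale preset, ≈360 terms) plus random same-namespace cross
  links (mixed `is_a`/`part_of`) forming DAG diamonds, and one obsolete
  stanza to exercise parsing.  Real GO is far larger and less regular;
  depth is kept GO-like so leaf terms are genuinely rare, which is what
  makes information content informative.
- **Corpus**: proteins annotated in 1–3 namespaces (mostly all three,
  so funSim is usually defined), up to 2 terms per namespace, term
  popularity following a power law with skew exponent 0.7.  The skew
  preserves the heavy reuse of a few terms seen in real GOA data while
  keeping the most popular term's direct frequency near 10% of
  proteins — in real corpora no specific term is directly asserted on
  half the proteome, and pushing the skew that far makes co-occurrence
  statistics degenerate.
- **PPI**: preferential attachment (heavy-tailed degrees, ~2 edges per
  node, ≈1000 edges at n = 500), the hierarchical replication model
  (decaying `C(k)`), or Erdős–Rényi; an optional planted near-clique
  around a named centroid (6-clique, `c_i = 2.5`) tethered to the
  background provides a known significant subnetwork.
- **Genome**: genes of ~0.8 kb tiled with exponential gaps (~0.6 kb
  mean) over two chromosomes; planted clusters are runs of consecutive
  genes pinned to one identical annotation set (one leaf term per
  namespace), flanked on both sides by a gene-free gap equal to the
  scan window size.  The flank models a coherent cluster in a
  gene-sparse neighborhood and guarantees that a window wholly
  containing the cluster contains only cluster genes; without it,
  selection of a planted cluster would depend on how many unrelated
  annotated genes happen to share the window, which is a property of
  local gene density rather than of the scan.
- **Hits**: per query, 10 subjects sharing a designated true term at
  log-uniform E-values 1e−30..1e−3 and 5 decoys at E-values 1..200
  (straddling the E = 125 cutoff).  True terms are drawn among terms
  with enough direct carriers and strictly rarer than all their
  ancestors, so the specific term rather than a broad ancestor is the
  recoverable signal.

Passing tests on this data show that the statistics recover structure
they were designed to detect under clean conditions; they do not show
robustness to the noise, bias and incompleteness of real annotation
corpora and interaction screens, nor to real genomes' operonic and
repeat structure.

## Problem sizes

Tests and the reproduction script run the study-scale preset
(≈360-term ontology, ≈530 proteins, ≈1000-edge PPI, ≈210-gene genome,
10 queries × 10 seeds for prediction recovery, 100 seeds × 100
randomizations for the clique significance check) — sizes chosen so
the full suite completes in about a minute while every statistic still
has enough support to be meaningful.

## Known limitations

- Evidence codes are not modeled; the GAF reader accepts full rows but
  only uses protein and term columns.
- The degree-exponent estimator is the descriptive log-log OLS fit,
  not a maximum-likelihood tail estimator; its R² is reported so poor
  fits are visible.
- The published forms of the subnetwork t statistic, the GOscore
  row/column combiner and the FDR variant are not recoverable; each
  default is documented above and the alternatives are config-exposed.
- PFP confidence calibration (p-values, expected accuracy) requires a
  benchmark score distribution and is out of scope; raw scores are
  comparable within a query, not across queries.
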