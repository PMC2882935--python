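"""PFP raw scoring: E-value-weighted GO term transfer from homology hits.

Given precomputed sequence-search hits for a query, every GO term f_a
is scored by summing, over the hits i and the terms f_j annotated to
each hit,

    s(f_a) = sum_i sum_j max(0, -ln E_value(i) + b) * P(f_a | f_j)

so a term gains score both from how often it (or a term co-occurring
with it) appears among the hits and from how strong those hits are.
The shift b = ln(125) lets weakly similar sequences (E-value up to 125)
contribute; a hit exactly at E = 125 contributes zero.  P(f_a | f_j) is
the pseudo-counted conditional co-occurrence probability

    P(f_a | f_j) = (c(f_a, f_j) + eps) / (c(f_j) + mu * eps)

with c(.) counted over a reference annotation corpus, mu the number of
unique terms and eps = 0.05.

Scores then propagate up the GO hierarchy (true path rule): a parent
receives from each scored child the child's score scaled by the ratio
of annotated-gene counts c(child)/c(parent), applied bottom-up so
scores cascade toward the root; the final raw score of a term is its
direct score plus what it received by propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .ontology import AnnotationCorpus, OntologyDAG

__all__ = [
    "DEFAULT_EPSILON",
    "DEFAULT_B",
    "Hit",
    "TermAssociationStats",
    "PFPScoreSet",
    "read_hits",
    "association_stats",
    "conditional_probability",
    "direct_scores",
    "propagate_and_finalize",
    "score_query",
    "write_scores",
]

DEFAULT_EPSILON = 0.05
#: score shift allowing hits up to E-value 125 to contribute
DEFAULT_B = math.log(125.0)


@dataclass(frozen=True)
class Hit:
    """One sequence-search hit: query, subject, E-value (> 0)."""

    query: str
    subject: str
    e_value: float

    def __post_init__(self):
        if self.e_value <= 0:
            raise ValueError(
                f"hit {self.query}->{self.subject}: E-value must be > 0")


def read_hits(source: TextIO | Iterable[str]) -> list[Hit]:
    """Read BLAST-tabular-style hits (query, subject, ..., evalue).

    Accepts a minimal 3-column ``query  subject  evalue`` table or full
    outfmt-6 rows, where the E-value is the second-to-last column.
    """
    hits: list[Hit] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 3:
            query, subject, e_value = fields
        elif len(fields) >= 11:
            query, subject, e_value = fields[0], fields[1], fields[-2]
        else:
            raise ValueError(
                f"line {lineno}: expected 3 or >= 11 columns, "
                f"got {len(fields)}")
        hits.append(Hit(query=query, subject=subject,
                        e_value=float(e_value)))
    return hits


@dataclass
class TermAssociationStats:
    """Co-occurrence counts of GO term pairs over a reference corpus.

    ``pair_count[(a, b)]`` (keys sorted) is the number of proteins
    assigned both terms; ``single_count[t]`` the number assigned ``t``.
    Counts default to the corpus's *direct* assignments, matching how
    annotation databases assert terms; ``closed=True`` counts the
    ancestor-closed sets instead.
    """

    single_count: dict[str, int]
    pair_count: dict[tuple[str, str], int]
    mu: int
    epsilon: float = DEFAULT_EPSILON
    #: terms observed co-assigned with a given term (includes itself)
    partners: dict[str, set[str]] = field(default_factory=dict)

    def c_pair(self, f_a: str, f_j: str) -> int:
        if f_a == f_j:
            return self.single_count.get(f_a, 0)
        key = (f_a, f_j) if f_a <= f_j else (f_j, f_a)
        return self.pair_count.get(key, 0)


def association_stats(corpus: AnnotationCorpus,
                      epsilon: float = DEFAULT_EPSILON,
                      closed: bool = False) -> TermAssociationStats:
    """Count term co-assignments protein by protein.

    mu is the number of unique terms with at least one assignment under
    the chosen counting mode.
    """
    single: dict[str, int] = {}
    pairs: dict[tuple[str, str], int] = {}
    partners: dict[str, set[str]] = {}
    source = corpus.closed if closed else corpus.direct
    for terms in source.values():
        ordered = sorted(terms)
        for i, term in enumerate(ordered):
            single[term] = single.get(term, 0) + 1
            partners.setdefault(term, set()).add(term)
            for other in ordered[i + 1:]:
                pairs[(term, other)] = pairs.get((term, other), 0) + 1
                partners[term].add(other)
                partners.setdefault(other, set()).add(term)
    return TermAssociationStats(single_count=single, pair_count=pairs,
                                mu=len(single), epsilon=epsilon,
                                partners=partners)


def conditional_probability(stats: TermAssociationStats,
                            f_a: str, f_j: str) -> float:
    """P(f_a | f_j) with pseudo-count smoothing; asymmetric in general."""
    return ((stats.c_pair(f_a, f_j) + stats.epsilon)
            / (stats.single_count.get(f_j, 0) + stats.mu * stats.epsilon))


@dataclass
class PFPScoreSet:
    """Raw PFP scores for one query: direct, propagated, final."""

    query: str
    direct: dict[str, float]
    propagated: dict[str, float] = field(default_factory=dict)

    @property
    def final(self) -> dict[str, float]:
        terms = set(self.direct) | set(self.propagated)
        return {t: self.direct.get(t, 0.0) + self.propagated.get(t, 0.0)
                for t in terms}

    def ranked(self) -> list[tuple[str, float]]:
        """Terms by decreasing final score (ties broken by term id)."""
        return sorted(self.final.items(), key=lambda kv: (-kv[1], kv[0]))


def direct_scores(hits: Iterable[Hit],
                  associations: Mapping[str, Iterable[str]],
                  stats: TermAssociationStats,
                  b: float = DEFAULT_B,
                  all_terms: bool = False) -> PFPScoreSet:
    """Eq-2-style direct scores for the query the hits belong to.

    Each hit contributes weight ``max(0, -ln E + b)`` spread over the
    candidate terms via the conditional co-occurrence probability
    against every term f_j annotated to the hit subject.  Candidates
    are the terms observed co-assigned with some f_j (every P(f_a|f_j)
    is positive under the pseudo-count, but only co-occurring terms get
    informative mass; ``all_terms=True`` scores all mu terms).
    """
    hits = list(hits)
    queries = {h.query for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits belong to several queries: {sorted(queries)}")
    query = queries.pop() if queries else ""
    scores: dict[str, float] = {}
    for hit in hits:
        weight = max(0.0, -math.log(hit.e_value) + b)
        if weight == 0.0:
            continue
        for f_j in associations.get(hit.subject, ()):
            if all_terms:
                candidates = stats.single_count.keys()
            else:
                candidates = stats.partners.get(f_j, {f_j})
            for f_a in candidates:
                scores[f_a] = (scores.get(f_a, 0.0)
                               + weight * conditional_probability(
                                   stats, f_a, f_j))
    return PFPScoreSet(query=query, direct=scores)


def propagate_and_finalize(score_set: PFPScoreSet, dag: OntologyDAG,
                           corpus: AnnotationCorpus,
                           cascade: bool = False) -> PFPScoreSet:
    """Ancestral score propagation up the DAG (true path rule).

    Each parent accumulates ``s(child) * c(child) / c(parent)`` from its
    scored children, where the counts c come from the ancestor-closed
    corpus (so the ratio is at most 1).  By default ``s(child)`` is the
    child's direct score, so propagation is single-level per edge; with
    ``cascade=True`` it is the child's running total (direct plus
    received propagation), applied children-first so scores compound up
    to the root.  Parents with zero annotation count are skipped.
    """
    propagated: dict[str, float] = {}
    running: dict[str, float] = dict(score_set.direct)
    for term in dag.topological_order():  # children before parents
        score = running.get(term, 0.0) if cascade \
            else score_set.direct.get(term, 0.0)
        if score <= 0.0:
            continue
        c_child = corpus.term_count.get(term, 0)
        if c_child == 0:
            continue
        for parent in dag.parents(term):
            c_parent = corpus.term_count.get(parent, 0)
            if c_parent == 0:
                continue  # unannotated ancestor: no ratio defined
            share = score * c_child / c_parent
            propagated[parent] = propagated.get(parent, 0.0) + share
            running[parent] = running.get(parent, 0.0) + share
    return PFPScoreSet(query=score_set.query, direct=dict(score_set.direct),
                       propagated=propagated)


def score_query(hits: Iterable[Hit], corpus: AnnotationCorpus,
                dag: OntologyDAG, stats: TermAssociationStats | None = None,
                b: float = DEFAULT_B, epsilon: float = DEFAULT_EPSILON,
                use_closed_associations: bool = False) -> PFPScoreSet:
    """Direct scoring plus propagation for one query's hit list.

    Subject annotations are the corpus's direct term sets; the
    co-occurrence statistics default to the same corpus.
    """
    if stats is None:
        stats = association_stats(corpus, epsilon=epsilon,
                                  closed=use_closed_associations)
    associations = {h.subject: corpus.terms_of(h.subject) for h in hits}
    direct = direct_scores(hits, associations, stats, b=b)
    return propagate_and_finalize(direct, dag, corpus)


def write_scores(score_sets: Iterable[PFPScoreSet],
                 destination: TextIO | str) -> None:
    """TSV: query, term, direct, propagated, final, rank."""
    rows = []
    for score_set in score_sets:
        for rank, (term, final) in enumerate(score_set.ranked(), start=1):
            rows.append((score_set.query, term,
                         score_set.direct.get(term, 0.0),
                         score_set.propagated.get(term, 0.0),
                         final, rank))
    frame = pd.DataFrame(rows, columns=[
        "query", "term", "direct", "propagated", "final", "rank"])
    frame.to_csv(destination, sep="\t", index=False, float_format="%.6g")
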