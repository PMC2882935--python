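"""GO semantic similarity: term pairs, term sets, and the funSim score.

Term similarity follows Schlicker's relevance measure: the Lin ratio
``2 ln p(c) / (ln p(c1) + ln p(c2))`` maximized over the common
ancestors ``c`` of the two terms, weighted by ``1 - p(c)`` so that
similarity through a frequent (uninformative) ancestor counts for
little.  A plain-Lin mode drops the relevance weight, in which case a
term's self-similarity is exactly 1.

Protein-level category scores build the all-by-all term similarity
matrix S_ij between the two proteins' annotation sets in one namespace;
the row score averages the row maxima, the column score the column
maxima, and the category GOscore combines the two (max by default).
The funSim score averages the squared BP, CC and MF GOscores (each
normalized by its maximum of 1), giving a value in [0, 1].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, TextIO

import numpy as np
import pandas as pd

from .ontology import (
    AnnotationCorpus,
    InformationContent,
    OntologyDAG,
    OntologyError,
    ancestor_closure,
)

__all__ = [
    "CategoryScore",
    "FunSimResult",
    "term_similarity",
    "go_score",
    "fun_sim",
    "all_pairs_scores",
    "write_pairs",
    "read_pairs",
    "TermSimilarityCache",
]

Mode = Literal["schlicker", "lin"]
Combiner = Literal["max", "mean"]

CATEGORIES = ("BP", "CC", "MF")

#: column order of a scored-pair table
PAIR_COLUMNS = ("protein_a", "protein_b", "bp", "cc", "mf", "funsim")


def term_similarity(c1: str, c2: str, dag: OntologyDAG,
                    ic: InformationContent, mode: Mode = "schlicker") -> float:
    """Similarity of two GO terms in the same namespace, in [0, 1].

    Maximizes ``relevance(c) * 2 ln p(c) / (ln p(c1) + ln p(c2))`` over
    the common ancestors ``c`` of ``c1`` and ``c2`` (each term counts as
    its own ancestor), where ``relevance(c)`` is ``1 - p(c)`` in
    Schlicker mode and 1 in plain-Lin mode.  Symmetric; clamped to
    [0, 1]; terms with undefined ``p`` raise :class:`OntologyError`.
    """
    if dag.namespace_of[c1] != dag.namespace_of[c2]:
        raise OntologyError(
            f"terms {c1!r} and {c2!r} are in different namespaces"
        )
    log_p1, log_p2 = math.log(ic[c1]), math.log(ic[c2])
    denominator = log_p1 + log_p2
    common = ancestor_closure(dag, [c1]) & ancestor_closure(dag, [c2])
    best = 0.0
    for ancestor in common:
        if ancestor not in ic:
            continue
        p = ic[ancestor]
        if denominator == 0.0:
            continue  # both terms at the root: no information to share
        lin = 2.0 * math.log(p) / denominator
        relevance = 1.0 - p if mode == "schlicker" else 1.0
        best = max(best, relevance * lin)
    return min(1.0, max(0.0, best))


class TermSimilarityCache:
    """Memoized term similarity for repeated all-pairs scoring."""

    def __init__(self, dag: OntologyDAG, ic: InformationContent,
                 mode: Mode = "schlicker"):
        self.dag = dag
        self.ic = ic
        self.mode = mode
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, c1: str, c2: str) -> float:
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        try:
            return self._cache[key]
        except KeyError:
            value = term_similarity(key[0], key[1], self.dag, self.ic,
                                    self.mode)
            self._cache[key] = value
            return value


@dataclass(frozen=True)
class CategoryScore:
    """A category GOscore with its row/column components."""

    value: float
    category: str | None
    row_score: float
    col_score: float


@dataclass(frozen=True)
class FunSimResult:
    """Per-category GOscores and the combined funSim for one protein pair.

    A category score is ``None`` when either protein lacks annotations
    in that namespace; funSim is present only when all three are.
    """

    bp: float | None
    cc: float | None
    mf: float | None
    funsim: float | None


def go_score(set_a: Iterable[str], set_b: Iterable[str], dag: OntologyDAG,
             ic: InformationContent, category: str | None = None,
             mode: Mode = "schlicker", combiner: Combiner = "max",
             similarity=None) -> CategoryScore:
    """Category GOscore of two non-empty term sets in one namespace.

    Builds the N x M matrix ``S_ij = sim(a_i, b_j)``; the row score is
    the mean of row maxima, the column score the mean of column maxima,
    and the GOscore combines them with ``max`` (default) or ``mean``.
    Symmetric under exchange of the two sets for both combiners.
    """
    rows, cols = sorted(set(set_a)), sorted(set(set_b))
    if not rows or not cols:
        raise OntologyError("go_score requires two non-empty term sets")
    if combiner not in ("max", "mean"):
        raise ValueError(f"unknown combiner {combiner!r}")
    sim = similarity or TermSimilarityCache(dag, ic, mode)
    matrix = np.array([[sim(a, b) for b in cols] for a in rows])
    row_score = float(matrix.max(axis=1).mean())
    col_score = float(matrix.max(axis=0).mean())
    if combiner == "max":
        value = max(row_score, col_score)
    else:
        value = (row_score + col_score) / 2.0
    return CategoryScore(value=value, category=category,
                         row_score=row_score, col_score=col_score)


def fun_sim(bp: float, cc: float, mf: float) -> float:
    """Combined three-category similarity: mean of the squared GOscores.

    Each GOscore is already normalized to a maximum of 1, so
    ``funSim = (bp^2 + cc^2 + mf^2) / 3`` lies in [0, 1].
    """
    for name, value in (("bp", bp), ("cc", cc), ("mf", mf)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} score {value} outside [0, 1]")
    return (bp * bp + cc * cc + mf * mf) / 3.0


def score_pair(protein_a: str, protein_b: str, corpus: AnnotationCorpus,
               dag: OntologyDAG, ic: InformationContent,
               mode: Mode = "schlicker", combiner: Combiner = "max",
               use_closed: bool = False, similarity=None) -> FunSimResult:
    """Category GOscores and funSim for one protein pair.

    The similarity matrix is built over each protein's direct
    annotations per namespace (ancestors enter through the
    common-ancestor search); ``use_closed=True`` switches to the
    ancestor-closed sets.
    """
    sim = similarity or TermSimilarityCache(dag, ic, mode)
    scores: dict[str, float | None] = {}
    for category in CATEGORIES:
        terms_a = corpus.terms_of(protein_a, category, closed=use_closed)
        terms_b = corpus.terms_of(protein_b, category, closed=use_closed)
        terms_a = {t for t in terms_a if t in ic}
        terms_b = {t for t in terms_b if t in ic}
        if terms_a and terms_b:
            scores[category] = go_score(
                terms_a, terms_b, dag, ic, category=category,
                combiner=combiner, similarity=sim,
            ).value
        else:
            scores[category] = None
    if all(scores[c] is not None for c in CATEGORIES):
        funsim = fun_sim(scores["BP"], scores["CC"], scores["MF"])
    else:
        funsim = None
    return FunSimResult(bp=scores["BP"], cc=scores["CC"], mf=scores["MF"],
                        funsim=funsim)


def all_pairs_scores(corpus: AnnotationCorpus, dag: OntologyDAG,
                     ic: InformationContent, mode: Mode = "schlicker",
                     combiner: Combiner = "max",
                     use_closed: bool = False) -> pd.DataFrame:
    """All-by-all protein pair scores as a scored-pair table.

    One row per unordered pair of annotated proteins, columns
    ``protein_a, protein_b, bp, cc, mf, funsim`` with ``NaN`` where a
    score is undefined.  No self pairs.
    """
    proteins = sorted(corpus.proteins)
    if len(proteins) < 2:
        raise OntologyError("all-by-all scoring needs at least 2 proteins")
    sim = TermSimilarityCache(dag, ic, mode)
    records = []
    for protein_a, protein_b in itertools.combinations(proteins, 2):
        result = score_pair(protein_a, protein_b, corpus, dag, ic,
                            mode=mode, combiner=combiner,
                            use_closed=use_closed, similarity=sim)
        records.append((protein_a, protein_b, result.bp, result.cc,
                        result.mf, result.funsim))
    table = pd.DataFrame.from_records(records, columns=PAIR_COLUMNS)
    return table.astype({c: float for c in ("bp", "cc", "mf", "funsim")})


def write_pairs(table: pd.DataFrame, destination: TextIO | str) -> None:
    """Write a scored-pair table as TSV with ``NA`` for absent scores."""
    table.to_csv(destination, sep="\t", index=False, na_rep="NA",
                 float_format="%.6g")


def read_pairs(source: TextIO | str) -> pd.DataFrame:
    """Read a scored-pair table written by :func:`write_pairs`."""
    table = pd.read_csv(source, sep="\t", na_values=["NA"])
    missing = set(PAIR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"pair table missing columns {sorted(missing)}")
    return table
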