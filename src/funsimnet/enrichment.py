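"""Overrepresentation of GO terms in a protein cluster.

For a term carried (after ancestor closure) by m of the N annotated
proteins of the proteome and by k of the n annotated proteins of the
cluster, the one-sided hypergeometric tail

    p = sum_{j>=k} C(m, j) C(N - m, n - j) / C(N, n)

is the probability of seeing k or more carriers by chance.  Because
many terms are tested per cluster, p values are corrected for multiple
testing with the Benjamini-Hochberg false discovery rate over the q
unique terms annotated to the cluster's proteins.

Annotation gain compares overrepresented-term counts between two
annotation states of the same cluster (known alone vs known plus
predicted), reported as a percentage increase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
from scipy import stats

from .ontology import AnnotationCorpus

__all__ = [
    "OverrepresentationResult",
    "AnnotationGain",
    "overrepresentation_pvalue",
    "fdr_correct",
    "overrepresented_terms",
    "annotation_gain",
]


def overrepresentation_pvalue(k: int, n: int, m: int, N: int) -> float:
    """Hypergeometric tail P(X >= k) for k carriers in a cluster of n,
    drawn from N proteins of which m carry the term."""
    if not (0 <= k <= n <= N):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (0 <= m <= N):
        raise ValueError(f"need 0 <= m <= N, got m={m}, N={N}")
    if k > m:
        raise ValueError(f"k={k} carriers exceed m={m} in the proteome")
    # sf(k-1) is the upper tail P(X >= k); scipy computes it in log space
    return float(np.clip(stats.hypergeom.sf(k - 1, N, m, n), 0.0, 1.0))


def fdr_correct(p_values: Sequence[float],
                method: str = "bh") -> list[float]:
    """Multiple-testing adjustment over q = len(p_values) tests.

    ``"bh"`` is the Benjamini-Hochberg step-up rule: sort ascending,
    take ``p_adj(i) = min_{j >= i} p(j) * q / j`` capped at 1, and
    restore input order.  ``"bonferroni"`` multiplies each p by q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p values must lie in [0, 1]")
    q = p.size
    if q == 0:
        return []
    if method == "bonferroni":
        return list(np.minimum(p * q, 1.0))
    if method != "bh":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * q / np.arange(1, q + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(q)
    out[order] = adjusted
    return list(out)


@dataclass(frozen=True)
class OverrepresentationResult:
    """One term's hypergeometric test within one cluster."""

    term: str
    namespace: str
    k: int   # cluster proteins carrying the term
    n: int   # annotated proteins in the cluster (term's namespace)
    m: int   # proteome proteins carrying the term
    N: int   # annotated proteins in the proteome (term's namespace)
    p_raw: float
    p_fdr: float
    overrepresented: bool


def overrepresented_terms(cluster: Iterable[str], corpus: AnnotationCorpus,
                          alpha: float = 0.05, method: str = "bh",
                          ) -> list[OverrepresentationResult]:
    """Test every term annotated (ancestor-closed) to a cluster protein.

    "Annotated" for the n and N totals means carrying at least one term
    in the tested term's namespace.  The FDR correction is applied over
    all q tested terms jointly.  A cluster with no annotated protein
    returns an empty list with a warning.
    """
    cluster = set(cluster)
    members_closed = {p: corpus.closed.get(p, set()) for p in cluster}
    tested_terms = sorted(set().union(*members_closed.values())
                          if members_closed else set())
    if not tested_terms:
        warnings.warn("cluster contains no annotated proteins")
        return []

    n_by_ns = {
        ns: sum(1 for p in cluster if corpus.terms_of(p, ns))
        for ns in corpus.dag.roots
    }
    N_by_ns = {ns: len(corpus.annotated_proteins(ns))
               for ns in corpus.dag.roots}

    rows = []
    for term in tested_terms:
        ns = corpus.dag.namespace_of[term]
        k = sum(1 for terms in members_closed.values() if term in terms)
        rows.append((term, ns, k, n_by_ns[ns],
                     corpus.term_count.get(term, 0), N_by_ns[ns]))
    p_raw = [overrepresentation_pvalue(k, n, m, N)
             for _, _, k, n, m, N in rows]
    p_fdr = fdr_correct(p_raw, method=method)
    return [
        OverrepresentationResult(
            term=term, namespace=ns, k=k, n=n, m=m, N=N,
            p_raw=p, p_fdr=p_adj, overrepresented=p_adj < alpha)
        for (term, ns, k, n, m, N), p, p_adj in zip(rows, p_raw, p_fdr)
    ]


@dataclass(frozen=True)
class AnnotationGain:
    """Change in overrepresented-term count between annotation states.

    ``gain_percent`` is the percentage increase over ``n_before``;
    a cluster with no previously overrepresented term is flagged
    ``previously_unannotated`` instead of dividing by zero.
    """

    n_before: int
    n_after: int
    gain_percent: float | None
    previously_unannotated: bool


def annotation_gain(before: Sequence[OverrepresentationResult],
                    after: Sequence[OverrepresentationResult],
                    ) -> AnnotationGain:
    """Percentage increase in unique overrepresented terms."""
    n_before = len({r.term for r in before if r.overrepresented})
    n_after = len({r.term for r in after if r.overrepresented})
    if n_before == 0:
        return AnnotationGain(n_before=0, n_after=n_after,
                              gain_percent=None,
                              previously_unannotated=True)
    gain = 100.0 * (n_after - n_before) / n_before
    return AnnotationGain(n_before=n_before, n_after=n_after,
                          gain_percent=gain, previously_unannotated=False)
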