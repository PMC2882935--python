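"""Gene Ontology DAG model, annotation corpora, and information content.

The ontology is held as a directed graph with child->parent edges
(``is_a`` and ``part_of`` by default), one rooted component per GO
namespace (BP, CC, MF).  Annotation corpora obey the true path rule:
a protein annotated to a term is implicitly annotated to every ancestor
of that term, so ancestor closure is applied before any counting.
Information content is the annotation frequency of a term relative to
its namespace root, ``p(c) = count(c) / count(root)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

__all__ = [
    "NAMESPACES",
    "OntologyError",
    "OntologyDAG",
    "AnnotationCorpus",
    "InformationContent",
    "is_term_id",
    "parse_obo",
    "read_gaf",
    "ancestor_closure",
    "compute_ic",
]

#: canonical category codes, keyed by the namespace strings used in OBO files
NAMESPACES: Mapping[str, str] = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}

#: ancestor edge types followed by default
DEFAULT_RELATIONS: tuple[str, ...] = ("is_a", "part_of")

_TERM_RE = re.compile(r"^GO:\d{7}$")


class OntologyError(ValueError):
    """Raised for structural problems in an ontology or annotation corpus."""


def is_term_id(value: str) -> bool:
    """True if *value* has the canonical ``GO:`` + 7-digit form."""
    return bool(_TERM_RE.match(value))


@dataclass
class OntologyDAG:
    """A rooted, acyclic GO hierarchy with child->parent edges.

    Parameters
    ----------
    graph:
        Directed graph with an edge ``child -> parent`` for every
        retained ancestor relation.  Acyclic by construction.
    namespace_of:
        Term -> category code (``"BP"``, ``"CC"`` or ``"MF"``).
    name_of:
        Term -> human-readable name.
    roots:
        Category code -> root term of that namespace.
    """

    graph: nx.DiGraph
    namespace_of: dict[str, str]
    name_of: dict[str, str]
    roots: dict[str, str]

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of *term*, excluding *term* itself."""
        return nx.descendants(self.graph, term)

    def root_of(self, term: str) -> str:
        return self.roots[self.namespace_of[term]]

    def topological_order(self) -> list[str]:
        """Terms ordered so every child precedes its parents."""
        return list(nx.topological_sort(self.graph))


def parse_obo(
    source: TextIO | str,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into an :class:`OntologyDAG`.

    Obsolete terms are excluded, edges not in *relations* and edges
    crossing namespaces are dropped, and one root per namespace is
    identified.  A reference to an undefined term, a term without a
    namespace, or a cycle raises :class:`OntologyError`.
    """
    multigraph = obonet.read_obo(source, ignore_obsolete=True)
    relations = set(relations)

    namespace_of: dict[str, str] = {}
    name_of: dict[str, str] = {}
    for term, data in multigraph.nodes(data=True):
        if "name" not in data:
            raise OntologyError(f"reference to undefined term {term!r}")
        if "namespace" not in data:
            raise OntologyError(f"term {term!r} has no namespace")
        ns = data["namespace"]
        if ns not in NAMESPACES:
            raise OntologyError(f"term {term!r} has unknown namespace {ns!r}")
        namespace_of[term] = NAMESPACES[ns]
        name_of[term] = data["name"]

    graph = nx.DiGraph()
    graph.add_nodes_from(namespace_of)
    for child, parent, key in multigraph.edges(keys=True):
        if key not in relations:
            continue
        if namespace_of[child] != namespace_of[parent]:
            continue  # per-namespace analyses: cross-namespace links dropped
        graph.add_edge(child, parent)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")

    roots: dict[str, str] = {}
    for term in graph.nodes:
        if graph.out_degree(term) == 0:
            ns = namespace_of[term]
            if ns in roots:
                raise OntologyError(
                    f"namespace {ns} has multiple roots: {roots[ns]!r}, {term!r}"
                )
            roots[ns] = term

    return OntologyDAG(graph=graph, namespace_of=namespace_of,
                       name_of=name_of, roots=roots)


def ancestor_closure(dag: OntologyDAG, terms: Iterable[str]) -> set[str]:
    """Input terms plus all their ancestors up to the namespace roots.

    Idempotent and monotone; unknown terms raise :class:`OntologyError`.
    """
    closed: set[str] = set()
    for term in terms:
        if term not in dag:
            raise OntologyError(f"unknown term {term!r}")
        closed.add(term)
        closed |= dag.ancestors(term)
    return closed


def read_gaf(source: TextIO | Iterable[str]) -> list[tuple[str, str]]:
    """Read protein->term pairs from a GAF-style tab-separated stream.

    Accepts minimal two-column files (protein id, GO id) as well as full
    GAF 2.x rows, where the object id is column 2 and the GO id is
    column 5; comment lines start with ``!``.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) >= 5 and is_term_id(fields[4]):
            pairs.append((fields[1], fields[4]))
        elif len(fields) >= 2 and is_term_id(fields[1]):
            pairs.append((fields[0], fields[1]))
        else:
            raise OntologyError(
                f"line {lineno}: cannot find a (protein, GO id) pair in {line!r}"
            )
    return pairs


@dataclass
class AnnotationCorpus:
    """Protein -> GO term annotations with ancestor closure and counts.

    ``direct`` holds the terms as asserted; ``closed`` the ancestor
    closure of each protein's set.  ``term_count[t]`` is the number of
    proteins whose closed set contains ``t``, so after closure the count
    of a parent is at least the count of each child and the count of a
    namespace root equals the number of proteins annotated in that
    namespace.
    """

    dag: OntologyDAG
    direct: dict[str, set[str]]
    closed: dict[str, set[str]] = field(init=False)
    term_count: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.closed = {
            protein: ancestor_closure(self.dag, terms)
            for protein, terms in self.direct.items()
        }
        counts: dict[str, int] = {}
        for terms in self.closed.values():
            for term in terms:
                counts[term] = counts.get(term, 0) + 1
        self.term_count = counts

    @classmethod
    def from_pairs(cls, dag: OntologyDAG,
                   pairs: Iterable[tuple[str, str]]) -> "AnnotationCorpus":
        direct: dict[str, set[str]] = {}
        for protein, term in pairs:
            if term not in dag:
                raise OntologyError(f"annotation to unknown term {term!r}")
            direct.setdefault(protein, set()).add(term)
        return cls(dag=dag, direct=direct)

    @property
    def proteins(self) -> set[str]:
        return set(self.direct)

    @property
    def n_terms(self) -> int:
        """Number of unique terms used after closure (the mu of the
        co-occurrence pseudo-count model)."""
        return len(self.term_count)

    def terms_of(self, protein: str, namespace: str | None = None,
                 closed: bool = False) -> set[str]:
        """A protein's terms, optionally restricted to one namespace."""
        terms = (self.closed if closed else self.direct).get(protein, set())
        if namespace is None:
            return set(terms)
        return {t for t in terms if self.dag.namespace_of[t] == namespace}

    def annotated_proteins(self, namespace: str) -> set[str]:
        """Proteins with at least one term in *namespace*."""
        return {p for p in self.direct if self.terms_of(p, namespace)}

    def restricted_to(self, proteins: Iterable[str]) -> "AnnotationCorpus":
        keep = set(proteins)
        return AnnotationCorpus(
            dag=self.dag,
            direct={p: set(t) for p, t in self.direct.items() if p in keep},
        )

    def merged_with(self, other: "AnnotationCorpus") -> "AnnotationCorpus":
        """Union of two corpora on the same ontology (known + predicted)."""
        direct: dict[str, set[str]] = {p: set(t) for p, t in self.direct.items()}
        for protein, terms in other.direct.items():
            direct.setdefault(protein, set()).update(terms)
        return AnnotationCorpus(dag=self.dag, direct=direct)


@dataclass
class InformationContent:
    """Per-term annotation frequency relative to the namespace root.

    ``p[c]`` is in ``(0, 1]``; terms never annotated (count 0) are
    absent from the mapping, and any similarity involving them is an
    error rather than zero, since ``ln p`` is undefined.
    """

    p: dict[str, float]

    def __contains__(self, term: str) -> bool:
        return term in self.p

    def __getitem__(self, term: str) -> float:
        try:
            return self.p[term]
        except KeyError:
            raise OntologyError(
                f"term {term!r} has no annotations; p(c) undefined"
            ) from None


def compute_ic(dag: OntologyDAG, corpus: AnnotationCorpus,
               require_all_namespaces: bool = True) -> InformationContent:
    """Annotation frequencies ``p(c) = count(c) / count(root)``.

    Counts come from the ancestor-closed corpus, so ``p`` is monotone
    non-decreasing from child to parent and ``p(root) = 1`` exactly.
    """
    root_counts = {ns: corpus.term_count.get(root, 0)
                   for ns, root in dag.roots.items()}
    if require_all_namespaces:
        for ns, count in root_counts.items():
            if count == 0:
                raise OntologyError(f"no annotated proteins in namespace {ns}")
    p: dict[str, float] = {}
    for term, count in corpus.term_count.items():
        root_count = root_counts[dag.namespace_of[term]]
        if root_count:
            p[term] = count / root_count
    return InformationContent(p=p)
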