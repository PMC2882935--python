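"""PPI networks: annotation enrichment, centroid subnetworks, and the
degree-preserving randomization test for subnetwork connectivity.

A centroid subnetwork is a protein together with all its interaction
partners and the edges among them; its connectivity coefficient is the
edge-to-node ratio ``c_i = g_i / n_i``.  Significance is assessed
against networks randomized while preserving every node's degree
(double-edge-swap null model): the subnetwork of the same centroid is
extracted from each randomized network and the real ``c_i`` is compared
to the randomized values with a one-sided Student t statistic.

Self-interactions occur in real PPI data and are tracked, but excluded
from degrees, subnetwork edge counts and randomization, where the
statistics are defined on simple-graph neighborhoods.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import igraph
import networkx as nx
import numpy as np
from scipy import stats

from .ontology import AnnotationCorpus

__all__ = [
    "PPINetwork",
    "Subnetwork",
    "SubnetworkSignificance",
    "read_ppi",
    "interaction_annotation_status",
    "centroid_subnetworks",
    "randomize_preserving_degree",
    "subnetwork_significance",
    "significant_subnetworks",
]


@dataclass
class PPINetwork:
    """An undirected, deduplicated PPI graph plus its self-loop set."""

    graph: nx.Graph
    self_loops: set[str] = field(default_factory=set)

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, protein: str) -> int:
        return self.graph.degree(protein)


def read_ppi(source: TextIO | Iterable[str]) -> PPINetwork:
    """Read a 2-column edge list (tab or whitespace separated).

    Order-reversed and repeated duplicates collapse to one undirected
    edge; a self-interaction ``a a`` is recorded in ``self_loops`` but
    contributes no graph edge (and hence no degree).
    """
    graph = nx.Graph()
    self_loops: set[str] = set()
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected two ids, got {line!r}")
        a, b = fields[0], fields[1]
        if a == b:
            self_loops.add(a)
            graph.add_node(a)
        else:
            graph.add_edge(a, b)
    return PPINetwork(graph=graph, self_loops=self_loops)


def interaction_annotation_status(
    ppi: PPINetwork,
    known: AnnotationCorpus,
    predicted: AnnotationCorpus | None = None,
    categories: Sequence[str] = ("BP", "CC", "MF"),
) -> dict[str, dict[str, dict[str, float]]]:
    """Fraction of edges with both / one / neither endpoint annotated.

    Classifies every non-self edge per GO category under two annotation
    states: previously known annotations alone, and known plus
    predicted.  Returns
    ``{state: {category: {"both": .., "one": .., "none": ..,
    "n_edges": ..}}}``; the three fractions sum to 1.
    """
    states: dict[str, AnnotationCorpus] = {"known": known}
    if predicted is not None:
        states["known+predicted"] = known.merged_with(predicted)
    edges = list(ppi.graph.edges)
    summary: dict[str, dict[str, dict[str, float]]] = {}
    for state, corpus in states.items():
        summary[state] = {}
        for category in categories:
            annotated = corpus.annotated_proteins(category)
            counts = {"both": 0, "one": 0, "none": 0}
            for a, b in edges:
                n_annotated = (a in annotated) + (b in annotated)
                counts[("none", "one", "both")[n_annotated]] += 1
            total = len(edges)
            summary[state][category] = {
                key: (value / total if total else 0.0)
                for key, value in counts.items()
            }
            summary[state][category]["n_edges"] = total
    return summary


@dataclass(frozen=True)
class Subnetwork:
    """A centroid, its neighbors, and the edges among all of them."""

    centroid: str
    members: frozenset[str]
    g_i: int  # edges among members (self-loops excluded)
    n_i: int  # member count

    @property
    def c_i(self) -> float:
        """Connectivity coefficient: edges per node."""
        return self.g_i / self.n_i


def _subnetwork_of(graph: nx.Graph, centroid: str) -> Subnetwork:
    members = {centroid} | set(graph.neighbors(centroid))
    sub = graph.subgraph(members)
    return Subnetwork(centroid=centroid, members=frozenset(members),
                      g_i=sub.number_of_edges(), n_i=len(members))


def centroid_subnetworks(ppi: PPINetwork) -> list[Subnetwork]:
    """One subnetwork per protein of degree >= 1, with Eq-style c_i."""
    return [
        _subnetwork_of(ppi.graph, protein)
        for protein in sorted(ppi.graph.nodes)
        if ppi.graph.degree(protein) >= 1
    ]


def randomize_preserving_degree(ppi: PPINetwork, seed: int,
                                swaps_per_edge: int = 10) -> PPINetwork:
    """Degree-preserving shuffle of the interaction partners.

    Applies ``swaps_per_edge * n_edges`` attempted double edge swaps
    (rewiring that keeps the graph simple, so every node keeps its exact
    degree) via igraph's C implementation, seeded and reproducible.
    Networks admitting no legal swap are returned unchanged with a
    warning.  Self-loops are not randomized; they are carried over.
    """
    graph = ppi.graph
    m = graph.number_of_edges()
    if m < 2:
        warnings.warn("fewer than 2 edges; no legal swap, returning input")
        return PPINetwork(graph=graph.copy(), self_loops=set(ppi.self_loops))
    nodes = sorted(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    ig = igraph.Graph(
        n=len(nodes),
        edges=[(index[u], index[v]) for u, v in graph.edges],
        directed=False,
    )
    state = random.getstate()
    try:
        # python-igraph draws its randomness from the stdlib random module
        random.seed(seed)
        ig.rewire(n=swaps_per_edge * m, mode="simple")
    finally:
        random.setstate(state)
    shuffled = nx.Graph()
    shuffled.add_nodes_from(nodes)
    shuffled.add_edges_from((nodes[e.source], nodes[e.target]) for e in ig.es)
    if shuffled.number_of_edges() == m and all(
        shuffled.degree(v) == graph.degree(v) for v in nodes
    ):
        return PPINetwork(graph=shuffled, self_loops=set(ppi.self_loops))
    # a failed rewire would break the degree contract; fall back to input
    warnings.warn("rewiring did not preserve degrees; returning input")
    return PPINetwork(graph=graph.copy(), self_loops=set(ppi.self_loops))


@dataclass(frozen=True)
class SubnetworkSignificance:
    """One-sided t test of a subnetwork's connectivity coefficient
    against its degree-preserving randomizations."""

    centroid: str
    c_i: float
    nu: float        # mean of randomized connectivity coefficients
    s: float         # their sample variance
    n_randomizations: int
    t: float
    p_value: float
    significant: bool
    degenerate_variance: bool = False


def subnetwork_significance(real: Subnetwork,
                            randomized_cs: Sequence[float],
                            alpha: float = 0.05,
                            two_sided: bool = False,
                            population_variance: bool = False,
                            ) -> SubnetworkSignificance:
    """t = (c_i - nu) / sqrt(s / R) with R - 1 degrees of freedom.

    ``nu`` and ``s`` are the mean and sample variance of the
    connectivity coefficients of the same centroid's subnetwork in the
    R randomized networks; the test is one-sided for enriched
    connectivity by default.  Zero randomized variance with c_i above
    the mean is reported as significant with p = 0 and a degeneracy
    flag.
    """
    values = np.asarray(randomized_cs, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 randomized values")
    big_r = len(values)
    nu = float(values.mean())
    s = float(values.var(ddof=0 if population_variance else 1))
    c_i = real.c_i
    if s == 0.0:
        if math.isclose(c_i, nu):
            return SubnetworkSignificance(
                centroid=real.centroid, c_i=c_i, nu=nu, s=s,
                n_randomizations=big_r, t=0.0, p_value=1.0,
                significant=False, degenerate_variance=True)
        return SubnetworkSignificance(
            centroid=real.centroid, c_i=c_i, nu=nu, s=s,
            n_randomizations=big_r, t=math.inf if c_i > nu else -math.inf,
            p_value=0.0 if (two_sided or c_i > nu) else 1.0,
            significant=two_sided or c_i > nu,
            degenerate_variance=True)
    t = (c_i - nu) / math.sqrt(s / big_r)
    if two_sided:
        p_value = 2.0 * stats.t.sf(abs(t), df=big_r - 1)
    else:
        p_value = float(stats.t.sf(t, df=big_r - 1))
    return SubnetworkSignificance(
        centroid=real.centroid, c_i=c_i, nu=nu, s=s,
        n_randomizations=big_r, t=float(t), p_value=p_value,
        significant=p_value < alpha)


def significant_subnetworks(ppi: PPINetwork, n_randomizations: int = 100,
                            seed: int = 0, alpha: float = 0.05,
                            centroids: Iterable[str] | None = None,
                            ) -> list[SubnetworkSignificance]:
    """Test every centroid subnetwork against R randomized networks.

    Each randomization rewires the whole network once (seeded from
    *seed*); the subnetwork of each centroid is re-extracted from every
    randomized network, giving R connectivity coefficients per centroid.
    """
    if centroids is None:
        targets = [s.centroid for s in centroid_subnetworks(ppi)]
    else:
        targets = [c for c in centroids if ppi.graph.degree(c) >= 1]
    real = {c: _subnetwork_of(ppi.graph, c) for c in targets}
    randomized: dict[str, list[float]] = {c: [] for c in targets}
    for r in range(n_randomizations):
        shuffled = randomize_preserving_degree(ppi, seed=seed * 100003 + r)
        for c in targets:
            randomized[c].append(_subnetwork_of(shuffled.graph, c).c_i)
    return [
        subnetwork_significance(real[c], randomized[c], alpha=alpha)
        for c in targets
    ]
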