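"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume —
a three-namespace GO-like DAG, an annotation corpus with skewed
term-usage frequencies (so information content varies), scale-free and
hierarchically modular interaction networks, a linear genome with
planted functionally coherent gene clusters, and homology hit tables
with a designated recoverable true term per query.  All outputs are
standard flat formats (OBO, GAF-style TSV, edge lists, coordinate
tables) so the real readers are exercised, not bypassed.

Planted structures are the recoverable ground truth: a clique-like
subnetwork around a named centroid (connectivity significance), runs of
consecutive genes sharing an identical annotation set (window scan;
their pairwise funSim is 1 by construction), and per-query true terms
(PFP rank recovery).  Planted gene clusters are placed with a gene-free
flanking gap on both sides — the model is a coherent cluster in a
gene-sparse neighborhood — so a scan window wholly containing a cluster
contains only cluster genes.

Every generator derives an independent RNG stream from the scenario
seed, so the same seed and parameters reproduce byte-identical files.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from . import simnet
from .ontology import AnnotationCorpus, OntologyDAG, parse_obo, read_gaf

__all__ = [
    "OntologyParams",
    "CorpusParams",
    "PPIParams",
    "PlantedClique",
    "GenomeParams",
    "PlantedCluster",
    "HitParams",
    "SyntheticScenario",
    "ScenarioData",
    "make_obo",
    "make_ontology_and_corpus",
    "make_ppi",
    "make_genome",
    "make_hit_table",
    "generate_scenario",
    "smoke_scenario",
    "paper_shaped_scenario",
]

_NS_LONG = ("biological_process", "cellular_component", "molecular_function")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """One independent stream per generator, all derived from the seed."""
    return np.random.default_rng([int(seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# ontology + corpus


@dataclass
class OntologyParams:
    """Three rooted trees of `depth` levels and `branching` children,
    plus random same-namespace cross links that turn them into DAGs."""

    depth: int = 4
    branching: int = 3
    cross_links: int = 10
    include_obsolete: bool = True

    def __post_init__(self):
        if self.depth < 2 or self.branching < 2:
            raise ValueError("need depth >= 2 and branching >= 2")


@dataclass
class CorpusParams:
    """Annotation corpus shape: how many proteins, how many namespaces
    each is annotated in, terms per namespace, and the power-law skew
    of term popularity (larger skew -> a few heavily reused terms)."""

    n_proteins: int = 100
    annotated_fraction: float = 1.0
    p_namespaces: tuple[float, float, float] = (0.1, 0.2, 0.7)  # P(1), P(2), P(3)
    max_terms_per_namespace: int = 3
    skew: float = 1.0


@dataclass
class _OntologyLayout:
    """Internal: term ids per namespace with their tree level."""

    terms: dict[str, list[str]]            # ns code -> term ids
    level: dict[str, int]                  # term -> level (root = 0)
    parents: dict[str, list[tuple[str, str]]]  # term -> [(parent, relation)]
    roots: dict[str, str]


def _build_layout(params: OntologyParams, rng: np.random.Generator,
                  ) -> _OntologyLayout:
    terms: dict[str, list[str]] = {}
    level: dict[str, int] = {}
    parents: dict[str, list[tuple[str, str]]] = {}
    roots: dict[str, str] = {}
    counter = 1
    for ns_index, ns in enumerate(("BP", "CC", "MF")):
        ns_terms: list[str] = []
        previous_level: list[str] = []
        for depth in range(params.depth):
            width = params.branching ** depth
            current = []
            for i in range(width):
                term = f"GO:{counter:07d}"
                counter += 1
                ns_terms.append(term)
                level[term] = depth
                if depth == 0:
                    roots[ns] = term
                    parents[term] = []
                else:
                    parent = previous_level[i // params.branching]
                    parents[term] = [(parent, "is_a")]
                current.append(term)
            previous_level = current
        # cross links: an extra parent at a strictly shallower level
        added = 0
        attempts = 0
        while added < params.cross_links and attempts < 50 * params.cross_links:
            attempts += 1
            child = ns_terms[int(rng.integers(1, len(ns_terms)))]
            shallower = [t for t in ns_terms if level[t] < level[child]]
            parent = shallower[int(rng.integers(len(shallower)))]
            if parent in [p for p, _ in parents[child]]:
                continue
            relation = "part_of" if rng.random() < 0.5 else "is_a"
            parents[child].append((parent, relation))
            added += 1
        terms[ns] = ns_terms
    return _OntologyLayout(terms=terms, level=level, parents=parents,
                           roots=roots)


def _layout_to_obo(layout: _OntologyLayout,
                   include_obsolete: bool) -> str:
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for ns, long_name in zip(("BP", "CC", "MF"), _NS_LONG):
        for term in layout.terms[ns]:
            lines += [
                "[Term]",
                f"id: {term}",
                f"name: synthetic {long_name} term {term[3:]}",
                f"namespace: {long_name}",
            ]
            for parent, relation in layout.parents[term]:
                if relation == "is_a":
                    lines.append(f"is_a: {parent} ! parent")
                else:
                    lines.append(f"relationship: part_of {parent} ! parent")
            lines.append("")
    if include_obsolete:
        lines += [
            "[Term]",
            "id: GO:9999999",
            "name: synthetic obsolete term",
            "namespace: biological_process",
            "is_obsolete: true",
            "",
        ]
    return "\n".join(lines)


def make_obo(params: OntologyParams, seed: int) -> str:
    """OBO 1.2 text for a synthetic three-namespace DAG."""
    layout = _build_layout(params, _rng(seed, 1))
    return _layout_to_obo(layout, params.include_obsolete)


def _ancestors_in_layout(layout: _OntologyLayout, term: str) -> set[str]:
    seen: set[str] = set()
    stack = [p for p, _ in layout.parents[term]]
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(p for p, _ in layout.parents[t])
    return seen


def _sample_terms(layout: _OntologyLayout, ns: str, count: int,
                  weights: np.ndarray, rng: np.random.Generator) -> set[str]:
    """Distinct non-root terms, popularity-weighted, with no
    ancestor-descendant pair inside the sampled set."""
    candidates = layout.terms[ns][1:]
    chosen: set[str] = set()
    blocked: set[str] = set()
    for _ in range(8 * count):
        if len(chosen) == count:
            break
        term = candidates[int(rng.choice(len(candidates), p=weights))]
        if term in chosen or term in blocked:
            continue
        ancestors = _ancestors_in_layout(layout, term)
        if ancestors & chosen:
            continue
        chosen.add(term)
        blocked |= ancestors
    return chosen


def _popularity_weights(n: int, skew: float,
                        rng: np.random.Generator) -> np.ndarray:
    ranks = rng.permutation(n) + 1
    weights = ranks.astype(float) ** (-skew)
    return weights / weights.sum()


def make_ontology_and_corpus(
    ontology_params: OntologyParams,
    corpus_params: CorpusParams,
    seed: int,
    protein_ids: Sequence[str] | None = None,
    identical_groups: Sequence[tuple[Sequence[str], Sequence[str]]] = (),
) -> tuple[str, str]:
    """OBO text plus a GAF-style annotation table.

    Background proteins draw 1-3 namespaces and up to
    ``max_terms_per_namespace`` terms each, with power-law term
    popularity.  ``identical_groups`` pins the listed proteins to the
    exact term set given (planted coherent clusters); their random
    annotations are replaced.
    """
    layout = _build_layout(ontology_params, _rng(seed, 1))
    obo_text = _layout_to_obo(layout, ontology_params.include_obsolete)

    rng = _rng(seed, 2)
    if protein_ids is None:
        protein_ids = [f"p{i + 1:04d}"
                       for i in range(corpus_params.n_proteins)]
    weights = {ns: _popularity_weights(len(layout.terms[ns]) - 1,
                                       corpus_params.skew, rng)
               for ns in ("BP", "CC", "MF")}
    pinned = {}
    for members, term_set in identical_groups:
        for member in members:
            pinned[member] = sorted(term_set)

    lines = ["!gaf-version: synthetic 2-column (protein, GO id)"]
    for protein in protein_ids:
        if protein in pinned:
            for term in pinned[protein]:
                lines.append(f"{protein}\t{term}")
            continue
        if rng.random() >= corpus_params.annotated_fraction:
            continue
        n_namespaces = 1 + int(rng.choice(
            3, p=np.asarray(corpus_params.p_namespaces, dtype=float)))
        namespaces = sorted(
            rng.choice(["BP", "CC", "MF"], size=n_namespaces, replace=False))
        for ns in namespaces:
            n_terms = 1 + int(rng.integers(
                corpus_params.max_terms_per_namespace))
            for term in sorted(_sample_terms(layout, ns, n_terms,
                                             weights[ns], rng)):
                lines.append(f"{protein}\t{term}")
    return obo_text, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PPI


@dataclass
class PlantedClique:
    """A dense subnetwork (clique minus a few edges) around a centroid."""

    centroid: str = "clq_centroid"
    size: int = 6
    missing_edges: int = 0
    member_prefix: str = "clq_m"


@dataclass
class PPIParams:
    """Interaction-network shape.

    ``model`` is one of ``preferential-attachment`` (heavy-tailed
    degrees), ``hierarchical-replication`` (C(k) decaying with k) or
    ``erdos-renyi``; an optional planted clique supports the
    subnetwork-significance tests, and ``n_self_loops`` exercises the
    self-interaction bookkeeping.
    """

    model: str = "preferential-attachment"
    n: int = 500
    edges_per_node: int = 2       # preferential-attachment m
    er_p: float = 0.01
    hierarchy_levels: int = 2
    planted_clique: PlantedClique | None = None
    n_self_loops: int = 0
    node_prefix: str = "p"

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("need n >= 4")
        if self.model not in ("preferential-attachment",
                              "hierarchical-replication", "erdos-renyi"):
            raise ValueError(f"unknown model {self.model!r}")


def make_ppi(params: PPIParams, seed: int) -> str:
    """Edge-list text (2-column TSV) for a synthetic PPI network."""
    rng = _rng(seed, 3)
    nx_seed = int(rng.integers(2**31))
    if params.model == "preferential-attachment":
        graph = nx.barabasi_albert_graph(params.n, params.edges_per_node,
                                         seed=nx_seed)
    elif params.model == "erdos-renyi":
        graph = nx.gnp_random_graph(params.n, params.er_p, seed=nx_seed)
    else:
        graph = simnet.hierarchical_network(levels=params.hierarchy_levels)
    name = {i: f"{params.node_prefix}{i + 1:04d}" for i in graph.nodes}
    lines = [f"{name[u]}\t{name[v]}" for u, v in sorted(graph.edges)]

    if params.planted_clique is not None:
        clique = params.planted_clique
        members = [clique.centroid] + [
            f"{clique.member_prefix}{i + 1}" for i in range(clique.size - 1)]
        edges = [(a, b) for i, a in enumerate(members)
                 for b in members[i + 1:]]
        removable = [e for e in edges if clique.centroid not in e]
        for index in sorted(
                rng.choice(len(removable), size=clique.missing_edges,
                           replace=False), reverse=True):
            edges.remove(removable[index])
        # tether the clique to the background so it is one component
        anchor = name[sorted(graph.nodes)[0]]
        edges.append((members[-1], anchor))
        lines += [f"{a}\t{b}" for a, b in edges]

    for i in range(params.n_self_loops):
        node = name[sorted(graph.nodes)[i % len(name)]]
        lines.append(f"{node}\t{node}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# genome


@dataclass
class PlantedCluster:
    """A run of consecutive genes sharing one annotation set, isolated
    by a gene-free flank on both sides."""

    size: int = 5
    chromosome: str = "chr1"
    flank: int = 10_000
    intra_gap: int = 200
    name: str = "cl1"


@dataclass
class GenomeParams:
    """Linear genome: genes tiled with stochastic spacing, random
    strands, and planted coherent clusters."""

    n_genes: int = 200
    n_chromosomes: int = 2
    gene_length: int = 800
    mean_gap: int = 600
    planted_clusters: tuple[PlantedCluster, ...] = ()
    gene_prefix: str = "g"


def make_genome(params: GenomeParams, seed: int,
                ) -> tuple[str, list[dict]]:
    """Gene coordinate TSV (1-based inclusive) plus planted-cluster info.

    Background genes are split evenly across chromosomes; each planted
    cluster is inserted at a random point of its chromosome's gene
    order, with ``flank`` empty base pairs before and after so windows
    wholly containing the cluster hold no other gene.
    """
    rng = _rng(seed, 4)
    chromosomes = [f"chr{i + 1}" for i in range(params.n_chromosomes)]
    for cluster in params.planted_clusters:
        if cluster.chromosome not in chromosomes:
            raise ValueError(f"cluster on unknown {cluster.chromosome!r}")
    names = {c: n for n, c in zip(
        np.array_split(np.arange(params.n_genes), params.n_chromosomes),
        chromosomes)}

    lines = ["protein\tchromosome\tstart\tend\tstrand"]
    cluster_info: list[dict] = []
    gene_counter = 0
    for chromosome in chromosomes:
        n_background = len(names[chromosome])
        clusters = [c for c in params.planted_clusters
                    if c.chromosome == chromosome]
        insert_after = sorted(
            int(rng.integers(n_background + 1)) for _ in clusters)
        cursor = int(rng.integers(1, 2000))
        cluster_queue = list(zip(insert_after, clusters))

        def emit(name: str, length: int, strand: str, start: int) -> int:
            end = start + length - 1  # 1-based inclusive
            lines.append(f"{name}\t{chromosome}\t{start}\t{end}\t{strand}")
            return end

        for index in range(n_background + 1):
            while cluster_queue and cluster_queue[0][0] == index:
                _, cluster = cluster_queue.pop(0)
                cursor += cluster.flank
                members = []
                span_start = cursor
                for j in range(cluster.size):
                    member = f"{cluster.name}_g{j + 1}"
                    strand = "+" if rng.random() < 0.5 else "-"
                    end = emit(member, params.gene_length, strand, cursor)
                    members.append(member)
                    cursor = end + 1 + cluster.intra_gap
                cluster_info.append({
                    "name": cluster.name,
                    "chromosome": chromosome,
                    "members": members,
                    "start": span_start,
                    "end": cursor - cluster.intra_gap - 1,
                })
                cursor += cluster.flank
            if index == n_background:
                break
            gene_counter += 1
            name = f"{params.gene_prefix}{gene_counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            length = params.gene_length + int(rng.integers(-200, 201))
            end = emit(name, length, strand, cursor)
            cursor = end + 1 + int(rng.exponential(params.mean_gap)) + 1
    return "\n".join(lines) + "\n", cluster_info


# ---------------------------------------------------------------------------
# homology hits


@dataclass
class HitParams:
    """Hit-table shape: per query, ``true_hits`` subjects sharing the
    designated true term at low E-values (log-uniform 1e-30..1e-3) and
    ``decoy_hits`` random subjects at high E-values (1..200, straddling
    the E = 125 contribution cutoff)."""

    n_queries: int = 10
    true_hits: int = 10
    decoy_hits: int = 5
    query_prefix: str = "q"


def make_hit_table(corpus: AnnotationCorpus, params: HitParams,
                   seed: int) -> tuple[str, dict[str, str]]:
    """Hit-table text plus the query -> true-term manifest.

    True terms are drawn among terms directly annotated to at least
    ``true_hits`` proteins and rarer than every one of their ancestors
    (so the specific term, not a broad ancestor, is the recoverable
    signal).
    """
    rng = _rng(seed, 5)
    direct_count: dict[str, int] = {}
    for terms in corpus.direct.values():
        for term in terms:
            direct_count[term] = direct_count.get(term, 0) + 1
    candidates = sorted(
        term for term, count in direct_count.items()
        if count >= params.true_hits and all(
            corpus.term_count.get(a, 0) > corpus.term_count[term]
            for a in corpus.dag.ancestors(term))
    )
    if not candidates:
        raise ValueError("no term has enough direct carriers for a hit table")
    proteins = sorted(corpus.proteins)

    lines: list[str] = []
    truth: dict[str, str] = {}
    for i in range(params.n_queries):
        query = f"{params.query_prefix}{i + 1:03d}"
        term = candidates[int(rng.integers(len(candidates)))]
        truth[query] = term
        carriers = sorted(p for p in proteins
                          if term in corpus.direct.get(p, ()))
        subjects = [carriers[j] for j in rng.choice(
            len(carriers), size=params.true_hits, replace=False)]
        for subject in subjects:
            e_value = 10.0 ** rng.uniform(-30, -3)
            lines.append(f"{query}\t{subject}\t{e_value:.3e}")
        for _ in range(params.decoy_hits):
            subject = proteins[int(rng.integers(len(proteins)))]
            e_value = 10.0 ** rng.uniform(0, math.log10(200.0))
            lines.append(f"{query}\t{subject}\t{e_value:.3e}")
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# full scenario


@dataclass
class SyntheticScenario:
    """Everything the pipeline consumes, under one seed."""

    seed: int = 0
    ontology: OntologyParams = field(default_factory=OntologyParams)
    corpus: CorpusParams = field(default_factory=CorpusParams)
    ppi: PPIParams = field(default_factory=PPIParams)
    genome: GenomeParams = field(default_factory=GenomeParams)
    hits: HitParams = field(default_factory=HitParams)
    window_size: int = 10_000


@dataclass
class ScenarioData:
    """Generated file texts plus the planted-structure manifest."""

    files: dict[str, str]     # filename -> text
    truth: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for filename, text in self.files.items():
            (outdir / filename).write_text(text)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))
        return outdir


def _deep_terms(dag: OntologyDAG, corpus_seed_rng: np.random.Generator,
                ) -> dict[str, str]:
    """One leaf term per namespace, for planted identical annotation."""
    chosen = {}
    for ns, root in sorted(dag.roots.items()):
        leaves = sorted(t for t in dag.terms
                        if dag.namespace_of[t] == ns and not dag.children(t))
        chosen[ns] = leaves[int(corpus_seed_rng.integers(len(leaves)))]
    return chosen


def generate_scenario(scenario: SyntheticScenario) -> ScenarioData:
    """Generate all input files for one scenario, coordinated so that
    planted genome clusters carry identical annotation sets and hit
    tables reference annotated proteins."""
    seed = scenario.seed
    genes_text, cluster_info = make_genome(scenario.genome, seed)
    rng = _rng(seed, 6)

    # planted clusters share one leaf term per namespace, per cluster
    obo_probe = make_obo(scenario.ontology, seed)
    dag = parse_obo(io.StringIO(obo_probe))
    identical_groups = []
    for info in cluster_info:
        terms = sorted(_deep_terms(dag, rng).values())
        info["terms"] = terms
        identical_groups.append((info["members"], terms))

    ppi_text = make_ppi(scenario.ppi, seed)
    gene_ids = [line.split("\t")[0]
                for line in genes_text.splitlines()[1:]]
    ppi_ids = sorted({p for line in ppi_text.splitlines()
                      for p in line.split("\t")})
    protein_ids = list(dict.fromkeys(gene_ids + ppi_ids))

    obo_text, gaf_text = make_ontology_and_corpus(
        scenario.ontology, scenario.corpus, seed,
        protein_ids=protein_ids, identical_groups=identical_groups)

    corpus = AnnotationCorpus.from_pairs(dag, read_gaf(io.StringIO(gaf_text)))
    hits_text, query_truth = make_hit_table(corpus, scenario.hits, seed)

    truth = {
        "seed": seed,
        "window_size": scenario.window_size,
        "planted_clusters": cluster_info,
        "planted_clique": (
            None if scenario.ppi.planted_clique is None else {
                "centroid": scenario.ppi.planted_clique.centroid,
                "size": scenario.ppi.planted_clique.size,
            }),
        "queries": query_truth,
        "parameters": {
            "ontology": asdict(scenario.ontology),
            "corpus": asdict(scenario.corpus),
        },
    }
    files = {
        "go.obo": obo_text,
        "annot.gaf": gaf_text,
        "ppi.tsv": ppi_text,
        "genes.tsv": genes_text,
        "hits.tsv": hits_text,
    }
    return ScenarioData(files=files, truth=truth)


def smoke_scenario(seed: int = 0) -> SyntheticScenario:
    """Small scenario for fast end-to-end checks.

    The ontology keeps a GO-like depth so leaf terms stay rare enough
    for planted clusters to stand out; everything else is minimal.
    """
    return SyntheticScenario(
        seed=seed,
        ontology=OntologyParams(depth=4, branching=3, cross_links=4),
        corpus=CorpusParams(n_proteins=40, annotated_fraction=0.9,
                            skew=0.7, max_terms_per_namespace=2),
        ppi=PPIParams(n=30, planted_clique=PlantedClique(size=5)),
        genome=GenomeParams(
            n_genes=30, n_chromosomes=1, planted_clusters=(
                PlantedCluster(size=4, chromosome="chr1"),)),
        hits=HitParams(n_queries=3, true_hits=3, decoy_hits=3),
        window_size=10_000,
    )


def paper_shaped_scenario(seed: int = 0) -> SyntheticScenario:
    """Study-scale scenario: a three-namespace DAG of a few hundred
    terms, a few hundred annotated proteins, a ~1000-edge scale-free
    PPI with a planted 6-clique, and a two-chromosome genome with two
    planted 5-gene coherent clusters (10 kb scan windows)."""
    return SyntheticScenario(
        seed=seed,
        ontology=OntologyParams(depth=5, branching=3, cross_links=12),
        corpus=CorpusParams(n_proteins=200, annotated_fraction=0.75,
                            skew=0.7, max_terms_per_namespace=2),
        ppi=PPIParams(n=500, edges_per_node=2,
                      planted_clique=PlantedClique(size=6)),
        genome=GenomeParams(
            n_genes=200, n_chromosomes=2, planted_clusters=(
                PlantedCluster(size=5, chromosome="chr1", name="cl1"),
                PlantedCluster(size=5, chromosome="chr2", name="cl2"),
            )),
        hits=HitParams(n_queries=10, true_hits=10, decoy_hits=5),
        window_size=10_000,
    )
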