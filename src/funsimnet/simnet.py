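"""Functional similarity networks and their topology statistics.

A functional similarity network connects two proteins when their
selected similarity score (BP, CC, MF or funSim) reaches a threshold;
the thresholds studied are 0.80, 0.95 and 0.99.  Topology summaries
report what distinguishes these networks from PPI networks: the degree
exponent gamma of the power-law degree distribution P(k) ~ k^-gamma,
the average clustering coefficient (modularity), and the clustering
degree exponent beta of C(k) ~ k^-beta, whose value near 1 is the
signature of hierarchical modularity.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, asdict
from typing import TextIO

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SCORE_KINDS",
    "DEFAULT_THRESHOLDS",
    "build_network",
    "clustering_coefficient",
    "fit_degree_exponent",
    "clustering_spectrum_beta",
    "network_summary",
    "TopologySummary",
    "write_edge_list",
    "write_sif",
    "power_law_histogram_graph",
    "hierarchical_network",
]

SCORE_KINDS = ("bp", "cc", "mf", "funsim")
DEFAULT_THRESHOLDS = (0.80, 0.95, 0.99)


def build_network(pairs: pd.DataFrame, score_kind: str,
                  threshold: float) -> nx.Graph:
    """Threshold a scored-pair table into an undirected network.

    An edge joins a pair whose *score_kind* value is present and at
    least *threshold*; every protein appearing in the table is kept as
    a node, so proteins whose scores all fall below the threshold remain
    as isolates (they still count in component fractions).
    """
    if score_kind not in SCORE_KINDS:
        raise ValueError(f"unknown score kind {score_kind!r}; "
                         f"expected one of {SCORE_KINDS}")
    net = nx.Graph(score_kind=score_kind, threshold=threshold)
    net.add_nodes_from(pd.unique(pairs[["protein_a", "protein_b"]]
                                 .values.ravel()))
    scored = pairs.dropna(subset=[score_kind])
    hits = scored[scored[score_kind] >= threshold]
    net.add_weighted_edges_from(
        hits[["protein_a", "protein_b", score_kind]].itertuples(index=False),
        weight="score",
    )
    return net


def clustering_coefficient(net: nx.Graph, node) -> float | None:
    """Fraction of a node's neighbor pairs that are directly connected.

    ``C = n / (k (k - 1) / 2)`` with ``k`` neighbors and ``n`` edges
    among them; undefined (``None``) below degree 2.
    """
    neighbors = [v for v in net.neighbors(node) if v != node]
    k = len(neighbors)
    if k < 2:
        return None
    n = sum(1 for u, v in itertools.combinations(neighbors, 2)
            if net.has_edge(u, v))
    return n / (k * (k - 1) / 2)


def _log_log_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS of log y on log x; returns (-slope, r_squared)."""
    result = stats.linregress(np.log(x), np.log(y))
    return float(-result.slope), float(result.rvalue ** 2)


def fit_degree_exponent(net: nx.Graph, min_degree: int = 1,
                        ) -> dict[str, float]:
    """Degree exponent gamma of P(k) ~ k^-gamma by log-log least squares.

    P(k) is the fraction of nodes of degree >= *min_degree* with degree
    exactly k; zero-count degrees are excluded and the straight-line fit
    is on raw (un-binned) frequencies.  Requires at least two distinct
    observed degrees.
    """
    degrees = [d for _, d in net.degree() if d >= min_degree]
    if not degrees:
        raise ValueError("no nodes at or above the minimum degree")
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least 2 distinct degrees to fit gamma")
    p_k = counts / len(degrees)
    gamma, r_squared = _log_log_fit(values.astype(float), p_k)
    return {"gamma": gamma, "r_squared": r_squared}


def clustering_spectrum(net: nx.Graph) -> pd.DataFrame:
    """Mean clustering coefficient per degree, ``C(k)`` for k >= 2."""
    by_degree: dict[int, list[float]] = {}
    for node in net.nodes:
        c = clustering_coefficient(net, node)
        if c is None:
            continue
        by_degree.setdefault(net.degree(node), []).append(c)
    rows = [(k, float(np.mean(cs)), len(cs))
            for k, cs in sorted(by_degree.items())]
    return pd.DataFrame(rows, columns=["k", "c_k", "n_nodes"])


def clustering_spectrum_beta(net: nx.Graph) -> dict[str, object]:
    """Clustering degree exponent beta of C(k) ~ k^-beta.

    Fits log C(k) on log k over degrees with C(k) > 0.  A flat spectrum
    gives beta = 0; a spectrum with no positive C(k) has no finite
    logarithm and raises ``ValueError``.
    """
    spectrum = clustering_spectrum(net)
    positive = spectrum[spectrum["c_k"] > 0]
    if len(spectrum) < 2:
        raise ValueError("need at least 2 distinct degrees with defined C(k)")
    if positive.empty:
        raise ValueError("all C(k) are zero; no finite log to fit")
    if len(positive) < 2:
        raise ValueError("need at least 2 positive C(k) values to fit beta")
    beta, r_squared = _log_log_fit(positive["k"].to_numpy(float),
                                   positive["c_k"].to_numpy(float))
    return {"beta": beta, "r_squared": r_squared, "spectrum": spectrum}


@dataclass
class TopologySummary:
    """Counts, component structure and power-law fits of one network."""

    n_nodes: int
    n_edges: int
    n_nodes_deg2plus: int
    largest_component_fraction: float
    avg_clustering: float | None
    gamma: float | None = None
    gamma_r_squared: float | None = None
    beta: float | None = None
    beta_r_squared: float | None = None
    fit_notes: str | None = None

    def to_json(self, destination: TextIO | str | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if destination is not None:
            if hasattr(destination, "write"):
                destination.write(text)
            else:
                with open(destination, "w") as handle:
                    handle.write(text)
        return text


def network_summary(net: nx.Graph) -> TopologySummary:
    """Aggregate topology statistics; failed fits become absent fields.

    The largest-component fraction is over all nodes including
    isolates; average clustering is over nodes of degree >= 2 only,
    where the clustering coefficient is defined.
    """
    n_nodes = net.number_of_nodes()
    n_edges = net.number_of_edges()
    deg2plus = [v for v in net.nodes if net.degree(v) >= 2]
    clusterings = [clustering_coefficient(net, v) for v in deg2plus]
    avg_clustering = float(np.mean(clusterings)) if clusterings else None
    if n_nodes:
        largest = max((len(c) for c in nx.connected_components(net)),
                      default=0)
        largest_fraction = largest / n_nodes
    else:
        largest_fraction = 0.0

    summary = TopologySummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_nodes_deg2plus=len(deg2plus),
        largest_component_fraction=largest_fraction,
        avg_clustering=avg_clustering,
    )
    notes = []
    try:
        fit = fit_degree_exponent(net)
        summary.gamma = fit["gamma"]
        summary.gamma_r_squared = fit["r_squared"]
    except ValueError as exc:
        notes.append(f"gamma fit skipped: {exc}")
    try:
        fit = clustering_spectrum_beta(net)
        summary.beta = fit["beta"]
        summary.beta_r_squared = fit["r_squared"]
    except ValueError as exc:
        notes.append(f"beta fit skipped: {exc}")
    summary.fit_notes = "; ".join(notes) or None
    return summary


def write_edge_list(net: nx.Graph, destination: TextIO | str) -> None:
    """Two-column TSV edge list (plus score when present)."""
    rows = [
        (u, v, data.get("score", ""))
        for u, v, data in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"]).to_csv(
        destination, sep="\t", index=False)


def write_sif(net: nx.Graph, destination: TextIO | str,
              relation: str = "sim") -> None:
    """Cytoscape SIF: ``node relation node`` per edge, isolates bare."""
    lines = [f"{u}\t{relation}\t{v}" for u, v in net.edges]
    lines += [str(v) for v in net.nodes if net.degree(v) == 0]
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w") as handle:
            handle.write(text)


def power_law_histogram_graph(gamma: float = 2.0,
                              degrees: tuple[int, ...] = (1, 2, 4, 8),
                              ) -> nx.Graph:
    """A simple graph whose degree histogram is exactly ~ k^-gamma.

    Degree counts are the smallest integers proportional to k^-gamma
    over the given degrees (which must make that possible, e.g. powers
    of 2 for gamma = 2); the sequence is realized by the Havel-Hakimi
    construction.  Useful as a fixture with a known exact exponent.
    """
    weights = [degrees[-1] ** gamma / (k ** gamma) for k in degrees]
    counts = [round(w) for w in weights]
    for k, w, c in zip(degrees, weights, counts):
        if not math.isclose(w, c):
            raise ValueError(
                f"count for degree {k} ({w}) is not an integer; "
                "choose degrees compatible with gamma")
    sequence = [k for k, c in zip(degrees, counts) for _ in range(c)]
    if sum(sequence) % 2:
        raise ValueError("degree sequence has odd sum; not realizable")
    return nx.havel_hakimi_graph(sequence)


def hierarchical_network(levels: int = 2, module_size: int = 5) -> nx.Graph:
    """Deterministic hierarchically modular network (replication model).

    Starts from a complete module of *module_size* nodes and, at each
    level, makes ``module_size - 1`` copies of the current network and
    wires every copied peripheral node to the original central hub.
    The construction's clustering spectrum follows C(k) ~ k^-1, the
    scaling-law signature of hierarchical modularity.
    """
    if module_size < 3 or levels < 0:
        raise ValueError("need module_size >= 3 and levels >= 0")
    net = nx.complete_graph(module_size)
    center = 0
    peripheral = set(range(1, module_size))
    for _ in range(levels):
        size = net.number_of_nodes()
        combined = nx.Graph(net)
        new_peripheral = set()
        for copy_index in range(1, module_size):
            offset = copy_index * size
            combined.add_edges_from(
                (u + offset, v + offset) for u, v in net.edges)
            new_peripheral |= {p + offset for p in peripheral}
        combined.add_edges_from((p, center) for p in new_peripheral)
        net, peripheral = combined, new_peripheral
    return net
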