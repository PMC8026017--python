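"""Directed word multigraphs and their attributes.

A speech graph maps each distinct word of a token window to a node and
each transition between successive words to a directed edge occurrence
(self-loops and parallel occurrences allowed).  Fifteen attributes are
computed per graph:

general        N (nodes), E (edge occurrences), WC (tokens);
recurrence     RE (repeated edges), PE (parallel edges),
               L1/L2/L3 (loops of one/two/three nodes);
connectivity   LCC/LSC (largest weakly/strongly connected component),
               ATD (average total degree);
global         D (density), DI (diameter), ASP (average shortest path),
               CC (mean clustering coefficient).

Conventions (documented, config-switchable where noted):

* E, RE, L1 and ATD count edge *occurrences* (multiplicity); D counts
  distinct directed non-self edges so that it stays in [0, 1].
* RE defaults to excess traversals, ``E - #distinct directed edges``;
  ``re_mode="total"`` instead counts every occurrence of a pair that is
  traversed more than once.
* DI, ASP and CC are computed on the undirected simple projection
  (self-loops dropped); DI/ASP are restricted to the largest weak
  component.  ``distance_mode="directed"`` switches DI/ASP to directed
  distances within the largest strongly connected component.
* Degenerate single-node graphs yield D = DI = ASP = CC = 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, fields
from typing import Iterable, Literal, Sequence

import networkx as nx

__all__ = [
    "SpeechGraph",
    "GraphAttributes",
    "ATTRIBUTE_NAMES",
    "EmptyWindowError",
    "build_graph",
    "recurrence_counts",
    "loop_counts",
    "largest_weakly_connected",
    "largest_strongly_connected",
    "global_measures",
    "compute_attributes",
    "write_edge_list",
]

ATTRIBUTE_NAMES = (
    "N", "E", "WC", "RE", "PE", "L1", "L2", "L3",
    "LCC", "LSC", "ATD", "D", "DI", "ASP", "CC",
)


class EmptyWindowError(ValueError):
    """Raised when a graph is requested for an empty token window."""


@dataclass(frozen=True)
class SpeechGraph:
    """Directed word multigraph with edge multiplicities.

    ``edges`` maps each ordered (source, target) pair to its occurrence
    count; ``token_count`` is the number of tokens that built the graph,
    so total occurrences equal ``token_count - 1``.
    """

    nodes: frozenset[str]
    edges: dict[tuple[str, str], int]
    token_count: int

    @property
    def edge_occurrences(self) -> int:
        return sum(self.edges.values())


@dataclass(frozen=True)
class GraphAttributes:
    N: int
    E: int
    WC: int
    RE: int
    PE: int
    L1: int
    L2: int
    L3: int
    LCC: int
    LSC: int
    ATD: float
    D: float
    DI: float
    ASP: float
    CC: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def build_graph(tokens: Sequence[str]) -> SpeechGraph:
    """Build the word multigraph from an ordered token window.

    One edge occurrence per consecutive token pair, including self-pairs
    for immediate repetitions.
    """
    if not tokens:
        raise EmptyWindowError("cannot build a graph from an empty window")
    edges = Counter(zip(tokens, tokens[1:]))
    return SpeechGraph(
        nodes=frozenset(tokens),
        edges=dict(edges),
        token_count=len(tokens),
    )


def _nx_multigraph(g: SpeechGraph) -> nx.MultiDiGraph:
    mg = nx.MultiDiGraph()
    mg.add_nodes_from(sorted(g.nodes))
    for (u, v), m in sorted(g.edges.items()):
        for _ in range(m):
            mg.add_edge(u, v)
    return mg


def _undirected_simple(g: SpeechGraph) -> nx.Graph:
    """Undirected simple projection, self-loops removed."""
    ug = nx.Graph()
    ug.add_nodes_from(sorted(g.nodes))
    ug.add_edges_from((u, v) for (u, v) in g.edges if u != v)
    return ug


def recurrence_counts(
    g: SpeechGraph, re_mode: Literal["excess", "total"] = "excess"
) -> tuple[int, int]:
    """Repeated-edge and parallel-edge counts (RE, PE).

    RE in the default ``excess`` mode is the number of edge occurrences
    beyond the first for each distinct directed pair, so fully
    non-repetitive text yields RE = 0.  PE counts unordered node pairs
    {a, b}, a != b, linked in both directions.
    """
    if re_mode == "excess":
        re_count = sum(m - 1 for m in g.edges.values())
    elif re_mode == "total":
        re_count = sum(m for m in g.edges.values() if m > 1)
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown re_mode {re_mode!r}")
    pe_count = sum(
        1
        for (u, v) in g.edges
        if u < v and (v, u) in g.edges
    )
    return re_count, pe_count


def loop_counts(g: SpeechGraph) -> tuple[int, int, int]:
    """Loops of one, two and three nodes (L1, L2, L3).

    L1 counts self-loop occurrences with multiplicity; L2 counts
    unordered reciprocal pairs; L3 counts directed 3-cycles over distinct
    node triples, once per cyclic class, ignoring multiplicity.
    """
    l1 = sum(m for (u, v), m in g.edges.items() if u == v)
    l2 = sum(1 for (u, v) in g.edges if u < v and (v, u) in g.edges)
    succ: dict[str, set[str]] = {}
    for (u, v) in g.edges:
        if u != v:
            succ.setdefault(u, set()).add(v)
    l3 = 0
    for a in succ:
        for b in succ[a]:
            for c in succ.get(b, ()):
                if c != a and a in succ.get(c, set()):
                    # each directed 3-cycle is seen from 3 rotations
                    l3 += 1
    l3 //= 3
    return l1, l2, l3


def largest_weakly_connected(g: SpeechGraph) -> int:
    """Node count of the largest component when direction is ignored."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes)
    dg.add_edges_from(g.edges)
    return max(len(c) for c in nx.weakly_connected_components(dg))


def largest_strongly_connected(g: SpeechGraph) -> int:
    """Node count of the largest strongly connected component."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes)
    dg.add_edges_from(g.edges)
    return max(len(c) for c in nx.strongly_connected_components(dg))


def global_measures(
    g: SpeechGraph,
    distance_mode: Literal["undirected", "directed"] = "undirected",
) -> tuple[float, float, float, float, float]:
    """ATD, D, DI, ASP and CC for one graph.

    ATD is 2E/N with E counted with multiplicity (a self-loop adds 2 to
    its node's degree).  D is distinct directed non-self edges over
    N(N-1).  DI/ASP are unweighted shortest-path statistics over
    unordered pairs in the largest weak component of the undirected
    simple projection (or directed distances within the largest strong
    component under ``distance_mode="directed"``).  CC is the mean local
    clustering coefficient over all nodes, 0 for degree < 2.
    """
    n = len(g.nodes)
    atd = 2.0 * g.edge_occurrences / n
    if n > 1:
        distinct_nonself = sum(1 for (u, v) in g.edges if u != v)
        density = distinct_nonself / (n * (n - 1))
    else:
        density = 0.0

    ug = _undirected_simple(g)
    cc = nx.average_clustering(ug) if n > 0 else 0.0

    if distance_mode == "undirected":
        comp = max(nx.connected_components(ug), key=len)
        sub = ug.subgraph(comp)
        if len(comp) > 1:
            di = float(nx.diameter(sub))
            asp = float(nx.average_shortest_path_length(sub))
        else:
            di = asp = 0.0
    elif distance_mode == "directed":
        dg = nx.DiGraph()
        dg.add_nodes_from(g.nodes)
        dg.add_edges_from((u, v) for (u, v) in g.edges if u != v)
        comp = max(nx.strongly_connected_components(dg), key=len)
        sub = dg.subgraph(comp)
        if len(comp) > 1:
            di = float(nx.diameter(sub))
            asp = float(nx.average_shortest_path_length(sub))
        else:
            di = asp = 0.0
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    return atd, density, di, asp, cc


def compute_attributes(
    tokens: Sequence[str],
    re_mode: Literal["excess", "total"] = "excess",
    distance_mode: Literal["undirected", "directed"] = "undirected",
) -> GraphAttributes:
    """All fifteen attributes for one token window."""
    g = build_graph(tokens)
    re_count, pe_count = recurrence_counts(g, re_mode=re_mode)
    l1, l2, l3 = loop_counts(g)
    atd, density, di, asp, cc = global_measures(g, distance_mode=distance_mode)
    return GraphAttributes(
        N=len(g.nodes),
        E=g.edge_occurrences,
        WC=len(tokens),
        RE=re_count,
        PE=pe_count,
        L1=l1,
        L2=l2,
        L3=l3,
        LCC=largest_weakly_connected(g),
        LSC=largest_strongly_connected(g),
        ATD=atd,
        D=density,
        DI=di,
        ASP=asp,
        CC=cc,
    )


def write_edge_list(g: SpeechGraph, path) -> None:
    """Export edges as ``source<TAB>target<TAB>multiplicity`` text."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tmultiplicity\n")
        for (u, v), m in sorted(g.edges.items()):
            fh.write(f"{u}\t{v}\t{m}\n")
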