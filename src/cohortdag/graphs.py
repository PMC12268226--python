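"""Causal-graph queries: paths, confounder/mediator roles, outcome parents.

Once the validated, thresholded adjacency is in hand, epidemiological
reasoning happens on the graph: which directed pathways connect an exposure
to the outcome, which variables mediate them, and which act as confounders.
A mediator lies on a directed path exposure -> ... -> outcome; a confounder
is an ancestor of both exposure and outcome that is not itself a mediator
(the common-ancestor reading of "associated with both exposure and outcome
but not an intermediary").
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .notears import WeightMatrix

__all__ = [
    "CausalGraph",
    "to_graph",
    "directed_paths",
    "classify_role",
    "outcome_parents",
]

#: Simple-path enumeration cap; queries report truncation explicitly.
MAX_PATHS = 10_000


@dataclass
class CausalGraph:
    """Directed acyclic graph with nonzero edge weights."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("graph contains a directed cycle")
        for u, v, w in self.graph.edges(data="weight"):
            if w == 0:
                raise ValueError(f"zero-weight edge {u} -> {v}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, float(w)) for u, v, w in self.graph.edges(data="weight")]

    def _check(self, *names: str) -> None:
        for name in names:
            if name not in self.graph:
                raise KeyError(f"unknown node {name!r}")

    def to_weight_matrix(self) -> WeightMatrix:
        nodes = self.nodes
        idx = {n: i for i, n in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for u, v, w in self.edges:
            W[idx[u], idx[v]] = w
        return WeightMatrix(W, nodes)

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v, w in self.edges:
            lines.append(f'  "{u}" -> "{v}" [weight={w:g}, label="{w:.3g}"];')
        lines.append("}")
        return "\n".join(lines)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def from_graphml(cls, path) -> "CausalGraph":
        g = nx.read_graphml(path)
        out = nx.DiGraph()
        out.add_nodes_from(g.nodes)
        for u, v, data in g.edges(data=True):
            out.add_edge(u, v, weight=float(data.get("weight", 1.0)))
        return cls(out)


def to_graph(w: WeightMatrix) -> CausalGraph:
    """One edge per nonzero entry; direction is row (parent) -> column (child)."""
    g = nx.DiGraph()
    g.add_nodes_from(w.nodes)
    rows, cols = np.nonzero(w.W)
    for i, j in zip(rows, cols):
        g.add_edge(w.nodes[i], w.nodes[j], weight=float(w.W[i, j]))
    return CausalGraph(g)


def directed_paths(
    cg: CausalGraph, source: str, target: str, max_paths: int = MAX_PATHS
) -> tuple[list[list[str]], bool]:
    """All simple directed paths source -> target, lexicographically ordered.

    Returns (paths, truncated); ``truncated`` is True when enumeration hit
    ``max_paths`` before exhausting the graph.
    """
    cg._check(source, target)
    if source == target:
        raise ValueError("source and target must differ")
    paths: list[list[str]] = []
    truncated = False
    for path in nx.all_simple_paths(cg.graph, source, target):
        paths.append(list(path))
        if len(paths) >= max_paths:
            truncated = True
            break
    paths.sort()
    return paths, truncated


def classify_role(cg: CausalGraph, exposure: str, outcome: str, variable: str) -> str:
    """Role of ``variable`` relative to an exposure-outcome pair.

    ``mediator``  — lies on some directed path exposure -> ... -> outcome;
    ``confounder`` — ancestor of both exposure and outcome, not a mediator;
    ``neither``   — otherwise.
    """
    cg._check(exposure, outcome, variable)
    if len({exposure, outcome, variable}) != 3:
        raise ValueError("exposure, outcome and variable must be distinct")
    g = cg.graph
    on_path = (
        nx.has_path(g, exposure, variable)
        and nx.has_path(g, variable, outcome)
    )
    if on_path:
        return "mediator"
    anc_exposure = nx.ancestors(g, exposure)
    anc_outcome = nx.ancestors(g, outcome)
    if variable in anc_exposure and variable in anc_outcome:
        return "confounder"
    return "neither"


def outcome_parents(cg: CausalGraph, outcome: str) -> list[tuple[str, float]]:
    """Direct parents of the outcome with weights, sorted by |weight| desc."""
    cg._check(outcome)
    parents = [
        (u, float(cg.graph[u][outcome]["weight"])) for u in cg.graph.predecessors(outcome)
    ]
    parents.sort(key=lambda it: (-abs(it[1]), it[0]))
    return parents
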