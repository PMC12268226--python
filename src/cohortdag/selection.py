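"""BIC scoring of discrete DAGs and elbow-based edge-weight thresholding.

The final hard threshold on |W| controls the sparsity of the reported DAG.
Candidate thresholds are scored by the decomposable discrete BIC

    score(G; D) = LL(G; D) - (ln N / 2) * dim(G),

where LL is the maximized multinomial log-likelihood (natural log) summed
over node families and dim(G) = sum_i (r_i - 1) * prod_{p in parents(i)} r_p
with r the level counts. Higher is better. The threshold is chosen at the
elbow of the (threshold, BIC) curve: the grid point of maximum perpendicular
distance to the chord joining the curve's endpoints after min-max
normalizing both axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ingest import Dataset
from .notears import WeightMatrix

__all__ = [
    "ThresholdCurve",
    "bic_score",
    "build_threshold_curve",
    "select_threshold",
    "apply_threshold",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.round(np.arange(0.0, 0.51, 0.01), 2))
#: Published reference threshold for the cohort pipeline.
REFERENCE_THRESHOLD = 0.1


@dataclass
class ThresholdCurve:
    """(threshold, edge count, BIC score) triples on an increasing grid."""

    thresholds: np.ndarray
    edge_counts: np.ndarray
    scores: np.ndarray
    skipped: list[float]

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.edge_counts = np.asarray(self.edge_counts, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any(np.diff(self.edge_counts) > 0):
            raise ValueError("edge count must be non-increasing in the threshold")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "edges": self.edge_counts, "bic": self.scores}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _cardinalities(data: Dataset) -> dict[str, int]:
    card = {}
    for spec in data.specs:
        if not spec.is_discrete:
            raise ValueError(f"column {spec.name!r} is continuous; BIC needs discrete data")
        card[spec.name] = spec.cardinality
    return card


def bic_score(graph: nx.DiGraph, data: Dataset) -> float:
    """Decomposable BIC of a discrete DAG fitted to the data (higher better).

    Every node of ``graph`` must be a discrete column of ``data``; the
    maximized log-likelihood uses observed conditional frequencies with the
    convention 0*log(0) = 0.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("graph contains a directed cycle")
    card = _cardinalities(data)
    df = data.to_frame()
    N = data.n
    penalty_unit = np.log(N) / 2.0
    score = 0.0
    for node in graph.nodes:
        if node not in card:
            raise KeyError(f"graph node {node!r} not in dataset")
        parents = sorted(graph.predecessors(node))
        score += _family_ll(df, node, parents) - penalty_unit * _family_dim(card, node, parents)
    return float(score)


def _family_ll(df: pd.DataFrame, node: str, parents: list[str]) -> float:
    """Maximized multinomial log-likelihood of one node given its parents."""
    if parents:
        counts = df.groupby(parents + [node], observed=True).size()
        totals = counts.groupby(level=list(range(len(parents)))).transform("sum")
    else:
        counts = df.groupby(node, observed=True).size()
        totals = counts.sum()
    c = counts.to_numpy(dtype=float)
    t = np.asarray(totals, dtype=float)
    return float(np.sum(c * (np.log(c) - np.log(t))))


def _family_dim(card: dict[str, int], node: str, parents: list[str]) -> float:
    dim = card[node] - 1
    for p in parents:
        dim *= card[p]
    return float(dim)


def apply_threshold(w: WeightMatrix, t: float) -> WeightMatrix:
    """Zero every entry with |weight| < t; leave the rest unchanged."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    W = w.W.copy()
    W[np.abs(W) < t] = 0.0
    return WeightMatrix(W, list(w.nodes), h=w.h, converged=w.converged,
                        n_dual_iter=w.n_dual_iter, loss=w.loss)


def _repair_cycles(W: np.ndarray, nodes: list[str]) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Drop the weakest edge on each remaining cycle until the support is a DAG."""
    W = W.copy()
    removed: list[tuple[str, str]] = []
    while True:
        g = nx.from_numpy_array(W != 0, create_using=nx.DiGraph)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return W, removed
        i, j = min(((e[0], e[1]) for e in cycle), key=lambda e: abs(W[e[0], e[1]]))
        W[i, j] = 0.0
        removed.append((nodes[i], nodes[j]))
        logger.info("cycle repair: removed edge %s -> %s", nodes[i], nodes[j])


def support_graph(w: WeightMatrix) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(w.nodes)
    rows, cols = np.nonzero(w.W)
    for i, j in zip(rows, cols):
        g.add_edge(w.nodes[i], w.nodes[j], weight=float(w.W[i, j]))
    return g


def build_threshold_curve(w: WeightMatrix, data: Dataset, grid=DEFAULT_GRID) -> ThresholdCurve:
    """Score the thresholded structure on the discrete data for each t.

    At each grid point, entries with |W| < t are zeroed, any residual cycle
    is repaired by removing its weakest edge (logged), and the resulting
    structure is scored with :func:`bic_score`. Grid points whose support
    cannot be scored are skipped and reported.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise ValueError("grid must be nonempty, strictly increasing, and >= 0")
    ts, counts, scores, skipped = [], [], [], []
    for t in grid:
        wt = apply_threshold(w, float(t))
        Wr, _ = _repair_cycles(wt.W, wt.nodes)
        wt = WeightMatrix(Wr, list(wt.nodes))
        try:
            s = bic_score(support_graph(wt), data)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("threshold %.3g skipped: %s", t, exc)
            skipped.append(float(t))
            continue
        ts.append(float(t))
        counts.append(int(np.count_nonzero(wt.W)))
        scores.append(s)
    return ThresholdCurve(np.array(ts), np.array(counts), np.array(scores), skipped)


def select_threshold(curve: ThresholdCurve) -> float:
    """Elbow of the BIC curve: maximum chord distance, ties to the smaller t.

    Both axes are min-max normalized to [0, 1]; each point's perpendicular
    distance to the straight line joining the first and last curve points is
    computed, and the threshold with the largest distance wins. A degenerate
    (exactly linear or constant) curve returns the smallest threshold.
    """
    t = curve.thresholds
    s = curve.scores
    if t.size < 3:
        raise ValueError("need at least 3 curve points to locate an elbow")
    tn = _minmax(t)
    sn = _minmax(s)
    p0 = np.array([tn[0], sn[0]])
    p1 = np.array([tn[-1], sn[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return float(t[0])
    pts = np.column_stack([tn, sn]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    # ties (within float noise) break toward the smaller threshold
    best = int(np.flatnonzero(dist >= dist.max() - 1e-12)[0])
    return float(t[best])


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)
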