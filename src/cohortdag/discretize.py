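"""Supervised MDL discretization (Fayyad-Irani recursive entropy partitioning).

Continuous features are binned against the binary study outcome before
structure learning. A candidate cut is the midpoint between adjacent sorted
values whose class composition differs (a boundary point); the cut with the
highest information gain is accepted only when the gain clears the
minimum-description-length criterion

    gain > log2(n-1)/n + delta/n,
    delta = log2(3^k - 2) - [k*Ent(S) - k1*Ent(S1) - k2*Ent(S2)],

with k the number of classes present in a segment and entropies in base 2.
Accepted cuts recurse independently into each side, so a feature may end up
with zero cuts (collapsing to a single level) or several.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .ingest import Dataset, FeatureSpec

__all__ = ["CutPointSet", "mdlp_cuts", "apply_cuts", "discretize_dataset"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutPointSet:
    """Strictly increasing thresholds partitioning one feature's axis."""

    feature: str
    cuts: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError(f"cuts for {self.feature!r} not strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.cuts) + 1


def _entropy(counts: np.ndarray) -> float:
    """Base-2 entropy of a class-count vector (0*log0 = 0)."""
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, labels: np.ndarray) -> tuple[int, float] | None:
    """Highest-gain boundary cut of a sorted segment, if it passes MDL.

    ``values`` must be sorted ascending. Returns (split position, cut value)
    where the left part is ``values[:pos]``, or None when no candidate cut
    survives the MDL criterion.
    """
    n = len(values)
    if n < 2:
        return None
    # class counts by cumulative prefix: counts_left[i] = counts in values[:i]
    c1 = np.cumsum(labels)
    total = np.array([n - c1[-1], c1[-1]], dtype=float)
    ent_s = _entropy(total)

    # candidates: every distinct-value midpoint (a superset of the class
    # boundary points, where the optimal cut is guaranteed to lie)
    pos = np.arange(1, n)
    distinct = values[1:] > values[:-1]
    cand = pos[distinct]
    if cand.size == 0:
        return None

    best = None
    best_gain = -np.inf
    for i in cand:
        left = np.array([i - c1[i - 1], c1[i - 1]], dtype=float)
        right = total - left
        ent_l = _entropy(left)
        ent_r = _entropy(right)
        gain = ent_s - (i / n) * ent_l - ((n - i) / n) * ent_r
        if gain > best_gain:
            best_gain = gain
            best = (int(i), ent_l, ent_r, left, right)
    if best is None:
        return None
    i, ent_l, ent_r, left, right = best
    k = int((total > 0).sum())
    k1 = int((left > 0).sum())
    k2 = int((right > 0).sum())
    delta = np.log2(3.0**k - 2.0) - (k * ent_s - k1 * ent_l - k2 * ent_r)
    threshold = np.log2(n - 1) / n + delta / n
    if best_gain <= threshold:
        return None
    cut = float((values[i - 1] + values[i]) / 2.0)
    return i, cut


def mdlp_cuts(values, labels, feature: str = "") -> CutPointSet:
    """Recursive MDL-accepted cut points of one feature against binary labels."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.ndim != 1 or labels.shape != values.shape:
        raise ValueError("values and labels must be equal-length vectors")
    if len(values) < 2:
        raise ValueError("need at least two observations")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1, 0.0, 1.0}:
        raise ValueError(f"labels must be binary 0/1, saw {sorted(uniq)}")
    labels = labels.astype(int)

    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    # within ties of v, sort labels so prefix counts are well defined per value
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        res = _best_cut(v[lo:hi], y[lo:hi])
        if res is None:
            return
        i, cut = res
        cuts.append(cut)
        recurse(lo, lo + i)
        recurse(lo + i, hi)

    recurse(0, len(v))
    return CutPointSet(feature=feature, cuts=tuple(sorted(cuts)))


def apply_cuts(values, cutset: CutPointSet) -> np.ndarray:
    """Map each value to its bin index: the count of cuts strictly below it.

    Bins are left-closed/right-open at each cut: a value equal to a cut
    falls into the bin to the cut's right.
    """
    values = np.asarray(values, dtype=float)
    if not cutset.cuts:
        return np.zeros(values.shape, dtype=int)
    return np.searchsorted(np.asarray(cutset.cuts), values, side="right").astype(int)


def discretize_dataset(
    dataset: Dataset, drop_constant: bool = True
) -> tuple[Dataset, dict[str, CutPointSet]]:
    """Replace every continuous column by its MDLP codes.

    The binary study outcome supervises every feature. Discrete columns pass
    through unchanged; discretized columns get ordinal specs whose levels
    name the induced half-open intervals. Features where MDLP accepts no cut
    collapse to a single constant level; these are uninformative and, when
    ``drop_constant`` is true, removed from the returned dataset with a
    logged warning.

    Returns the discretized dataset and the feature -> cut-point mapping.
    """
    y = dataset.values[:, dataset.outcome_index].astype(int)
    cutsets: dict[str, CutPointSet] = {}
    new_specs: list[FeatureSpec] = []
    new_cols: list[np.ndarray] = []
    for j, spec in enumerate(dataset.specs):
        col = dataset.values[:, j]
        if spec.is_discrete:
            new_specs.append(spec)
            new_cols.append(col)
            continue
        cs = mdlp_cuts(col, y, feature=spec.name)
        cutsets[spec.name] = cs
        if cs.n_levels == 1:
            msg = f"MDLP accepted no cut for {spec.name!r}; column is constant"
            if drop_constant:
                logger.warning("%s - excluded from structure learning", msg)
                warnings.warn(msg + " - excluded", stacklevel=2)
                continue
        codes = apply_cuts(col, cs)
        levels = _interval_labels(cs)
        scale = "binary" if cs.n_levels == 2 else "ordinal"
        if cs.n_levels == 1:
            scale = "ordinal"
            levels = (levels[0], "(unused)")  # single observed level
        new_specs.append(FeatureSpec(spec.name, scale, levels))
        new_cols.append(codes.astype(float))
    out = Dataset(np.column_stack(new_cols), new_specs, dataset.dropped)
    return out, cutsets


def _interval_labels(cs: CutPointSet) -> tuple[str, ...]:
    edges = ["-inf", *(f"{c:g}" for c in cs.cuts), "inf"]
    return tuple(f"[{a}, {b})" for a, b in zip(edges, edges[1:]))


def cuts_to_json(cutsets: dict[str, CutPointSet]) -> str:
    """Cut points as JSON (feature -> list of thresholds) for audit/re-use."""
    return json.dumps({k: list(v.cuts) for k, v in cutsets.items()}, indent=2)


def cuts_from_json(text: str) -> dict[str, CutPointSet]:
    return {k: CutPointSet(k, tuple(v)) for k, v in json.loads(text).items()}
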