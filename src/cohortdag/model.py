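"""Model/Results surface tying the pipeline stages together.

`CausalStructureModel` holds an encoded cohort; `fit()` runs supervised
discretization (when continuous columns are present) followed by
constrained structure learning and returns a `CausalStructureResults`
carrying the weighted adjacency. The results object exposes the follow-up
stages — permutation validation, BIC threshold selection, graph queries —
and a text `summary()`.

    >>> model = CausalStructureModel(dataset)
    >>> res = model.fit()
    >>> res.validate_edges(PermutationConfig(B=200, master_seed=1))
    >>> graph = res.final_graph()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import CutPointSet, discretize_dataset
from .graphs import CausalGraph, to_graph
from .group_stats import build_comparison_table
from .ingest import Dataset, FeatureSpec, encode, load_specs
from .notears import FitSettings, WeightMatrix, notears_fit
from .selection import (
    DEFAULT_GRID,
    REFERENCE_THRESHOLD,
    ThresholdCurve,
    apply_threshold,
    build_threshold_curve,
    select_threshold,
)
from .validation import EdgePValues, PermutationConfig, edge_pvalues, prune_insignificant

__all__ = ["CausalStructureModel", "CausalStructureResults"]


class CausalStructureModel:
    """Linear-SEM causal structure model of an encoded cohort table."""

    def __init__(self, dataset: Dataset):
        if not isinstance(dataset, Dataset):
            raise TypeError("expected a Dataset; use from_dataframe/from_csv for raw tables")
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, raw: pd.DataFrame, specs) -> "CausalStructureModel":
        """Build from a raw labelled table plus feature specs (or a config)."""
        if not (specs and isinstance(specs[0], FeatureSpec)):
            specs = load_specs(specs)
        return cls(encode(raw, specs))

    @classmethod
    def from_csv(cls, csv_path, spec_path) -> "CausalStructureModel":
        return cls(encode(csv_path, load_specs(spec_path)))

    def fit(self, settings: FitSettings | None = None, discretize: bool = True) -> "CausalStructureResults":
        """Discretize continuous columns (MDLP vs the outcome) and learn W."""
        settings = settings or FitSettings()
        cutsets: dict[str, CutPointSet] = {}
        data = self.dataset
        if discretize and any(not s.is_discrete for s in data.specs):
            data, cutsets = discretize_dataset(data)
        weights = notears_fit(data.values, settings, nodes=data.names)
        return CausalStructureResults(self, data, weights, settings, cutsets)


@dataclass
class CausalStructureResults:
    """Fitted structure plus the validation/selection stages."""

    model: CausalStructureModel
    data: Dataset  # fully discrete fitting data
    weights: WeightMatrix
    settings: FitSettings
    cutsets: dict[str, CutPointSet] = field(default_factory=dict)
    pvalues: EdgePValues | None = None
    pruned: WeightMatrix | None = None
    curve: ThresholdCurve | None = None
    threshold: float | None = None

    def validate_edges(self, config: PermutationConfig | None = None) -> EdgePValues:
        """Permutation-test every edge and prune the insignificant ones."""
        config = config or PermutationConfig()
        w_obs, self.pvalues = edge_pvalues(self.data, self.settings, config)
        # keep the original fit; the refit inside edge_pvalues is identical
        self.pruned = prune_insignificant(self.weights, self.pvalues, config.alpha)
        return self.pvalues

    def _working_weights(self) -> WeightMatrix:
        return self.pruned if self.pruned is not None else self.weights

    def threshold_curve(self, grid=DEFAULT_GRID) -> ThresholdCurve:
        self.curve = build_threshold_curve(self._working_weights(), self.data, grid)
        return self.curve

    def select_threshold(self, grid=DEFAULT_GRID) -> float:
        if self.curve is None:
            self.threshold_curve(grid)
        self.threshold = select_threshold(self.curve)
        return self.threshold

    def final_weights(self, threshold: float | None = None) -> WeightMatrix:
        """Validated, thresholded adjacency (threshold: given > selected > 0.1)."""
        t = threshold if threshold is not None else self.threshold
        if t is None:
            t = REFERENCE_THRESHOLD
        return apply_threshold(self._working_weights(), t)

    def final_graph(self, threshold: float | None = None) -> CausalGraph:
        return to_graph(self.final_weights(threshold))

    def comparison_table(self) -> pd.DataFrame:
        """Baseline two-group comparison of the original (pre-MDLP) table."""
        return build_comparison_table(self.model.dataset)

    def summary(self, threshold: float | None = None, top: int = 20) -> str:
        w = self.final_weights(threshold)
        rows, cols = np.nonzero(w.W)
        entries = []
        for i, j in zip(rows, cols):
            p = self.pvalues.P[i, j] if self.pvalues is not None else None
            entries.append((w.nodes[i], w.nodes[j], w.W[i, j], p))
        entries.sort(key=lambda e: -abs(e[2]))
        lines = [
            "Causal structure fit",
            "====================",
            f"nodes: {w.d}   edges: {len(entries)}   h(W): {self.weights.h:.3g}",
            f"loss: {self.weights.loss:.4f}   converged: {self.weights.converged}",
            f"threshold: {threshold if threshold is not None else (self.threshold if self.threshold is not None else REFERENCE_THRESHOLD)}",
            "",
            f"{'parent':<28}{'child':<28}{'weight':>10}{'perm. p':>10}",
            "-" * 76,
        ]
        for u, v, wt, p in entries[:top]:
            ptxt = f"{p:.4f}" if p is not None else "-"
            lines.append(f"{u:<28}{v:<28}{wt:>10.3f}{ptxt:>10}")
        if len(entries) > top:
            lines.append(f"... ({len(entries) - top} more edges)")
        return "\n".join(lines)
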