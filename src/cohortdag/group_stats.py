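"""Two-group comparison machinery for cohort tables.

Mirrors the standard baseline-characteristics table of an epidemiological
study: continuous features are compared between outcome groups with a
Welch (unequal-variance) t-test — computable from printed summaries alone —
and categorical features with a global Pearson chi-square over all levels
plus level-vs-rest 2x2 chi-squares, all without continuity correction and
without multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .ingest import Dataset

__all__ = [
    "welch_t_from_summary",
    "chi2_global",
    "chi2_per_level",
    "counts_from_percentages",
    "build_comparison_table",
]


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df and two-sided p.

    Works from group summaries (mean, SD, n), so printed table rows can be
    re-tested without the raw data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi2_global(table) -> tuple[float, float, float]:
    """Pearson chi-square of an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) <= 0).any() or (table.sum(axis=1) <= 0).any():
        raise ValueError("every row and column must have positive total")
    res = scipy.stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.dof), float(res.pvalue)


def chi2_per_level(levels, group_counts, level) -> tuple[float, float, float]:
    """Level-vs-rest 2x2 chi-square for one level of a categorical feature.

    ``group_counts`` is an r x 2 array of counts (rows = levels in the order
    of ``levels``, columns = groups).
    """
    levels = list(levels)
    if level not in levels:
        raise KeyError(f"level {level!r} not among {levels}")
    counts = np.asarray(group_counts, dtype=float)
    k = levels.index(level)
    row = counts[k]
    rest = counts.sum(axis=0) - row
    return chi2_global(np.array([row, rest]))


def counts_from_percentages(percentages, n: int) -> np.ndarray:
    """Reconstruct integer level counts from printed percentages of group size n."""
    return np.array([int(round(p * n / 100.0)) for p in percentages])


@dataclass
class FeatureComparison:
    """One row of the comparison table."""

    feature: str
    kind: str  # "continuous" or "categorical"
    summary: dict
    statistic: float
    p_value: float
    per_level: dict[str, float | None] | None = None


def build_comparison_table(dataset: Dataset) -> pd.DataFrame:
    """Group comparison of every feature against the binary outcome.

    One row per feature (plus one per categorical level): continuous rows
    carry mean±SD per group and the Welch p; categorical rows carry
    per-level percentages, the global chi-square p and level-vs-rest
    p-values. Levels unobserved in one group entirely (zero count in both
    margins impossible) but absent overall are reported not-applicable.
    """
    y = dataset.values[:, dataset.outcome_index].astype(int)
    groups = (y == 0, y == 1)
    if not (groups[0].any() and groups[1].any()):
        raise ValueError("empty group: outcome column is constant")
    rows = []
    for j, spec in enumerate(dataset.specs):
        if spec.is_outcome:
            continue
        col = dataset.values[:, j]
        if not spec.is_discrete:
            m = [col[g].mean() for g in groups]
            s = [col[g].std(ddof=1) for g in groups]
            n = [int(g.sum()) for g in groups]
            t, df, p = welch_t_from_summary(m[0], s[0], n[0], m[1], s[1], n[1])
            rows.append(
                {
                    "feature": spec.name,
                    "level": "",
                    "kind": "continuous",
                    "group0": f"{m[0]:.2f}±{s[0]:.2f}",
                    "group1": f"{m[1]:.2f}±{s[1]:.2f}",
                    "statistic": t,
                    "p_value": p,
                }
            )
        else:
            counts = np.zeros((spec.cardinality, 2))
            for gi, g in enumerate(groups):
                vals, cnt = np.unique(col[g].astype(int), return_counts=True)
                counts[vals, gi] = cnt
            present = counts.sum(axis=1) > 0
            chi2, dof, p = chi2_global(counts[present])
            rows.append(
                {
                    "feature": spec.name,
                    "level": "(overall)",
                    "kind": "categorical",
                    "group0": "",
                    "group1": "",
                    "statistic": chi2,
                    "p_value": p,
                }
            )
            totals = counts.sum(axis=0)
            for k, lev in enumerate(spec.levels):
                pct = 100.0 * counts[k] / totals
                if counts[k].sum() == 0:
                    lp = np.nan  # zero-count level: test not applicable
                    stat = np.nan
                else:
                    stat, _, lp = chi2_per_level(list(spec.levels), counts, lev)
                rows.append(
                    {
                        "feature": spec.name,
                        "level": lev,
                        "kind": "categorical",
                        "group0": f"{pct[0]:.2f}%",
                        "group1": f"{pct[1]:.2f}%",
                        "statistic": stat,
                        "p_value": lp,
                    }
                )
    return pd.DataFrame(rows)


def comparison_to_markdown(table: pd.DataFrame) -> str:
    cols = list(table.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in table.iterrows():
        cells = [
            f"{v:.4g}" if isinstance(v, float) and np.isfinite(v) else ("-" if isinstance(v, float) and np.isnan(v) else str(v))
            for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
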