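"""Cohort-table ingestion: feature specifications and categorical encoding.

Epidemiological registries arrive as one row per patient and one column per
feature, with a mix of continuous measurements (age, lipid panels), ordered
categories (education, sleep duration), unordered categories (occupation,
cooking oil) and presence/absence indicators. Structure learning downstream
needs a fully numeric matrix, so every discrete column is mapped to integer
codes: ordinal levels in their real-world order, nominal levels in declared
order, and binary features as 0 = absent, 1 = present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Scale",
    "FeatureSpec",
    "Dataset",
    "load_specs",
    "encode",
    "decode",
]

#: Recognised measurement scales.
SCALES = ("continuous", "ordinal", "nominal", "binary")


class SpecError(ValueError):
    """Raised when a feature specification violates its contract."""


@dataclass(frozen=True)
class FeatureSpec:
    """Per-column metadata: measurement scale and label encoding.

    Parameters
    ----------
    name : str
        Column identifier.
    scale : str
        One of ``continuous``, ``ordinal``, ``nominal``, ``binary``.
    levels : tuple of str, optional
        Category labels for discrete scales, in code order (ordinal order
        for ordinal features, declared order for nominal, (absent, present)
        for binary).
    is_outcome : bool
        Marks the single binary outcome column of a study.
    """

    name: str
    scale: str
    levels: tuple[str, ...] = ()
    is_outcome: bool = False

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise SpecError(f"unknown scale {self.scale!r} for {self.name!r}")
        if self.scale == "continuous":
            if self.levels:
                raise SpecError(f"continuous feature {self.name!r} cannot declare levels")
        else:
            if len(self.levels) < 2:
                raise SpecError(f"discrete feature {self.name!r} needs >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise SpecError(f"duplicate levels in {self.name!r}")
        if self.scale == "binary" and len(self.levels) != 2:
            raise SpecError(f"binary feature {self.name!r} needs exactly 2 levels")
        if self.is_outcome and self.scale != "binary":
            raise SpecError(f"outcome {self.name!r} must be binary")

    @property
    def is_discrete(self) -> bool:
        return self.scale != "continuous"

    @property
    def codes(self) -> dict[str, int]:
        """Label -> integer code, assigned by level order (first level -> 0)."""
        return {lev: i for i, lev in enumerate(self.levels)}

    @property
    def cardinality(self) -> int:
        """Number of levels (0 means unconstrained/continuous)."""
        return len(self.levels)

    def label_of(self, code: int) -> str:
        return self.levels[int(code)]


def _validate_spec_set(specs: Sequence[FeatureSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SpecError(f"duplicate feature names: {dupes}")
    outcomes = [s.name for s in specs if s.is_outcome]
    if len(outcomes) != 1:
        raise SpecError(
            f"exactly one outcome flag required, found {len(outcomes)}: {outcomes}"
        )


def load_specs(config_source) -> list[FeatureSpec]:
    """Parse a feature-specification config into :class:`FeatureSpec` objects.

    ``config_source`` may be a path to a YAML/JSON file, a YAML/JSON string,
    or an already-parsed list of mappings. Each entry declares ``name``,
    ``scale``, optionally ``levels`` (required for discrete scales) and
    ``outcome: true`` for the single binary outcome column.
    """
    entries = _coerce_config(config_source)
    specs = []
    for entry in entries:
        if not isinstance(entry, Mapping):
            raise SpecError(f"config entry is not a mapping: {entry!r}")
        unknown = set(entry) - {"name", "scale", "levels", "outcome"}
        if unknown:
            raise SpecError(f"unknown config keys {sorted(unknown)} in {entry.get('name')!r}")
        try:
            name = str(entry["name"])
            scale = str(entry["scale"])
        except KeyError as exc:
            raise SpecError(f"config entry missing {exc} field: {entry!r}") from None
        levels = tuple(str(v) for v in entry.get("levels", ()))
        if scale == "ordinal" and not levels:
            raise SpecError(f"ordinal feature {name!r} declares no level order")
        specs.append(
            FeatureSpec(
                name=name,
                scale=scale,
                levels=levels,
                is_outcome=bool(entry.get("outcome", False)),
            )
        )
    _validate_spec_set(specs)
    return specs


def _coerce_config(source) -> list:
    if isinstance(source, (list, tuple)):
        return list(source)
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))
    ):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        raise SpecError(f"cannot interpret config source of type {type(source).__name__}")
    parsed = yaml.safe_load(text)  # YAML superset also covers JSON
    if not isinstance(parsed, list):
        raise SpecError("feature config must be a list of per-column entries")
    return parsed


@dataclass
class Dataset:
    """Encoded numeric cohort table with its feature specifications.

    ``values`` is an ``n x d`` float array; discrete columns hold integer
    codes, continuous columns real measurements. ``dropped`` counts rows
    removed during ingestion because of missing or unparseable cells.
    """

    values: np.ndarray
    specs: list[FeatureSpec]
    dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, d = self.values.shape
        if d != len(self.specs):
            raise ValueError(f"{d} columns but {len(self.specs)} specs")
        if n < 1 or d < 2:
            raise ValueError(f"need n >= 1 and d >= 2, got n={n}, d={d}")
        if not np.isfinite(self.values).all():
            raise ValueError("dataset contains non-finite values after ingestion")
        for j, spec in enumerate(self.specs):
            if spec.is_discrete:
                col = self.values[:, j]
                valid = set(range(spec.cardinality))
                seen = set(np.unique(col).astype(int))
                if not np.array_equal(col, np.round(col)) or not seen <= valid:
                    raise ValueError(f"column {spec.name!r} holds codes outside its spec")
        _validate_spec_set(self.specs)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def outcome_index(self) -> int:
        return next(i for i, s in enumerate(self.specs) if s.is_outcome)

    @property
    def outcome_name(self) -> str:
        return self.specs[self.outcome_index].name

    def spec_of(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Encoded table as a DataFrame (integer codes for discrete columns)."""
        df = pd.DataFrame(self.values, columns=self.names)
        for s in self.specs:
            if s.is_discrete:
                df[s.name] = df[s.name].astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def replace_values(self, values: np.ndarray, specs: list[FeatureSpec] | None = None) -> "Dataset":
        return Dataset(values, specs if specs is not None else list(self.specs), self.dropped)


def encode(raw_table, specs: Sequence[FeatureSpec]) -> Dataset:
    """Encode a raw labelled table into a numeric :class:`Dataset`.

    ``raw_table`` is a :class:`pandas.DataFrame` or a CSV path. Discrete
    cells are replaced by their declared integer codes; continuous cells are
    parsed as floats. Rows with any missing or unparseable cell are dropped
    (listwise deletion) and counted in ``Dataset.dropped``.

    Raises
    ------
    SpecError
        If a column has no spec or a discrete cell holds an undeclared label
        (a spec/data mismatch, as opposed to missingness).
    ValueError
        If every row is dropped.
    """
    specs = list(specs)
    _validate_spec_set(specs)
    if isinstance(raw_table, (str, Path)):
        raw_table = pd.read_csv(raw_table, dtype=str, keep_default_na=True)
    df = raw_table.copy()
    missing_cols = [s.name for s in specs if s.name not in df.columns]
    if missing_cols:
        raise SpecError(f"raw table lacks columns {missing_cols}")

    n = len(df)
    encoded = np.full((n, len(specs)), np.nan)
    for j, spec in enumerate(specs):
        col = df[spec.name]
        if spec.is_discrete:
            labels = col.astype("string")
            mapped = labels.map({str(k): v for k, v in spec.codes.items()})
            unseen = labels.notna() & mapped.isna()
            if unseen.any():
                bad = sorted(labels[unseen].unique())
                raise SpecError(f"undeclared labels {bad} in column {spec.name!r}")
            encoded[:, j] = mapped.to_numpy(dtype=float, na_value=np.nan)
        else:
            encoded[:, j] = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)

    keep = ~np.isnan(encoded).any(axis=1)
    dropped = int(n - keep.sum())
    if keep.sum() == 0:
        raise ValueError("all rows dropped during ingestion")
    return Dataset(encoded[keep], specs, dropped=dropped)


def decode(dataset: Dataset) -> pd.DataFrame:
    """Inverse of :func:`encode` for retained rows: codes back to labels."""
    df = dataset.to_frame().astype(object)
    for s in dataset.specs:
        if s.is_discrete:
            df[s.name] = [s.label_of(c) for c in dataset.column(s.name)]
    return df


def specs_to_json(specs: Sequence[FeatureSpec]) -> str:
    entries = []
    for s in specs:
        e: dict = {"name": s.name, "scale": s.scale}
        if s.levels:
            e["levels"] = list(s.levels)
        if s.is_outcome:
            e["outcome"] = True
        entries.append(e)
    return json.dumps(entries, indent=2)
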