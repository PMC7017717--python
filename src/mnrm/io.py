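"""Readers, writers, and configuration parsing.

Response matrices travel as CSV: a header row of item identifiers, one row
per person, integer category codes, empty cells or ``NA`` marking missing
responses.  An optional leading ``person``/``id`` column supplies person
identifiers.  Model configurations are JSON or YAML naming the latent
dimensions and their scoring functions (templates or explicit vectors);
item parameters round-trip through CSV at full precision, one row per item
with slope columns ``a_<dim>`` followed by intercepts ``c_0..c_{K-1}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .model import (
    ItemParameters,
    MNRMModel,
    ResponseMatrix,
    ScoringFunctionSet,
    scoring_template,
)

__all__ = [
    "ModelConfig",
    "load_responses",
    "load_config",
    "write_parameters",
    "read_parameters",
    "write_scores",
    "write_table",
]

_ID_COLUMNS = {"person", "person_id", "id", "subject"}


@dataclass
class DimensionSpec:
    label: str
    scoring: object  # template name, vector, or per-item vectors
    role: str = "substantive"


@dataclass
class ModelConfig:
    """Validated model configuration.

    Holds the dimension specs, grid and estimation settings, and — once
    bound to data via :meth:`scoring_for` — the expanded scoring-function
    set.  Validation is total: any error aborts construction, so no
    partially built configuration escapes.
    """

    dimensions: list[DimensionSpec]
    n_categories: object | None = None  # int, or mapping item id -> K
    grid: dict = field(default_factory=dict)
    estimation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [d.label for d in self.dimensions]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"dimension labels must be unique: {labels}")
        if not self.dimensions:
            raise ValidationError("configuration names no dimensions")

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.dimensions]

    def categories_for(self, responses: ResponseMatrix) -> np.ndarray:
        if self.n_categories is None:
            return responses.K
        if isinstance(self.n_categories, int):
            return np.full(responses.n_items, self.n_categories, dtype=int)
        try:
            return np.array(
                [int(self.n_categories[i]) for i in responses.item_ids]
            )
        except KeyError as e:
            raise ValidationError(f"no category count for item {e}") from None

    def scoring_for(self, responses: ResponseMatrix) -> ScoringFunctionSet:
        """Expand templates for the data's items and run the
        identification rank check."""
        Ks = self.categories_for(responses)
        templates = []
        for spec in self.dimensions:
            sc = spec.scoring
            if isinstance(sc, dict):
                try:
                    sc = [sc[i] for i in responses.item_ids]
                except KeyError as e:
                    raise ValidationError(
                        f"dimension {spec.label!r}: no scoring vector for item {e}"
                    ) from None
            templates.append(sc)
        return ScoringFunctionSet.from_templates(self.labels, templates, Ks)


def load_responses(
    path: str | Path, K: object | None = None
) -> ResponseMatrix:
    """Read a response CSV into a :class:`ResponseMatrix`.

    Category counts are taken from ``K`` (an int, or a per-item mapping) or
    inferred as 1 + the maximum observed code per item.  Out-of-range or
    non-integer cells raise errors naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, na_values=["NA", "na", ""], skipinitialspace=True)
    if df.columns.size and df.columns[0].strip().lower() in _ID_COLUMNS:
        df = df.set_index(df.columns[0])
    for col in df.columns:
        vals = df[col].dropna()
        bad = vals[~vals.apply(lambda v: float(v) == int(float(v)))]
        if len(bad):
            row = bad.index[0]
            raise ValidationError(
                f"non-integer response {bad.iloc[0]!r} at row {row!r}, "
                f"column {col!r}"
            )
    Ks = None
    if K is not None:
        if isinstance(K, int):
            Ks = [K] * df.shape[1]
        else:
            Ks = [int(K[c]) for c in df.columns]
    return ResponseMatrix.from_dataframe(df, K=Ks)


def load_config(path: str | Path) -> ModelConfig:
    """Parse a JSON or YAML model configuration.

    Runs the scoring-function expansion rules but defers the per-item
    identification check to :meth:`ModelConfig.scoring_for`, which needs the
    data's category counts; with ``n_categories`` given, the check runs
    immediately on a dummy item set so redundant dimension definitions are
    rejected at load time.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "dimensions" not in raw:
        raise ValidationError(f"{path}: expected a mapping with 'dimensions'")
    dims = []
    for i, d in enumerate(raw["dimensions"]):
        if not isinstance(d, dict) or "label" not in d or "scoring" not in d:
            raise ValidationError(
                f"{path}: dimension entry {i} needs 'label' and 'scoring'"
            )
        dims.append(
            DimensionSpec(
                label=str(d["label"]),
                scoring=d["scoring"],
                role=str(d.get("role", "substantive")),
            )
        )
    cfg = ModelConfig(
        dimensions=dims,
        n_categories=raw.get("n_categories"),
        grid=dict(raw.get("grid", {})),
        estimation=dict(raw.get("estimation", {})),
    )
    if isinstance(cfg.n_categories, int):
        # eager identification check on a nominal single item
        K = cfg.n_categories
        templates = []
        for spec in cfg.dimensions:
            sc = spec.scoring
            if isinstance(sc, dict):
                sc = next(iter(sc.values()))
            templates.append(sc)
        ScoringFunctionSet.from_templates(cfg.labels, templates, [K])
    return cfg


def write_parameters(
    path: str | Path, model: MNRMModel, item_ids: list[str] | None = None
) -> None:
    """Write item parameters as CSV at full precision (round-trip exact)."""
    rows = []
    for j, item in enumerate(model.items):
        row: dict = {"item": item_ids[j] if item_ids else f"item{j + 1}"}
        for d, lab in enumerate(model.labels):
            row[f"a_{lab}"] = repr(float(item.a[d]))
        for k in range(item.K):
            row[f"c_{k}"] = repr(float(item.c[k]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_parameters(
    path: str | Path, scoring: ScoringFunctionSet, R: np.ndarray | None = None
) -> MNRMModel:
    """Read a parameter CSV (as written by :func:`write_parameters`) into a
    model bound to the given scoring functions."""
    df = pd.read_csv(Path(path))
    a_cols = [f"a_{lab}" for lab in scoring.labels]
    for col in a_cols:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing slope column {col!r}")
    c_cols = sorted(
        (c for c in df.columns if c.startswith("c_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    items = []
    for _, row in df.iterrows():
        c = row[c_cols].astype(float).to_numpy()
        c = c[~np.isnan(c)]  # items may differ in K
        items.append(ItemParameters(a=row[a_cols].astype(float).to_numpy(), c=c))
    return MNRMModel(items=items, scoring=scoring, R=R)


def write_scores(path: str | Path, frame: pd.DataFrame) -> None:
    """Write a per-person score table as CSV at full precision."""
    frame.to_csv(path, index_label="person", float_format="%.17g")


def write_table(path: str | Path, table) -> None:
    """Write a translation table as CSV (v, p, EAP, SD)."""
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
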