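"""Typed feature tables for mixed-type clinical cohorts.

A cohort is a patients x features table in which every feature is declared
as ``continuous``, ``binary`` or ``categorical`` by a companion schema.
The schema also carries per-feature Gower weights and a ``log_transform``
flag for skewed non-negative continuous variables (durations, counts),
which :func:`apply_transforms` maps through ``ln(1+x)`` so that zero-valued
durations remain representable.

Missing data are kept as missing throughout (empty CSV cells, configurable
sentinel strings); downstream Gower weighting handles them — there is no
imputation anywhere in the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "FeatureSchema",
    "FeatureTable",
    "OutcomeTable",
    "SchemaError",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "read_outcome_table",
    "write_outcome_table",
    "apply_transforms",
]

KINDS = ("continuous", "binary", "categorical")

DEFAULT_NA_VALUES = ("", "NA", "NaN", "nan")


class SchemaError(ValueError):
    """Schema file is malformed or does not match the table."""


class ValidationError(ValueError):
    """Table values violate the declared feature kinds."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one feature: its name, kind, transform flag and weight."""

    name: str
    kind: str
    log_transform: bool = False
    weight: float = 1.0
    #: symmetric binary (0-0 agreement counts) is the default; asymmetric
    #: (Jaccard-style, 0-0 pairs ignored) is available per feature.
    asymmetric_binary: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.log_transform and self.kind != "continuous":
            raise SchemaError(
                f"feature {self.name!r}: log_transform requires kind=continuous"
            )
        if self.asymmetric_binary and self.kind != "binary":
            raise SchemaError(
                f"feature {self.name!r}: asymmetric_binary requires kind=binary"
            )
        if not (self.weight >= 0) or not math.isfinite(self.weight):
            raise SchemaError(f"feature {self.name!r}: weight must be finite and >= 0")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` plus the id column name."""

    id_column: str
    features: tuple[FeatureSpec, ...]
    transforms_applied: bool = False

    def __post_init__(self) -> None:
        if len(self.features) == 0:
            raise SchemaError("schema must declare at least one feature")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dupes}")
        if self.id_column in names:
            raise SchemaError("id_column may not also be a feature")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "id_column": self.id_column,
            "transforms_applied": self.transforms_applied,
            "features": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "log_transform": f.log_transform,
                    "weight": f.weight,
                    "asymmetric_binary": f.asymmetric_binary,
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        try:
            feats = tuple(
                FeatureSpec(
                    name=f["name"],
                    kind=f["kind"],
                    log_transform=bool(f.get("log_transform", False)),
                    weight=float(f.get("weight", 1.0)),
                    asymmetric_binary=bool(f.get("asymmetric_binary", False)),
                )
                for f in d["features"]
            )
            return cls(
                id_column=d["id_column"],
                features=feats,
                transforms_applied=bool(d.get("transforms_applied", False)),
            )
        except KeyError as e:  # pragma: no cover - message detail only
            raise SchemaError(f"schema missing required key: {e}") from e

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))


class FeatureTable:
    """Patients x mixed-type features, validated against a :class:`FeatureSchema`.

    Values live in a :class:`pandas.DataFrame` indexed by patient id:
    continuous and binary columns are float (``NaN`` = missing, binary
    restricted to {0, 1}); categorical columns are pandas ``category``
    with levels in discovery order.
    """

    def __init__(self, patient_ids: Sequence, schema: FeatureSchema, values: pd.DataFrame):
        patient_ids = list(patient_ids)
        if len(patient_ids) < 2:
            raise ValidationError("a feature table needs at least 2 patients")
        if len(set(map(str, patient_ids))) != len(patient_ids):
            raise ValidationError("patient ids must be unique")
        if len(values) != len(patient_ids):
            raise ValidationError("row count does not match patient_ids")
        missing_cols = [n for n in schema.names if n not in values.columns]
        if missing_cols:
            raise SchemaError(f"table lacks declared features: {missing_cols}")
        extra = [c for c in values.columns if c not in schema.names]
        if extra:
            raise SchemaError(f"undeclared columns in table: {extra}")

        df = pd.DataFrame(index=pd.Index([str(p) for p in patient_ids], name=schema.id_column))
        for spec in schema.features:
            col = values[spec.name].reset_index(drop=True)
            df[spec.name] = _coerce_column(col, spec).values
        self.patient_ids: list[str] = [str(p) for p in patient_ids]
        self.schema = schema
        self.values = df

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.schema.features)

    def subset(self, feature_names: Iterable[str]) -> "FeatureTable":
        """Restrict to the named features (order follows the schema)."""
        keep = [f for f in self.schema.features if f.name in set(feature_names)]
        schema = FeatureSchema(
            id_column=self.schema.id_column,
            features=tuple(keep),
            transforms_applied=self.schema.transforms_applied,
        )
        return FeatureTable(self.patient_ids, schema, self.values[[f.name for f in keep]])

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureTable({self.n_patients} patients x {self.n_features} features)"


def _coerce_column(col: pd.Series, spec: FeatureSpec) -> pd.Series:
    if spec.kind in ("continuous", "binary"):
        try:
            out = pd.to_numeric(col, errors="raise").astype(float)
        except (ValueError, TypeError) as e:
            raise ValidationError(f"feature {spec.name!r}: non-numeric value ({e})") from e
        if spec.kind == "binary":
            bad = out.dropna()[~out.dropna().isin([0.0, 1.0])]
            if len(bad):
                rows = bad.index.tolist()[:10]
                raise ValidationError(
                    f"binary feature {spec.name!r}: values outside {{0,1}} at rows {rows}"
                )
        else:
            vals = out.dropna()
            if not np.isfinite(vals.to_numpy()).all():
                raise ValidationError(f"continuous feature {spec.name!r}: non-finite values")
        return out
    # categorical: keep labels as strings, levels in discovery order
    as_obj = col.astype(object).where(col.notna(), other=None)
    labels = [str(v) for v in as_obj if v is not None]
    levels = list(dict.fromkeys(labels))
    out = pd.Series(
        pd.Categorical([str(v) if v is not None else None for v in as_obj], categories=levels)
    )
    return out


@dataclass(frozen=True)
class OutcomeTable:
    """Per-patient mortality (binary) and discharge disposition (categorical)."""

    patient_ids: tuple[str, ...]
    mortality: np.ndarray
    disposition: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.mortality, dtype=float)
        if len(self.patient_ids) != len(m) or len(self.patient_ids) != len(self.disposition):
            raise ValidationError("outcome components misaligned")
        if not np.isin(m, [0.0, 1.0]).all():
            raise ValidationError("mortality must be binary 0/1")
        object.__setattr__(self, "mortality", m.astype(int))

    def check_alignment(self, table: FeatureTable) -> None:
        if list(self.patient_ids) != list(table.patient_ids):
            raise ValidationError("outcome patient_ids do not match the feature table")


# ---------------------------------------------------------------------------
# I/O


def read_feature_table(
    table_path: str | Path,
    schema_path: str | Path,
    na_values: Sequence[str] = DEFAULT_NA_VALUES,
) -> FeatureTable:
    """Read a cohort CSV plus its JSON schema into a validated FeatureTable.

    Every non-id CSV column must be declared in the schema; empty cells (and
    the configured sentinel strings) become missing values.
    """
    schema = FeatureSchema.load(schema_path)
    df = pd.read_csv(
        table_path, dtype=str, keep_default_na=False, na_values=list(na_values)
    )
    if schema.id_column not in df.columns:
        raise SchemaError(f"id column {schema.id_column!r} not found in {table_path}")
    undeclared = [c for c in df.columns if c != schema.id_column and c not in schema.names]
    if undeclared:
        raise SchemaError(f"columns not declared in schema: {undeclared}")
    absent = [n for n in schema.names if n not in df.columns]
    if absent:
        raise SchemaError(f"schema features absent from table: {absent}")
    return FeatureTable(df[schema.id_column].tolist(), schema, df[schema.names])


def write_feature_table(table: FeatureTable, table_path: str | Path, schema_path: str | Path | None = None) -> None:
    out = table.values.copy()
    out.insert(0, table.schema.id_column, table.patient_ids)
    out.to_csv(table_path, index=False)
    if schema_path is not None:
        table.schema.save(schema_path)


def read_outcome_table(path: str | Path, na_values: Sequence[str] = DEFAULT_NA_VALUES) -> OutcomeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=list(na_values))
    for col in ("id", "mortality", "disposition"):
        if col not in df.columns:
            raise SchemaError(f"outcome table lacks column {col!r}")
    return OutcomeTable(
        patient_ids=tuple(df["id"].astype(str)),
        mortality=pd.to_numeric(df["mortality"]).to_numpy(),
        disposition=tuple(df["disposition"].astype(str)),
    )


def write_outcome_table(outcomes: OutcomeTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": outcomes.patient_ids,
            "mortality": outcomes.mortality,
            "disposition": outcomes.disposition,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transforms


def apply_transforms(table: FeatureTable, *, allow_applied: bool = False) -> FeatureTable:
    """Apply ``x -> ln(1+x)`` to every continuous feature flagged ``log_transform``.

    ``ln(1+x)`` rather than ``ln(x)`` because durations are legitimately 0.
    Missingness and all other entries are unchanged. The returned table's
    schema is marked ``transforms_applied``; re-applying raises unless
    ``allow_applied`` (then it is a no-op).
    """
    if table.schema.transforms_applied:
        if allow_applied:
            return table
        raise ValidationError("transforms already applied to this table")
    values = table.values.copy()
    for spec in table.schema.features:
        if spec.kind == "continuous" and spec.log_transform:
            x = values[spec.name].to_numpy(dtype=float)
            if np.nanmin(x, initial=np.inf) < 0:
                raise ValidationError(
                    f"feature {spec.name!r}: negative value under log_transform"
                )
            values[spec.name] = np.log1p(x)
    schema = replace(table.schema, transforms_applied=True)
    return FeatureTable(table.patient_ids, schema, values)
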