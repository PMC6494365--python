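"""Gower dissimilarity for mixed-type feature tables.

For a pair of patients (a, b) the dissimilarity is

    d(a, b) = sum_f w_f * delta_f * s_f  /  sum_f w_f * delta_f

where ``delta_f`` is 1 iff feature f is observed in both patients, ``w_f``
the schema weight, and the per-feature score ``s_f`` is

* continuous:  |x_a - x_b| / R_f  with R_f the observed range (0 if R_f = 0,
  so constant features contribute similarity rather than 0/0);
* binary (symmetric, the default): 0 on agreement — including 0-0 — else 1;
* binary (asymmetric option): as symmetric, but 0-0 pairs set delta_f = 0;
* categorical: 0 if equal else 1.

Ranges are computed once on the full cohort (after any transforms) and are
reused when consensus subsampling slices the matrix, so pairwise values are
subsample-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema_io import FeatureSchema, FeatureTable

__all__ = [
    "DissimilarityMatrix",
    "UndefinedPairError",
    "feature_ranges",
    "gower_pair",
    "gower_matrix",
]


class UndefinedPairError(ValueError):
    """Some patient pair shares no jointly observed feature."""


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric patient x patient dissimilarities in [0, 1]."""

    patient_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.patient_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match patient_ids")
        # full checks are O(n^2); above ~2000 patients validate on a
        # deterministic row stripe to keep construction cheap
        sel = v if n <= 2000 else v[:: max(n // 512, 1)]
        if not np.allclose(sel, v.T[:: max(n // 512, 1)] if n > 2000 else v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValueError("diagonal not zero")
        if sel.min() < -1e-12 or sel.max() > 1 + 1e-12:
            raise ValueError("entries outside [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def slice(self, indices: np.ndarray) -> np.ndarray:
        """Submatrix for the given patient indices (consensus subsampling)."""
        idx = np.asarray(indices)
        return self.values[np.ix_(idx, idx)]

    def save_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.patient_ids, columns=self.patient_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def load_tsv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def feature_ranges(table: FeatureTable) -> dict[str, float]:
    """Observed range (max - min) per continuous feature, ignoring missing."""
    ranges: dict[str, float] = {}
    for spec in table.schema.features:
        if spec.kind != "continuous":
            continue
        x = table.values[spec.name].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        ranges[spec.name] = float(obs.max() - obs.min()) if obs.size else 0.0
    return ranges


def _feature_arrays(table: FeatureTable):
    """Per feature: (spec, numeric codes array, observed mask)."""
    out = []
    for spec in table.schema.features:
        col = table.values[spec.name]
        if spec.kind == "categorical":
            codes = col.cat.codes.to_numpy(dtype=float)
            mask = codes >= 0
            x = codes
        else:
            x = col.to_numpy(dtype=float)
            mask = ~np.isnan(x)
        out.append((spec, x, mask))
    return out


def gower_pair(
    a: dict,
    b: dict,
    schema: FeatureSchema,
    ranges: dict[str, float],
) -> float:
    """Dissimilarity between two patient records given precomputed ranges.

    Records are feature-name -> value mappings; ``None``/NaN marks missing.
    Raises :class:`UndefinedPairError` when no feature is jointly observed
    (for asymmetric binaries a 0-0 pair does not count as observed).
    """

    def _missing(v) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v))

    num = 0.0
    den = 0.0
    for spec in schema.features:
        va, vb = a.get(spec.name), b.get(spec.name)
        if _missing(va) or _missing(vb):
            continue
        if spec.kind == "continuous":
            r = ranges.get(spec.name, 0.0)
            s = abs(float(va) - float(vb)) / r if r > 0 else 0.0
        elif spec.kind == "binary":
            if spec.asymmetric_binary and float(va) == 0.0 and float(vb) == 0.0:
                continue
            s = 0.0 if float(va) == float(vb) else 1.0
        else:
            s = 0.0 if str(va) == str(vb) else 1.0
        num += spec.weight * s
        den += spec.weight
    if den == 0.0:
        raise UndefinedPairError("no jointly observed feature for this pair")
    return num / den


def gower_matrix(
    table: FeatureTable,
    ranges: dict[str, float] | None = None,
) -> DissimilarityMatrix:
    """Full pairwise Gower matrix, vectorised one feature at a time.

    ``ranges`` defaults to :func:`feature_ranges` of the table itself; pass
    precomputed cohort ranges when scoring a subset of patients.
    """
    if table.n_patients < 2:
        raise ValueError("need at least 2 patients")
    if ranges is None:
        ranges = feature_ranges(table)
    n = table.n_patients
    num = np.zeros((n, n))
    den = np.zeros((n, n))

    # symmetric binaries in one missing-aware block: with X the 0/1 matrix
    # (missing -> 0) and m the observed mask, pairwise weighted mismatch
    # counts are A + A.T with A = (X w) (m - X)^T, and the weighted joint
    # observation count is (m w) m^T. Three GEMMs instead of a dense outer
    # product per feature — the cohort-scale hot path.
    sym_bin = [
        (spec, x, mask)
        for spec, x, mask in _feature_arrays(table)
        if spec.kind == "binary" and not spec.asymmetric_binary and spec.weight > 0
    ]
    if sym_bin:
        w = np.array([spec.weight for spec, _, _ in sym_bin])
        m = np.column_stack([mask for _, _, mask in sym_bin]).astype(float)
        X = np.column_stack([np.where(mask, x, 0.0) for _, x, mask in sym_bin])
        A = (X * w) @ (m - X).T
        num += A + A.T
        den += (m * w) @ m.T

    for spec, x, mask in _feature_arrays(table):
        if spec.weight == 0 or (spec.kind == "binary" and not spec.asymmetric_binary):
            continue
        joint = np.logical_and.outer(mask, mask)
        sw = spec.weight
        if spec.kind == "continuous":
            r = ranges.get(spec.name, 0.0)
            if r > 0:
                xs = np.where(mask, x, 0.0)
                s = np.subtract.outer(xs, xs)
                np.abs(s, out=s)
                s *= sw / r
                s *= joint
            else:
                s = np.zeros((n, n))
        else:
            if spec.kind == "binary" and spec.asymmetric_binary:
                zero = (x == 0.0) & mask
                joint &= ~np.logical_and.outer(zero, zero)
            s = (np.not_equal.outer(x, x) & joint).astype(float)
            s *= sw
        num += s
        den += joint * sw
    undefined = den == 0.0
    np.fill_diagonal(undefined, False)
    if undefined.any():
        i, j = np.argwhere(undefined)[0]
        raise UndefinedPairError(
            f"patients {table.patient_ids[i]!r} and {table.patient_ids[j]!r} "
            "share no jointly observed feature"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against fp noise
    return DissimilarityMatrix(tuple(table.patient_ids), d)
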