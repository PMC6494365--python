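import numpy as np
import pandas as pd
import pytest

from phenoclust.schema_io import FeatureSchema, FeatureSpec, FeatureTable


def make_table(columns: dict, kinds: dict, ids=None, **schema_kw) -> FeatureTable:
    """Small mixed-type FeatureTable from plain dicts (None = missing)."""
    df = pd.DataFrame({k: pd.Series(v, dtype=object) for k, v in columns.items()})
    specs = tuple(
        FeatureSpec(
            name,
            kinds[name] if isinstance(kinds[name], str) else kinds[name][0],
            **(kinds[name][1] if not isinstance(kinds[name], str) else {}),
        )
        for name in columns
    )
    n = len(df)
    ids = ids or [f"p{i}" for i in range(n)]
    return FeatureTable(ids, FeatureSchema("id", specs, **schema_kw), df)


def random_mixed_table(rng: np.random.Generator, n: int, n_bin: int, n_cont: int,
                       n_cat: int = 0, missing: float = 0.0) -> FeatureTable:
    """Random mixed table for oracle comparisons; every patient keeps at
    least one observed feature."""
    cols: dict = {}
    kinds: dict = {}
    for i in range(n_bin):
        cols[f"b{i}"] = rng.integers(0, 2, n).astype(float)
        kinds[f"b{i}"] = "binary"
    for i in range(n_cont):
        cols[f"c{i}"] = np.round(rng.normal(0, 1, n), 6)
        kinds[f"c{i}"] = "continuous"
    for i in range(n_cat):
        cols[f"g{i}"] = rng.choice(list("uvw"), n)
        kinds[f"g{i}"] = "categorical"
    df = pd.DataFrame(cols)
    if missing > 0:
        mask = rng.random(df.shape) < missing
        mask[mask.all(axis=1), 0] = False
        df = df.mask(mask)
    specs = tuple(FeatureSpec(name, kinds[name]) for name in cols)
    return FeatureTable([f"p{i}" for i in range(n)],
                        FeatureSchema("id", specs), df)


def random_dissimilarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix with zero diagonal, entries in [0, 1]."""
    a = rng.random((n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
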