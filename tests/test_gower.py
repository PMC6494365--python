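"""Gower dissimilarity against hand values and a scalar double-loop oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenoclust.gower import (
    UndefinedPairError,
    feature_ranges,
    gower_matrix,
    gower_pair,
)
from phenoclust.schema_io import FeatureSchema, FeatureSpec

from conftest import make_table, random_mixed_table


def records_of(table):
    """Plain dict records for the scalar oracle path."""
    out = []
    for i in range(table.n_patients):
        rec = {}
        for spec in table.schema.features:
            v = table.values[spec.name].iloc[i]
            rec[spec.name] = None if pd.isna(v) else v
        out.append(rec)
    return out


def oracle_matrix(table):
    """Independent double loop over gower_pair (itself hand-checkable)."""
    ranges = feature_ranges(table)
    recs = records_of(table)
    n = len(recs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = gower_pair(recs[i], recs[j], table.schema, ranges)
    return D


class TestFeatureRanges:
    def test_max_minus_min(self):
        t = make_table({"age": [40.0, 60.0, 90.0]}, {"age": "continuous"})
        assert feature_ranges(t) == {"age": 50.0}

    def test_constant_feature_zero_range(self):
        t = make_table({"age": [5.0, 5.0, 5.0]}, {"age": "continuous"})
        assert feature_ranges(t) == {"age": 0.0}

    def test_missing_excluded(self):
        t = make_table({"age": [40.0, None, 90.0]}, {"age": "continuous"})
        assert feature_ranges(t) == {"age": 50.0}


class TestGowerPair:
    SCHEMA = FeatureSchema("id", (FeatureSpec("age", "continuous"),
                                  FeatureSpec("shock", "binary")))

    def test_hand_value(self):
        # (|40-60|/50 + 1)/2 = 0.7
        d = gower_pair({"age": 40.0, "shock": 1.0}, {"age": 60.0, "shock": 0.0},
                       self.SCHEMA, {"age": 50.0})
        assert d == pytest.approx(0.7, abs=1e-15)

    def test_identical_records_zero(self):
        d = gower_pair({"age": 40.0, "shock": 1.0}, {"age": 40.0, "shock": 1.0},
                       self.SCHEMA, {"age": 50.0})
        assert d == 0.0

    def test_all_binary_total_disagreement_is_one(self):
        schema = FeatureSchema("id", tuple(FeatureSpec(f"b{i}", "binary")
                                           for i in range(3)))
        a = {f"b{i}": 1.0 for i in range(3)}
        b = {f"b{i}": 0.0 for i in range(3)}
        assert gower_pair(a, b, schema, {}) == 1.0

    def test_symmetric_binary_00_counts_as_agreement(self):
        schema = FeatureSchema("id", (FeatureSpec("b", "binary"),
                                      FeatureSpec("c", "binary")))
        assert gower_pair({"b": 0.0, "c": 1.0}, {"b": 0.0, "c": 0.0},
                          schema, {}) == 0.5

    def test_asymmetric_binary_00_excluded(self):
        schema = FeatureSchema(
            "id", (FeatureSpec("b", "binary", asymmetric_binary=True),
                   FeatureSpec("c", "binary")))
        # the 0-0 feature drops out of the denominator entirely
        assert gower_pair({"b": 0.0, "c": 1.0}, {"b": 0.0, "c": 0.0},
                          schema, {}) == 1.0

    def test_no_jointly_observed_feature(self):
        schema = FeatureSchema("id", (FeatureSpec("a", "continuous"),
                                      FeatureSpec("b", "continuous")))
        with pytest.raises(UndefinedPairError):
            gower_pair({"a": 1.0, "b": None}, {"a": None, "b": 2.0},
                       schema, {"a": 1.0, "b": 1.0})


class TestGowerMatrix:
    def test_identical_patients(self):
        t = make_table({"b": [1.0, 1.0]}, {"b": "binary"})
        np.testing.assert_array_equal(gower_matrix(t).values, np.zeros((2, 2)))

    def test_matches_scalar_oracle_mixed(self, rng):
        t = random_mixed_table(rng, 50, 4, 4, n_cat=2, missing=0.05)
        got = gower_matrix(t).values
        assert np.abs(got - oracle_matrix(t)).max() < 1e-12

    def test_permutation_equivariance(self, rng):
        t = random_mixed_table(rng, 12, 3, 3)
        perm = rng.permutation(12)
        t2 = make_table(
            {s.name: t.values[s.name].to_numpy()[perm] for s in t.schema.features},
            {s.name: s.kind for s in t.schema.features},
            ids=[t.patient_ids[i] for i in perm],
        )
        D1 = gower_matrix(t).values
        D2 = gower_matrix(t2).values
        np.testing.assert_allclose(D2, D1[np.ix_(perm, perm)], atol=1e-15)

    def test_undefined_pair_reports_patients(self):
        t = make_table({"a": [1.0, None, 2.0], "b": [None, 1.0, 2.0]},
                       {"a": "continuous", "b": "continuous"})
        with pytest.raises(UndefinedPairError, match="p0.*p1|p1.*p0"):
            gower_matrix(t)

    def test_agreeing_feature_never_increases_dissimilarity(self, rng):
        t = random_mixed_table(rng, 10, 3, 2)
        base = gower_matrix(t).values
        cols = {s.name: t.values[s.name].to_numpy() for s in t.schema.features}
        kinds = {s.name: s.kind for s in t.schema.features}
        cols["agree"] = np.ones(10)
        kinds["agree"] = "binary"
        grown = gower_matrix(make_table(cols, kinds)).values
        assert (grown <= base + 1e-12).all()

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_oracle_property_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        t = random_mixed_table(rng, n, int(rng.integers(1, 5)),
                               int(rng.integers(1, 5)),
                               n_cat=int(rng.integers(0, 3)),
                               missing=float(rng.choice([0.0, 0.05, 0.1])))
        D = gower_matrix(t)
        assert np.abs(D.values - oracle_matrix(t)).max() < 1e-12
        assert (D.values >= 0).all() and (D.values <= 1).all()
        np.testing.assert_array_equal(np.diag(D.values), 0)


def test_tsv_round_trip(tmp_path, rng):
    t = random_mixed_table(rng, 8, 2, 2)
    D = gower_matrix(t)
    D.save_tsv(tmp_path / "d.tsv")
    back = type(D).load_tsv(tmp_path / "d.tsv")
    assert back.patient_ids == D.patient_ids
    np.testing.assert_allclose(back.values, D.values, atol=1e-12)
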