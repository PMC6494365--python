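"""Feature-table I/O, schema validation and the ln(1+x) transform."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenoclust.schema_io import (
    FeatureSchema,
    FeatureSpec,
    SchemaError,
    ValidationError,
    apply_transforms,
    read_feature_table,
    read_outcome_table,
    write_feature_table,
    write_outcome_table,
)

from conftest import make_table


def _write_inputs(tmp_path, csv_text, schema_dict):
    table = tmp_path / "t.csv"
    schema = tmp_path / "s.json"
    table.write_text(csv_text)
    schema.write_text(json.dumps(schema_dict))
    return table, schema


BASIC_SCHEMA = {
    "id_column": "id",
    "features": [
        {"name": "age", "kind": "continuous"},
        {"name": "shock", "kind": "binary"},
    ],
}


class TestReadFeatureTable:
    def test_basic_parse(self, tmp_path):
        t, s = _write_inputs(tmp_path, "id,age,shock\na,50,1\nb,60,0\nc,70,1\n",
                             BASIC_SCHEMA)
        ft = read_feature_table(t, s)
        assert ft.n_patients == 3 and ft.n_features == 2
        assert ft.values["age"].tolist() == [50.0, 60.0, 70.0]

    def test_binary_out_of_range_names_offender(self, tmp_path):
        t, s = _write_inputs(tmp_path, "id,age,shock\na,50,1\nb,60,2\nc,70,1\n",
                             BASIC_SCHEMA)
        with pytest.raises(ValidationError, match="shock"):
            read_feature_table(t, s)

    def test_empty_cell_becomes_missing(self, tmp_path):
        t, s = _write_inputs(tmp_path, "id,age,shock\na,,1\nb,60,0\nc,70,1\n",
                             BASIC_SCHEMA)
        ft = read_feature_table(t, s)
        assert np.isnan(ft.values["age"].iloc[0])
        assert ft.values["age"].iloc[1:].tolist() == [60.0, 70.0]

    def test_undeclared_column_rejected(self, tmp_path):
        t, s = _write_inputs(tmp_path, "id,age,shock,extra\na,50,1,9\nb,60,0,9\n",
                             BASIC_SCHEMA)
        with pytest.raises(SchemaError, match="extra"):
            read_feature_table(t, s)

    def test_categorical_levels_in_discovery_order(self, tmp_path):
        schema = {"id_column": "id",
                  "features": [{"name": "src", "kind": "categorical"}]}
        t, s = _write_inputs(tmp_path, "id,src\na,home\nb,transfer\nc,home\n", schema)
        ft = read_feature_table(t, s)
        assert list(ft.values["src"].cat.categories) == ["home", "transfer"]

    def test_round_trip_identity(self, tmp_path, rng):
        from conftest import random_mixed_table

        ft = random_mixed_table(rng, 20, 3, 3, n_cat=1, missing=0.1)
        write_feature_table(ft, tmp_path / "o.csv", tmp_path / "o.json")
        back = read_feature_table(tmp_path / "o.csv", tmp_path / "o.json")
        assert back.patient_ids == ft.patient_ids
        assert back.schema == ft.schema
        for name in ft.schema.names:
            a, b = ft.values[name], back.values[name]
            assert a.isna().equals(b.isna())
            if ft.schema[name].kind == "categorical":
                assert a.dropna().tolist() == b.dropna().tolist()
            else:
                np.testing.assert_allclose(a.dropna(), b.dropna(), rtol=0, atol=1e-12)


class TestSchemaValidation:
    def test_duplicate_feature_names(self):
        with pytest.raises(SchemaError, match="duplicate"):
            FeatureSchema("id", (FeatureSpec("x", "binary"), FeatureSpec("x", "binary")))

    def test_log_transform_requires_continuous(self):
        with pytest.raises(SchemaError):
            FeatureSpec("x", "binary", log_transform=True)

    def test_at_least_one_feature(self):
        with pytest.raises(SchemaError):
            FeatureSchema("id", ())


class TestApplyTransforms:
    def _table(self, values):
        return make_table(
            {"days": values, "age": [40.0] * len(values)},
            {"days": ("continuous", {"log_transform": True}), "age": "continuous"},
        )

    def test_log1p_values(self):
        # ln(1+0)=0 and ln(1+(e-1))=1, plus a scalar-loop oracle on skewed values
        vals = [0.0, math.e - 1, 3.5, 10.0, None]
        out = apply_transforms(self._table(vals))
        got = out.values["days"]
        assert got.iloc[0] == 0.0
        assert got.iloc[1] == pytest.approx(1.0, abs=1e-12)
        for i, v in enumerate(vals[:4]):
            assert got.iloc[i] == pytest.approx(math.log(1.0 + v), abs=1e-12)
        assert np.isnan(got.iloc[4])
        # untouched feature and missingness preserved
        assert out.values["age"].tolist() == [40.0] * 5
        assert out.schema.transforms_applied

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            apply_transforms(self._table([1.0, -0.5, 2.0]))

    def test_reapply_rejected_or_noop(self):
        out = apply_transforms(self._table([1.0, 2.0]))
        with pytest.raises(ValidationError):
            apply_transforms(out)
        again = apply_transforms(out, allow_applied=True)
        assert again.values["days"].tolist() == out.values["days"].tolist()

    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=20,
                    unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_transform_preserves_order(self, xs):
        out = apply_transforms(self._table(xs)).values["days"].to_numpy()
        assert (np.argsort(out, kind="stable") == np.argsort(np.asarray(xs),
                                                             kind="stable")).all()


def test_outcome_round_trip(tmp_path):
    p = tmp_path / "out.csv"
    p.write_text("id,mortality,disposition\na,1,home\nb,0,other\n")
    ot = read_outcome_table(p)
    assert ot.mortality.tolist() == [1, 0]
    write_outcome_table(ot, tmp_path / "o2.csv")
    back = read_outcome_table(tmp_path / "o2.csv")
    assert back.patient_ids == ot.patient_ids
    assert back.mortality.tolist() == ot.mortality.tolist()
    assert back.disposition == ot.disposition
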