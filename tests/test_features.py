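import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonecast as cc
from clonecast.errors import MissingValueError, NotFittedError, SchemaError
from clonecast.features import encode_features, fit_preprocessor
from clonecast.schema import Attribute, BINARY, CATEGORIES, default_schema


class TestEncoding:
    def test_default_schema_yields_36_columns(self, sim_cohort):
        cohort, _ = sim_cohort
        fm = encode_features(cohort)
        assert fm.n_columns == 36
        kinds = [c.transform for c in fm.columns]
        assert kinds.count("log1p") == 17
        assert kinds.count("identity") == 19  # 2 binary + 17 raw

    def test_continuous_attribute_gives_raw_and_log1p_pair(self, tiny_cohort):
        fm = encode_features(tiny_cohort)
        frame = fm.to_frame()
        np.testing.assert_allclose(frame["dose"], [1, 2, 3, 4, 5])
        np.testing.assert_allclose(frame["log1p_dose"], np.log1p([1, 2, 3, 4, 5]))
        assert list(frame["flag"]) == [0, 1, 0, 1, 1]

    def test_category_restriction_matches_column_subset(self, sim_cohort):
        cohort, _ = sim_cohort
        full = encode_features(cohort)
        for cat in CATEGORIES:
            only = encode_features(cohort, (cat,))
            sub = full.restrict_categories((cat,))
            assert only.column_names == sub.column_names
            np.testing.assert_array_equal(
                np.nan_to_num(only.values), np.nan_to_num(sub.values)
            )

    def test_missing_value_propagates_to_both_derived_columns(self, tiny_cohort):
        tiny_cohort.data.loc["P2", "dose"] = np.nan
        fm = encode_features(tiny_cohort)
        frame = fm.to_frame()
        assert math.isnan(frame.loc["P2", "dose"])
        assert math.isnan(frame.loc["P2", "log1p_dose"])

    def test_empty_category_set_rejected(self, tiny_cohort):
        with pytest.raises(SchemaError):
            encode_features(tiny_cohort, ())

    @given(
        n_bin=st.integers(0, 5),
        n_cont=st.integers(1, 8),
        data=st.data(),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_column_count_formula_for_arbitrary_schemas(self, n_bin, n_cont, data):
        import pandas as pd

        cats = data.draw(st.lists(st.sampled_from(CATEGORIES),
                                  min_size=n_bin + n_cont,
                                  max_size=n_bin + n_cont))
        schema = tuple(
            Attribute(f"b{i}", cats[i], BINARY, allow_missing=False)
            for i in range(n_bin)
        ) + tuple(
            Attribute(f"c{i}", cats[n_bin + i]) for i in range(n_cont)
        )
        df = pd.DataFrame(
            {a.name: [0.0, 1.0, 0.0] for a in schema},
            index=pd.Index(["A", "B", "C"], name="patient_id"),
        )
        cohort = cc.CohortTable(schema, df)
        fm = encode_features(cohort)
        assert fm.n_columns == n_bin + 2 * n_cont


class TestPreprocessor:
    def _fm(self, values, names=None):
        import pandas as pd

        names = names or [f"c{i}" for i in range(values.shape[1])]
        schema = tuple(Attribute(n, "tumor") for n in names)
        df = pd.DataFrame(values, columns=names,
                          index=pd.Index([f"P{i}" for i in range(len(values))],
                                         name="patient_id"))
        return encode_features(cc.CohortTable(schema, df))

    def test_median_conventions(self):
        fm = self._fm(np.array([[1.0], [2.0], [9.0]]))
        assert fit_preprocessor(fm).medians[0] == 2.0
        fm = self._fm(np.array([[1.0], [3.0]]))
        assert fit_preprocessor(fm).medians[0] == 2.0

    def test_all_missing_column_raises(self):
        fm = self._fm(np.array([[1.0], [2.0]]))
        fm.values[:, 0] = np.nan
        with pytest.raises(MissingValueError, match="c0"):
            fit_preprocessor(fm)

    def test_training_matrix_centered_after_transform(self, sim_cohort):
        cohort, _ = sim_cohort
        fm = encode_features(cohort)
        pp = fit_preprocessor(fm)
        out = pp.transform(fm)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        sd = out.values.std(axis=0)
        np.testing.assert_allclose(sd[sd > 0], 1.0, atol=1e-12)

    def test_held_out_missing_cell_gets_training_median(self):
        fm = self._fm(np.array([[1.0], [2.0], [9.0]]))
        pp = fit_preprocessor(fm)
        held = self._fm(np.array([[np.nan]]))
        out = pp.transform(held)
        expected = (2.0 - pp.means[0]) / pp.scales[0]
        np.testing.assert_allclose(out.values[0, 0], expected)

    def test_constant_column_scale_guard(self):
        fm = self._fm(np.array([[3.0], [3.0], [3.0]]))
        pp = fit_preprocessor(fm)
        assert pp.scales[0] == 1.0
        np.testing.assert_array_equal(pp.transform(fm).values[:, 0], 0.0)

    def test_unfitted_preprocessor_raises(self, tiny_cohort):
        from clonecast.features import Preprocessor

        with pytest.raises(NotFittedError):
            Preprocessor().transform(encode_features(tiny_cohort))

    def test_leakage_preprocessor_invariant_to_held_out_row(self, sim_cohort):
        cohort, _ = sim_cohort
        fm = encode_features(cohort)
        train = fm.rows(np.arange(1, fm.values.shape[0]))
        pp = fit_preprocessor(train)
        tampered = encode_features(cohort)
        tampered.values[0] = 1e6
        pp2 = fit_preprocessor(tampered.rows(np.arange(1, fm.values.shape[0])))
        np.testing.assert_array_equal(pp.medians, pp2.medians)
        np.testing.assert_array_equal(pp.means, pp2.means)
        np.testing.assert_array_equal(pp.scales, pp2.scales)
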