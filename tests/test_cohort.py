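import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonecast as cc
from clonecast.cohort import (
    apply_score_fallback,
    derive_response,
    load_cohort,
    write_cohort,
)
from clonecast.errors import CohortParseError, MissingValueError, SchemaError


class TestLoadWrite:
    def test_simulated_cohort_round_trips(self, tmp_path):
        cohort, _ = cc.simulate_cohort(cc.SimulationConfig(seed=3))
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        loaded = load_cohort(path)
        assert loaded.n_patients == 21
        pd.testing.assert_frame_equal(cohort.data, loaded.data, check_dtype=False)
        # a second write/load cycle is bit-stable
        path2 = tmp_path / "cohort2.csv"
        write_cohort(loaded, path2)
        assert path.read_text() == path2.read_text()

    def test_tsv_dialect(self, tmp_path):
        cohort, _ = cc.simulate_cohort(cc.SimulationConfig(seed=4))
        path = tmp_path / "cohort.tsv"
        write_cohort(cohort, path)
        assert "\t" in path.read_text().splitlines()[0]
        loaded = load_cohort(path)
        pd.testing.assert_frame_equal(cohort.data, loaded.data, check_dtype=False)

    def test_header_only_file_gives_empty_cohort(self, tmp_path):
        cohort, _ = cc.simulate_cohort(cc.SimulationConfig(seed=3))
        path = tmp_path / "empty.csv"
        write_cohort(cohort.with_data(cohort.data.iloc[:0]), path)
        assert load_cohort(path).n_patients == 0

    def test_negative_continuous_value_is_parse_error(self, tmp_path):
        cohort, _ = cc.simulate_cohort(cc.SimulationConfig(seed=3))
        bad = cohort.copy()
        bad.data.loc[bad.patient_ids[2], "age"] = -1.0
        path = tmp_path / "bad.csv"
        write_cohort(bad, path)
        with pytest.raises(CohortParseError, match="age"):
            load_cohort(path)

    def test_unknown_column_is_schema_error(self, tmp_path):
        cohort, _ = cc.simulate_cohort(cc.SimulationConfig(seed=3))
        bad = cohort.copy()
        bad.data["mystery"] = 1.0
        path = tmp_path / "bad.csv"
        bad.data.to_csv(path, index_label="patient_id")
        with pytest.raises(SchemaError, match="mystery"):
            load_cohort(path)

    def test_non_numeric_cell_is_parse_error(self, tmp_path):
        cohort, _ = cc.simulate_cohort(cc.SimulationConfig(seed=3))
        path = tmp_path / "bad.csv"
        write_cohort(cohort, path)
        text = path.read_text().replace("\n", "\n", 1)
        lines = text.splitlines()
        cells = lines[1].split(",")
        cells[2] = "not-a-number"
        lines[1] = ",".join(cells)
        path.write_text("\n".join(lines))
        with pytest.raises(CohortParseError):
            load_cohort(path)


class TestScoreFallback:
    def _with_missing_score(self, cohort):
        out = cohort.copy()
        out.data.loc[out.patient_ids[0], "five_factor_score"] = np.nan
        out.data["bajorin_score"] = 2.0
        return out

    def test_missing_primary_gets_fallback(self):
        cohort, _ = cc.simulate_cohort(cc.SimulationConfig(seed=5))
        fixed = apply_score_fallback(self._with_missing_score(cohort))
        assert fixed.data.iloc[0]["five_factor_score"] == 2.0

    def test_idempotent_and_noop_when_complete(self):
        cohort, _ = cc.simulate_cohort(
            cc.SimulationConfig(seed=5, missing_rate=0.0))
        cohort.data["bajorin_score"] = 1.0
        once = apply_score_fallback(cohort)
        twice = apply_score_fallback(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        pd.testing.assert_frame_equal(cohort.data, once.data)

    def test_both_missing_strict_raises(self):
        cohort, _ = cc.simulate_cohort(cc.SimulationConfig(seed=5))
        bad = self._with_missing_score(cohort)
        bad.data.loc[bad.patient_ids[0], "bajorin_score"] = np.nan
        with pytest.raises(MissingValueError):
            apply_score_fallback(bad)
        permissive = apply_score_fallback(bad, strict=False)
        assert np.isnan(permissive.data.iloc[0]["five_factor_score"])


class TestDeriveResponse:
    @pytest.mark.parametrize(
        "counts,pseudo,base,expected",
        [
            ([0], 1.0, "e", [0.0]),
            ([math.e - 1], 1.0, "e", [1.0]),
            ([0, 3, 9], 1.0, "e", [0.0, math.log(4), math.log(10)]),
            ([9, 99], 1.0, 10, [1.0, 2.0]),
        ],
    )
    def test_values(self, tiny_cohort, counts, pseudo, base, expected):
        sub = tiny_cohort.with_data(tiny_cohort.data.iloc[: len(counts)].copy())
        sub.data["expanded_clone_count"] = counts
        np.testing.assert_allclose(
            derive_response(sub, pseudocount=pseudo, log_base=base), expected
        )

    def test_missing_count_raises_with_patient_ids(self, tiny_cohort):
        tiny_cohort.data.loc["P1", "expanded_clone_count"] = np.nan
        with pytest.raises(MissingValueError, match="P1"):
            derive_response(tiny_cohort)

    @given(counts=st.lists(st.integers(0, 10**6), min_size=2, max_size=20,
                           unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_monotone_in_count(self, tiny_schema, counts):
        df = pd.DataFrame(
            {a.name: 1.0 for a in tiny_schema},
            index=pd.Index([f"P{i}" for i in range(len(counts))],
                           name="patient_id"),
        )
        df["flag"] = 0.0
        df["expanded_clone_count"] = [float(c) for c in counts]
        cohort = cc.CohortTable(tiny_schema, df)
        y = derive_response(cohort)
        order = np.argsort(counts)
        assert np.all(np.diff(y[order]) > 0)
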