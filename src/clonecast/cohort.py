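"""Cohort data model and file I/O.

A cohort is a pandas DataFrame indexed by patient id, carrying the schema'd
attribute columns plus the post-treatment response (``expanded_clone_count``,
the number of tumor-infiltrating-lymphocyte clones detected as expanded in
peripheral blood after therapy), an optional durable-clinical-benefit label
(``dcb``, 1 = progression-free survival for at least six months), and optional
comparator-biomarker columns that are never model inputs (e.g. PD-L1 staining
percentage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CohortParseError, MissingValueError, SchemaError
from .schema import BINARY, Schema, default_schema, validate_schema

RESPONSE_COLUMN = "expanded_clone_count"
DCB_COLUMN = "dcb"
#: Columns accepted beyond the schema; carried through untouched.
DEFAULT_EXTRA_COLUMNS = ("pd_l1_staining_pct", "bajorin_score")
MISSING_TOKEN = "NA"


@dataclass
class CohortTable:
    """Validated patient cohort.

    ``data`` is indexed by unique patient id; every attribute column named in
    ``schema`` is present, as are the response and DCB columns (possibly all
    missing). Extra columns (comparator biomarkers, fallback scores) are kept
    but never used as model inputs.
    """

    schema: Schema
    data: pd.DataFrame
    extra_columns: tuple[str, ...] = field(default=DEFAULT_EXTRA_COLUMNS)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def attribute_frame(self) -> pd.DataFrame:
        """The n x 19 frame of schema'd attribute values only."""
        return self.data[[a.name for a in self.schema]]

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return replace(self, data=data)

    def copy(self) -> "CohortTable":
        return self.with_data(self.data.copy())


def _check_cell(attr, pid, value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if not attr.allow_missing:
            raise MissingValueError(
                f"attribute {attr.name!r} may not be missing (patient {pid!r})"
            )
        return
    if attr.kind == BINARY:
        if value not in (0, 1):
            raise CohortParseError(
                f"binary attribute {attr.name!r} has value {value!r} "
                f"for patient {pid!r}; expected 0 or 1"
            )
    else:
        if not math.isfinite(value) or value < 0:
            raise CohortParseError(
                f"continuous attribute {attr.name!r} has value {value!r} "
                f"for patient {pid!r}; expected finite and >= 0"
            )


def validate_cohort(cohort: CohortTable) -> CohortTable:
    """Type- and range-check every cell; raise on the first violation."""
    validate_schema(cohort.schema)
    df = cohort.data
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise SchemaError(f"duplicate patient ids: {dupes}")
    known = (
        {a.name for a in cohort.schema}
        | {RESPONSE_COLUMN, DCB_COLUMN}
        | set(cohort.extra_columns)
    )
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"columns not in schema: {unknown}")
    missing_cols = [a.name for a in cohort.schema if a.name not in df.columns]
    if missing_cols:
        raise SchemaError(f"schema attributes absent from table: {missing_cols}")

    for attr in cohort.schema:
        for pid, value in df[attr.name].items():
            _check_cell(attr, pid, value)
    if RESPONSE_COLUMN in df.columns:
        for pid, value in df[RESPONSE_COLUMN].items():
            if pd.isna(value):
                continue
            if not math.isfinite(value) or value < 0 or value != int(value):
                raise CohortParseError(
                    f"{RESPONSE_COLUMN} must be a non-negative integer; "
                    f"got {value!r} for patient {pid!r}"
                )
    if DCB_COLUMN in df.columns:
        for pid, value in df[DCB_COLUMN].items():
            if pd.isna(value):
                continue
            if value not in (0, 1):
                raise CohortParseError(
                    f"{DCB_COLUMN} must be 0 or 1; got {value!r} for patient {pid!r}"
                )
    return cohort


def _reader_kwargs(path, missing_token):
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    # round_trip parsing keeps load -> write -> load bit-identical
    return dict(sep=sep, na_values=[missing_token, ""], keep_default_na=False,
                float_precision="round_trip")


def load_cohort(
    path,
    schema: Schema | None = None,
    *,
    missing_token: str = MISSING_TOKEN,
    extra_columns: tuple[str, ...] = DEFAULT_EXTRA_COLUMNS,
) -> CohortTable:
    """Read and validate a cohort CSV/TSV.

    One row per patient; columns are ``patient_id``, the schema'd attributes,
    ``expanded_clone_count``, optionally ``dcb`` and comparator columns.
    Missing cells use ``missing_token`` (default ``"NA"``) or are left empty.
    """
    schema = validate_schema(schema or default_schema())
    df = pd.read_csv(path, dtype={"patient_id": str}, **_reader_kwargs(path, missing_token))
    if "patient_id" not in df.columns:
        raise SchemaError("cohort file lacks a patient_id column")
    df = df.set_index("patient_id")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                pid = bad.index[0]
                raise CohortParseError(
                    f"non-numeric value {bad.iloc[0]!r} in column {col!r} "
                    f"for patient {pid!r}"
                )
            df[col] = pd.to_numeric(df[col])
    for required in (RESPONSE_COLUMN, DCB_COLUMN):
        if required not in df.columns:
            df[required] = np.nan
    return validate_cohort(CohortTable(schema, df, tuple(extra_columns)))


def write_cohort(cohort: CohortTable, path, *, missing_token: str = MISSING_TOKEN) -> None:
    """Write the canonical cohort dialect; round-trips through load_cohort."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cohort.data.to_csv(path, sep=sep, na_rep=missing_token, index_label="patient_id")


def apply_score_fallback(
    cohort: CohortTable,
    primary: str = "five_factor_score",
    fallback: str = "bajorin_score",
    *,
    strict: bool = True,
) -> CohortTable:
    """Substitute a fallback score for patients missing the primary one.

    Mirrors the cohort's data-preparation rule where a patient without a
    5-factor prognostic score receives their Bajorin risk score instead. The
    substitution is generic so any primary/fallback attribute pair can reuse
    it; it is idempotent and leaves every other value untouched.

    With ``strict=True``, a patient missing both values is an error;
    otherwise the value stays missing (to be imputed downstream).
    """
    df = cohort.data
    if primary not in df.columns:
        raise SchemaError(f"primary column {primary!r} not in cohort")
    if fallback not in df.columns:
        raise SchemaError(f"fallback column {fallback!r} not in cohort")
    out = df.copy()
    needs = out[primary].isna()
    unresolved = needs & out[fallback].isna()
    if unresolved.any():
        pids = list(out.index[unresolved])
        if strict:
            raise MissingValueError(
                f"patients missing both {primary!r} and {fallback!r}: {pids}"
            )
        needs = needs & ~unresolved
    out.loc[needs, primary] = out.loc[needs, fallback]
    return validate_cohort(cohort.with_data(out))


def derive_response(
    cohort: CohortTable, pseudocount: float = 1.0, log_base: float | str = "e"
) -> np.ndarray:
    """Log-transformed expansion response: log(pseudocount + count).

    The natural log of 1 + the expanded-clone count is the default, keeping
    the transform defined at zero expansion; both the pseudocount and the
    base (``"e"`` or ``10``) are configurable and should be recorded in run
    metadata.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = cohort.data[RESPONSE_COLUMN]
    if counts.isna().any():
        pids = list(counts.index[counts.isna()])
        raise MissingValueError(f"patients without recorded clonal expansion: {pids}")
    vals = np.log(pseudocount + counts.to_numpy(dtype=float))
    if log_base not in ("e", np.e):
        vals = vals / np.log(float(log_base))
    return vals
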