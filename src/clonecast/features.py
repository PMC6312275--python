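"""Feature encoding and leakage-safe preprocessing.

Each binary attribute contributes a single 0/1 column; each continuous
attribute contributes a pair of columns, the raw value ``x`` and ``log(1+x)``,
so the linear model can capture simple nonlinear dose-response shapes. The
full 19-attribute schema therefore encodes to 2 + 17 x 2 = 36 columns.

Imputation (per-column training median) and standardization (training mean
and standard deviation) are fitted on training rows only and applied to
held-out rows, so no statistic of a held-out patient ever leaks into the
transform used to predict them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import CohortParseError, MissingValueError, NotFittedError, SchemaError
from .schema import BINARY, CATEGORIES

IDENTITY = "identity"
LOG1P = "log1p"


@dataclass(frozen=True)
class ColumnInfo:
    """Provenance of one encoded design-matrix column."""

    name: str
    source: str       # originating attribute
    transform: str    # "identity" or "log1p"
    category: str


@dataclass
class FeatureMatrix:
    """n x p design matrix with per-column provenance.

    Missing attribute values propagate to NaN cells in every derived column;
    they are filled only by a fitted :class:`Preprocessor`.
    """

    values: np.ndarray
    columns: tuple[ColumnInfo, ...]
    row_ids: tuple[str, ...]

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    def rows(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices)
        return FeatureMatrix(
            self.values[idx], self.columns, tuple(np.asarray(self.row_ids)[idx])
        )

    def category_columns(self, category: str) -> list[int]:
        return [j for j, c in enumerate(self.columns) if c.category == category]

    def restrict_categories(self, categories) -> "FeatureMatrix":
        keep = [j for j, c in enumerate(self.columns) if c.category in set(categories)]
        return FeatureMatrix(
            self.values[:, keep], tuple(self.columns[j] for j in keep), self.row_ids
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids),
                            columns=list(self.column_names))

    def to_tsv(self, path, metadata_path=None) -> None:
        """TSV of values plus a sidecar JSON of column provenance."""
        self.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="patient_id")
        if metadata_path is not None:
            meta = [c.__dict__ for c in self.columns]
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def encode_features(cohort: CohortTable, include_categories=CATEGORIES) -> FeatureMatrix:
    """Encode schema'd attributes into the design matrix.

    Only attributes whose category is in ``include_categories`` appear —
    this is the hook used by the category-ablation analysis.
    """
    include = tuple(include_categories)
    if not include:
        raise SchemaError("include_categories must be non-empty")
    unknown = set(include) - set(CATEGORIES)
    if unknown:
        raise SchemaError(f"unknown categories: {sorted(unknown)}")

    cols: list[ColumnInfo] = []
    data: list[np.ndarray] = []
    df = cohort.data
    for attr in cohort.schema:
        if attr.category not in include:
            continue
        x = df[attr.name].to_numpy(dtype=float)
        if attr.kind == BINARY:
            cols.append(ColumnInfo(attr.name, attr.name, IDENTITY, attr.category))
            data.append(x)
        else:
            if np.nanmin(x, initial=0.0) < 0:
                raise CohortParseError(
                    f"negative value in continuous attribute {attr.name!r}"
                )
            cols.append(ColumnInfo(attr.name, attr.name, IDENTITY, attr.category))
            data.append(x)
            cols.append(
                ColumnInfo(f"log1p_{attr.name}", attr.name, LOG1P, attr.category)
            )
            data.append(np.log1p(x))
    values = np.column_stack(data) if data else np.empty((cohort.n_patients, 0))
    return FeatureMatrix(values, tuple(cols), tuple(cohort.patient_ids))


@dataclass
class Preprocessor:
    """Median imputation + standardization, fitted on training rows only.

    Medians are taken over non-missing training cells of each encoded column
    (midpoint convention for even counts); means and scales are then computed
    on the imputed training columns. A zero-variance training column gets a
    scale guard of 1, so it becomes identically zero after centering rather
    than dividing by zero.
    """

    columns: tuple[ColumnInfo, ...] | None = None
    medians: np.ndarray | None = None
    means: np.ndarray | None = None
    scales: np.ndarray | None = None
    ddof: int = 0

    @property
    def fitted(self) -> bool:
        return self.medians is not None

    def fit(self, train: FeatureMatrix) -> "Preprocessor":
        X = np.asarray(train.values, dtype=float)
        all_missing = np.all(np.isnan(X), axis=0)
        if all_missing.any():
            names = [train.columns[j].name for j in np.flatnonzero(all_missing)]
            raise MissingValueError(f"columns with no non-missing training value: {names}")
        self.columns = train.columns
        self.medians = np.nanmedian(X, axis=0)
        Xi = np.where(np.isnan(X), self.medians, X)
        self.means = Xi.mean(axis=0)
        sd = Xi.std(axis=0, ddof=self.ddof)
        self.scales = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, m: FeatureMatrix) -> FeatureMatrix:
        if not self.fitted:
            raise NotFittedError("preprocessor must be fitted before use")
        if m.column_names != tuple(c.name for c in self.columns):
            raise SchemaError("feature-matrix columns do not match the preprocessor")
        X = np.asarray(m.values, dtype=float)
        Xi = np.where(np.isnan(X), self.medians, X)
        return FeatureMatrix((Xi - self.means) / self.scales, m.columns, m.row_ids)


def fit_preprocessor(train: FeatureMatrix, ddof: int = 0) -> Preprocessor:
    return Preprocessor(ddof=ddof).fit(train)


def apply_preprocessor(pp: Preprocessor, m: FeatureMatrix) -> FeatureMatrix:
    return pp.transform(m)
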