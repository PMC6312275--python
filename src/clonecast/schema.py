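"""Cohort attribute schema.

The default schema describes the 19 pre-treatment attributes used by the
clonal-expansion model: 7 clinical, 7 tumor-derived, and 5 circulating
(peripheral-blood TCR) attributes. Two clinical attributes (prior
intravesical BCG exposure and albumin below 4 g/dL) are binary; the rest are
non-negative continuous values or counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SchemaError

#: Valid attribute categories, in canonical order.
CATEGORIES: tuple[str, ...] = ("clinical", "tumor", "circulating")

BINARY = "binary"
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class Attribute:
    """One pre-treatment patient attribute.

    Parameters
    ----------
    name:
        Canonical column name in cohort files.
    category:
        One of :data:`CATEGORIES` — the feature-ablation / permutation-test
        grouping the attribute belongs to.
    kind:
        ``"binary"`` (values in {0, 1}) or ``"continuous"`` (finite, >= 0).
    allow_missing:
        Whether cells may be missing before imputation.
    """

    name: str
    category: str
    kind: str = CONTINUOUS
    allow_missing: bool = True

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"attribute {self.name!r}: unknown category {self.category!r}"
            )
        if self.kind not in (BINARY, CONTINUOUS):
            raise SchemaError(f"attribute {self.name!r}: unknown kind {self.kind!r}")


Schema = tuple[Attribute, ...]


def validate_schema(schema: Schema) -> Schema:
    """Check name uniqueness; return the schema unchanged."""
    names = [a.name for a in schema]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate attribute names: {dupes}")
    return tuple(schema)


def default_schema() -> Schema:
    """The 19-attribute schema of the urothelial anti-PD-L1 cohort.

    Attribute naming distinguishes tumor-resident TCR statistics
    (``tumor_tcr_*``) from the circulating, peripheral-blood ones
    (``blood_tcr_*``); both repertoires contribute clonality, diversity and
    T-cell fraction.
    """
    c, t, b = CATEGORIES
    return validate_schema((
        # clinical (7)
        Attribute("prior_bcg", c, BINARY, allow_missing=False),
        Attribute("age", c),
        Attribute("albumin_lt4", c, BINARY, allow_missing=False),
        Attribute("neutrophil_lymphocyte_ratio", c),
        Attribute("days_since_chemo", c),
        Attribute("five_factor_score", c),
        Attribute("chemo_regimens", c),
        # tumor (7)
        Attribute("missense_snv_count", t),
        Attribute("expressed_missense_snv_count", t),
        Attribute("neoantigen_count", t),
        Attribute("expressed_neoantigen_count", t),
        Attribute("tumor_tcr_clonality", t),
        Attribute("tumor_tcr_diversity", t),
        Attribute("tumor_t_cell_fraction", t),
        # circulating (5)
        Attribute("productive_tcr_count", b),
        Attribute("blood_tcr_clonality", b),
        Attribute("blood_tcr_diversity", b),
        Attribute("blood_t_cell_fraction", b),
        Attribute("top_clone_frequency_pct", b),
    ))


def attributes_by_category(schema: Schema, category: str) -> tuple[Attribute, ...]:
    if category not in CATEGORIES:
        raise SchemaError(f"unknown category {category!r}")
    return tuple(a for a in schema if a.category == category)
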