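"""Durable-clinical-benefit triage analysis.

A single-threshold triage rule treats every patient whose biomarker score is
at or above a cutoff. For each biomarker we ask: what is the *minimal*
fraction of non-DCB patients that must be treated so that 100% of DCB
patients are treated? Under a higher-is-better score the binding threshold is
the minimum score among DCB patients; non-DCB patients at or above it (ties
included, so full DCB capture is guaranteed under any tie structure) count as
treated. The statistic depends only on score ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, DCB_COLUMN
from .errors import TriageError


@dataclass
class TriageResult:
    biomarker: str
    higher_is_better: bool
    threshold: float
    n_dcb: int
    n_non_dcb: int
    treated_non_dcb: int
    fraction_non_dcb_treated: float
    threshold_percentile_among_non_dcb: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def triage_fraction(scores, dcb, higher_is_better: bool = True,
                    biomarker: str = "score") -> TriageResult:
    """Minimal non-DCB treat-fraction subject to treating all DCB patients.

    ``threshold_percentile_among_non_dcb`` is the percentage of non-DCB
    patients strictly below (above, for lower-is-better) the threshold, i.e.
    100 x (1 - fraction treated).
    """
    scores = np.asarray(scores, dtype=float)
    dcb = np.asarray(dcb)
    if scores.shape != dcb.shape:
        raise TriageError("scores and dcb labels must align")
    if np.isnan(scores).any():
        raise TriageError("scores must be finite")
    is_dcb = dcb == 1
    n_dcb = int(is_dcb.sum())
    n_non = int((~is_dcb).sum())
    if n_dcb == 0 or n_non == 0:
        raise TriageError("triage needs at least one DCB and one non-DCB patient")
    if higher_is_better:
        t = float(scores[is_dcb].min())
        treated = int(np.sum(scores[~is_dcb] >= t))
    else:
        t = float(scores[is_dcb].max())
        treated = int(np.sum(scores[~is_dcb] <= t))
    frac = treated / n_non
    return TriageResult(
        biomarker=biomarker,
        higher_is_better=higher_is_better,
        threshold=t,
        n_dcb=n_dcb,
        n_non_dcb=n_non,
        treated_non_dcb=treated,
        fraction_non_dcb_treated=frac,
        threshold_percentile_among_non_dcb=100.0 * (1.0 - frac),
    )


DEFAULT_COMPARATORS = (
    "missense_snv_count",
    "expressed_neoantigen_count",
    "pd_l1_staining_pct",
)

PREDICTED_EXPANSION = "predicted_expansion"


def biomarker_comparison(
    cohort: CohortTable,
    held_out_predictions,
    biomarkers=DEFAULT_COMPARATORS,
) -> pd.DataFrame:
    """Triage table: the model's held-out predictions vs single biomarkers.

    ``held_out_predictions`` are the leave-one-out predicted expansions (one
    per patient, cohort order). Each requested biomarker column is triaged
    higher-is-better; columns absent from the cohort are skipped with a
    warning. Patients lacking a DCB label are excluded throughout.
    """
    dcb = cohort.data[DCB_COLUMN]
    has_label = dcb.notna().to_numpy()
    if not has_label.any():
        raise TriageError("cohort has no DCB labels")
    labels = dcb.to_numpy(dtype=float)[has_label]
    rows = [triage_fraction(
        np.asarray(held_out_predictions, dtype=float)[has_label],
        labels, biomarker=PREDICTED_EXPANSION,
    )]
    for name in biomarkers:
        if name not in cohort.data.columns or cohort.data[name].isna().all():
            warnings.warn(f"biomarker {name!r} unavailable; skipped", stacklevel=2)
            continue
        scores = cohort.data[name].to_numpy(dtype=float)[has_label]
        # per-biomarker complete cases: patients missing this measurement
        # cannot be triaged by it
        keep = ~np.isnan(scores)
        rows.append(triage_fraction(scores[keep], labels[keep], biomarker=name))
    return pd.DataFrame([r.to_dict() for r in rows]).set_index("biomarker")
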