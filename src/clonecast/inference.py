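"""Permutation tests of association based on held-out (LOOCV) error.

Two nonparametric tests share one machinery:

* the **response-permutation test** shuffles the post-treatment responses
  across patients and asks whether the observed LOOCV error is unusually
  small relative to the null distribution — a global test that *any* input
  feature is associated with clonal expansion;
* the **category-permutation test** jointly shuffles all attributes of one
  category (clinical, tumor, or circulating) across patients while every
  other feature stays in place — a conditional test that the category adds
  signal beyond the rest.

Each replicate re-runs the full pipeline, including per-fold preprocessing
and hyperparameter selection. The p-value uses the add-one convention
(k+1)/(B+1), the exact-valid choice for permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable
from .errors import ConfigError, SchemaError
from .evaluation import (
    ModelSpec,
    fold_design_arrays,
    loocv_elastic_net_mse,
    loocv_predictions,
    prepare_loocv_folds,
    run_loocv,
)
from .features import encode_features
from .schema import CATEGORIES, attributes_by_category


@dataclass
class PermutationResult:
    observed_stat: float        # LOOCV MSE on the unpermuted cohort
    null_draws: np.ndarray      # B LOOCV MSEs under permutation
    p_value: float
    B: int
    seed: int
    permuted_target: str        # "response" or a category name

    def to_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "permuted_target": self.permuted_target,
            "null_draws": [float(v) for v in self.null_draws],
        }


def permutation_p_value(observed: float, null_draws) -> float:
    """One-sided add-one p-value: small observed error is evidence.

    p = (#{null <= observed} + 1) / (B + 1).
    """
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size == 0:
        raise ConfigError("need at least one null draw")
    k = int(np.sum(null_draws <= observed))
    return (k + 1) / (null_draws.size + 1)


def _replicate_rng(seed: int, b: int) -> np.random.Generator:
    # independent substream per replicate: results identical under any
    # execution order or parallel split
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(b)]))


def permute_response_test(
    cohort: CohortTable,
    model_spec: ModelSpec = ModelSpec(),
    B: int = 1000,
    seed: int = 0,
    include_categories=CATEGORIES,
    **loocv_kwargs,
) -> PermutationResult:
    """Global association test: permute responses uniformly at random."""
    if B < 1:
        raise ConfigError("B must be >= 1")
    observed = run_loocv(cohort, model_spec, include_categories, seed,
                         **loocv_kwargs)
    # The fold preprocessors depend only on features, so they are prepared
    # once and shared by every response permutation — numerically identical
    # to rerunning run_loocv on a response-permuted cohort.
    fm = encode_features(cohort, include_categories)
    folds = prepare_loocv_folds(fm)
    y = observed.y
    ids = cohort.patient_ids
    fused = model_spec.kind == "elastic_net"
    if fused:
        Xtr_all, Xte_all = fold_design_arrays(folds)
    draws = np.empty(B)
    for b in range(B):
        rng = _replicate_rng(seed, b + 1)
        perm = rng.permutation(cohort.n_patients)
        yp = y[perm]
        if fused:
            draws[b] = loocv_elastic_net_mse(Xtr_all, Xte_all, yp,
                                             model_spec.enet)
        else:
            preds, _, _ = loocv_predictions(folds, yp, model_spec, seed,
                                            ids, fm.columns)
            draws[b] = float(np.mean((yp - preds) ** 2))
    return PermutationResult(
        observed_stat=observed.mse,
        null_draws=draws,
        p_value=permutation_p_value(observed.mse, draws),
        B=B,
        seed=seed,
        permuted_target="response",
    )


def permute_category(cohort: CohortTable, category: str,
                     rng: np.random.Generator) -> CohortTable:
    """One uniform patient permutation applied jointly to a category block.

    All raw attributes of the category move together (rows of that block are
    reassigned to patients by a single permutation), so within-category
    structure — and the coherence of each attribute's (x, log1p x) encoded
    pair — is preserved. Permuting raw attributes before encoding is
    equivalent to jointly permuting the encoded columns because the encoding
    is row-wise.
    """
    attrs = [a.name for a in attributes_by_category(cohort.schema, category)]
    perm = rng.permutation(cohort.n_patients)
    permuted = cohort.copy()
    permuted.data[attrs] = cohort.data[attrs].to_numpy()[perm]
    return permuted


def permute_category_test(
    cohort: CohortTable,
    model_spec: ModelSpec = ModelSpec(),
    category: str = "tumor",
    B: int = 1000,
    seed: int = 0,
    **loocv_kwargs,
) -> PermutationResult:
    """Conditional association test for one feature category.

    The model always sees all features; only the category under test is
    decoupled from the patients by permutation in the null replicates.
    """
    if category not in CATEGORIES:
        raise SchemaError(f"unknown category {category!r}")
    if B < 1:
        raise ConfigError("B must be >= 1")
    observed = run_loocv(cohort, model_spec, CATEGORIES, seed, **loocv_kwargs)
    draws = np.empty(B)
    for b in range(B):
        rng = _replicate_rng(seed, b + 1)
        permuted = permute_category(cohort, category, rng)
        draws[b] = run_loocv(permuted, model_spec, CATEGORIES, seed,
                             **loocv_kwargs).mse
    return PermutationResult(
        observed_stat=observed.mse,
        null_draws=draws,
        p_value=permutation_p_value(observed.mse, draws),
        B=B,
        seed=seed,
        permuted_target=category,
    )
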