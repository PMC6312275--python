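"""Outer leave-one-out evaluation and category ablations.

Every fold withholds one patient, fits the *entire* pipeline — median
imputation, standardization, and hyperparameter selection — on the remaining
patients, and predicts the held-out patient. The mean held-out squared error
is compared against the in-sample error of the constant-mean predictor
(the empirical variance of the response), giving held-out variance explained:
``1 - loocv_mse / baseline_mse``, clamped at 0 for nominal reporting.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solver
from .cohort import CohortTable, derive_response
from .errors import ConfigError, ConvergenceError
from .features import encode_features, fit_preprocessor
from .regression import (
    ElasticNetConfig,
    RandomForestConfig,
    fit_elastic_net,
    fit_mean,
    fit_random_forest,
)
from .schema import CATEGORIES


@dataclass(frozen=True)
class ModelSpec:
    """Which learning pipeline to evaluate.

    ``kind`` is ``"elastic_net"``, ``"random_forest"``, or ``"mean"`` (the
    no-feature baseline that predicts the training-mean response).
    """

    kind: str = "elastic_net"
    enet: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    rf: RandomForestConfig = field(default_factory=RandomForestConfig)

    def __post_init__(self):
        if self.kind not in ("elastic_net", "random_forest", "mean"):
            raise ConfigError(f"unknown model kind {self.kind!r}")


def baseline_mse(y) -> float:
    """In-sample MSE of predicting the mean response for every patient.

    Equals the empirical variance of the response (denominator n); this is
    the total variance available for patient features to explain.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ConfigError("baseline MSE needs at least 2 responses")
    return float(np.mean((y - y.mean()) ** 2))


def variance_explained(mse: float, baseline: float) -> tuple[float, float]:
    """(raw, nominal) held-out variance explained.

    raw = 1 - mse/baseline may be negative when a pipeline predicts worse
    than the mean; the nominal value clamps at 0 for reporting.
    """
    if baseline <= 0:
        raise ConfigError("baseline variance must be > 0")
    raw = 1.0 - mse / baseline
    return raw, max(0.0, raw)


@dataclass
class LoocvResult:
    """Aggregated leave-one-out results for one pipeline and feature set."""

    patient_ids: tuple[str, ...]
    y: np.ndarray
    held_out_predictions: np.ndarray
    squared_errors: np.ndarray
    mse: float
    baseline_mse: float
    variance_explained_raw: float
    variance_explained_nominal: float
    fold_summaries: list[dict]
    include_categories: tuple[str, ...]
    seed: int
    fold_models: list | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": list(self.patient_ids),
            "y": self.y,
            "held_out_prediction": self.held_out_predictions,
            "squared_error": self.squared_errors,
        }).set_index("patient_id")

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "baseline_mse": self.baseline_mse,
            "variance_explained_raw": self.variance_explained_raw,
            "variance_explained_nominal": self.variance_explained_nominal,
            "include_categories": list(self.include_categories),
            "seed": self.seed,
            "n_patients": len(self.patient_ids),
            "fold_summaries": self.fold_summaries,
        }


def _fold_seed(seed: int, patient_id: str) -> int:
    """Per-fold RNG stream keyed on (seed, patient id): order-independent."""
    return int(np.random.SeedSequence(
        [int(seed), zlib.crc32(str(patient_id).encode())]
    ).generate_state(1)[0] % (2**31 - 1))


def _fit_fold(spec: ModelSpec, X, y, columns, preprocessor, fold_seed: int):
    if spec.kind == "elastic_net":
        return fit_elastic_net(X, y, spec.enet, columns=columns,
                               preprocessor=preprocessor)
    if spec.kind == "random_forest":
        cfg = RandomForestConfig(n_trees=spec.rf.n_trees, seed=fold_seed)
        return fit_random_forest(X, y, cfg, columns=columns,
                                 preprocessor=preprocessor)
    return fit_mean(X, y, columns=columns, preprocessor=preprocessor)


def prepare_loocv_folds(fm):
    """Per-fold preprocessing for leave-one-out evaluation.

    Returns one (preprocessor, X_train, X_held_out, train_idx) tuple per
    patient, with the preprocessor fitted on the non-withheld rows only.
    These depend only on the feature matrix, never on the response, so they
    may be reused across response permutations.
    """
    n = fm.values.shape[0]
    folds = []
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        fm_train = fm.rows(train_idx)
        pp = fit_preprocessor(fm_train)
        X_train = pp.transform(fm_train).values
        X_i = pp.transform(fm.rows([i])).values
        folds.append((pp, X_train, X_i, train_idx))
    return folds


def loocv_predictions(folds, y, model_spec, seed, patient_ids, columns,
                      keep_models=False):
    """Held-out predictions given prepared folds; returns (preds, summaries, models)."""
    n = len(folds)
    preds = np.empty(n)
    summaries = []
    models = [] if keep_models else None
    for i, (pp, X_train, X_i, train_idx) in enumerate(folds):
        fseed = _fold_seed(seed, patient_ids[i])
        fit = _fit_fold(model_spec, X_train, y[train_idx], columns, pp, fseed)
        preds[i] = float(fit.predict_preprocessed(X_i)[0])
        summary = {"patient_id": patient_ids[i]}
        if model_spec.kind == "elastic_net":
            summary.update(l1_ratio=fit.l1_ratio, lam=fit.lam,
                           n_retained=fit.n_retained)
        summaries.append(summary)
        if keep_models:
            models.append(fit)
    return preds, summaries, models


def fold_design_arrays(folds):
    """Stack prepared folds into the (n, n-1, p) / (n, p) solver layout."""
    Xtr_all = np.stack([f[1] for f in folds])
    Xte_all = np.vstack([f[2] for f in folds])
    return Xtr_all, Xte_all


def loocv_elastic_net_mse(Xtr_all, Xte_all, y, cfg) -> float:
    """Held-out MSE of the nested elastic net over prepared fold arrays.

    The hot path of the permutation tests: one jitted call runs all folds,
    including per-fold hyperparameter selection, with numerics identical to
    fitting fold by fold through :func:`clonecast.regression.fit_elastic_net`.
    """
    from .regression import _inner_k  # local import avoids a cycle

    preds, _, _, _, fail = solver.loocv_enet(
        Xtr_all, Xte_all, y, np.asarray(cfg.l1_ratio_grid, dtype=float),
        cfg.lambda_path_size, cfg.lambda_min_ratio, cfg.tolerance,
        cfg.max_iterations, _inner_k(cfg.inner_cv, len(y) - 1),
        cfg.tie_tolerance)
    if fail:
        raise ConvergenceError("active-set search did not settle in a fold")
    return float(np.mean((y - preds) ** 2))


def _loocv_elastic_net_fused(folds, y, cfg, patient_ids):
    from .regression import _inner_k

    Xtr_all, Xte_all = fold_design_arrays(folds)
    preds, rho_sel, lam_sel, n_ret, fail = solver.loocv_enet(
        Xtr_all, Xte_all, y, np.asarray(cfg.l1_ratio_grid, dtype=float),
        cfg.lambda_path_size, cfg.lambda_min_ratio, cfg.tolerance,
        cfg.max_iterations, _inner_k(cfg.inner_cv, len(y) - 1),
        cfg.tie_tolerance)
    if fail:
        raise ConvergenceError("active-set search did not settle in a fold")
    summaries = [
        {"patient_id": pid, "l1_ratio": float(r), "lam": float(l),
         "n_retained": int(m)}
        for pid, r, l, m in zip(patient_ids, rho_sel, lam_sel, n_ret)
    ]
    return preds, summaries


def run_loocv(
    cohort: CohortTable,
    model_spec: ModelSpec = ModelSpec(),
    include_categories=CATEGORIES,
    seed: int = 0,
    *,
    pseudocount: float = 1.0,
    log_base="e",
    keep_models: bool = False,
) -> LoocvResult:
    """Leave-one-out evaluation of the full pipeline.

    The preprocessor and the model (including its hyperparameter search) are
    fitted inside each fold on the non-withheld patients only, so held-out
    predictions carry no information leaked from the withheld patient.
    """
    if cohort.n_patients < 3:
        raise ConfigError("leave-one-out evaluation needs at least 3 patients")
    y = derive_response(cohort, pseudocount=pseudocount, log_base=log_base)
    fm = encode_features(cohort, include_categories)
    folds = prepare_loocv_folds(fm)
    if model_spec.kind == "elastic_net" and not keep_models:
        preds, summaries = _loocv_elastic_net_fused(folds, y, model_spec.enet,
                                                    cohort.patient_ids)
        models = None
    else:
        preds, summaries, models = loocv_predictions(
            folds, y, model_spec, seed, cohort.patient_ids, fm.columns,
            keep_models=keep_models,
        )
    sq = (y - preds) ** 2
    mse = float(np.mean(sq))
    base = baseline_mse(y)
    raw, nominal = variance_explained(mse, base)
    return LoocvResult(
        patient_ids=tuple(cohort.patient_ids),
        y=y,
        held_out_predictions=preds,
        squared_errors=sq,
        mse=mse,
        baseline_mse=base,
        variance_explained_raw=raw,
        variance_explained_nominal=nominal,
        fold_summaries=summaries,
        include_categories=tuple(include_categories),
        seed=seed,
        fold_models=models,
    )


def ablate_categories(
    cohort: CohortTable,
    model_spec: ModelSpec = ModelSpec(),
    seed: int = 0,
    **loocv_kwargs,
) -> dict[str, LoocvResult]:
    """LOOCV with each feature category excluded in turn.

    Returns a map keyed by the *excluded* category, plus ``"none"`` for the
    all-categories reference run.
    """
    out = {"none": run_loocv(cohort, model_spec, CATEGORIES, seed, **loocv_kwargs)}
    for cat in CATEGORIES:
        keep = tuple(c for c in CATEGORIES if c != cat)
        out[cat] = run_loocv(cohort, model_spec, keep, seed, **loocv_kwargs)
    return out
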