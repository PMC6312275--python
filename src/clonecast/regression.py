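"""Elastic-net model with inner-CV hyperparameter selection, plus comparators.

The core fit searches a grid of L1 ratios (rho) crossed with a geometric
penalty path per rho, scoring each (rho, lambda) by leave-one-out (or k-fold)
cross-validation *inside the training data*, then refits the winner on all
training rows. Ties within 1e-12 of the minimal inner-CV error resolve to the
largest lambda, then the smallest rho — the sparser, more regularized model.

A 1000-tree random forest and an intercept-only mean model are provided as
comparators with the same fit/predict contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from . import solver
from .errors import ConfigError, ConvergenceError, SchemaError
from .features import FeatureMatrix, Preprocessor

DEFAULT_L1_RATIO_GRID = (0.1, 0.5, 0.7, 0.9, 0.95, 0.99)


@dataclass(frozen=True)
class ElasticNetConfig:
    """Hyperparameter-search settings.

    ``l1_ratio_grid`` defaults to the six candidates recommended for
    CV-selected elastic nets; ``lambda_path_size`` geometric path points per
    ratio run from lambda_max down to ``lambda_max * lambda_min_ratio``.
    ``inner_cv`` is ``"loo"`` or an integer fold count.
    """

    l1_ratio_grid: tuple[float, ...] = DEFAULT_L1_RATIO_GRID
    lambda_path_size: int = 100
    lambda_min_ratio: float = 1e-3
    tolerance: float = 1e-7
    max_iterations: int = 1_000_000
    inner_cv: int | str = "loo"
    tie_tolerance: float = 1e-12

    def __post_init__(self):
        if not self.l1_ratio_grid:
            raise ConfigError("l1_ratio_grid must be non-empty")
        for r in self.l1_ratio_grid:
            if not (0.0 < r <= 1.0):
                raise ConfigError(f"l1 ratio {r} outside (0, 1]")
        if self.tolerance <= 0:
            raise ConfigError("tolerance must be > 0")
        if self.lambda_path_size < 1 or not (0 < self.lambda_min_ratio < 1):
            raise ConfigError("invalid lambda path settings")


#: A small, fast configuration for simulation studies that need thousands of
#: refits (permutation replicates); the selection logic is identical.
FAST_ENET_CONFIG = ElasticNetConfig(
    l1_ratio_grid=(0.5,), lambda_path_size=8, lambda_min_ratio=1e-2,
    tolerance=1e-5, inner_cv=3,
)


@dataclass
class FitResult:
    """Fitted elastic net: coefficients, chosen hyperparameters, provenance."""

    intercept: float
    coef: np.ndarray
    l1_ratio: float
    lam: float
    columns: tuple | None = None
    preprocessor: Preprocessor | None = None
    inner_cv_mse: float | None = None

    @property
    def retained_features(self) -> tuple[str, ...]:
        idx = np.flatnonzero(self.coef)
        if self.columns is not None:
            return tuple(self.columns[j].name for j in idx)
        return tuple(str(j) for j in idx)

    @property
    def n_retained(self) -> int:
        return int(np.count_nonzero(self.coef))

    def predict_preprocessed(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coef

    def to_dict(self) -> dict:
        names = (tuple(c.name for c in self.columns) if self.columns is not None
                 else tuple(map(str, range(len(self.coef)))))
        return {
            "intercept": self.intercept,
            "l1_ratio": self.l1_ratio,
            "lambda": self.lam,
            "coefficients": dict(zip(names, map(float, self.coef))),
            "retained_features": list(self.retained_features),
        }


def _inner_k(inner_cv, n: int) -> int:
    """Inner-CV fold count; 0 encodes leave-one-out for the solver core."""
    if inner_cv == "loo":
        return 0
    k = int(inner_cv)
    if k < 2 or k > n:
        raise ConfigError(f"inner_cv fold count {k} invalid for n={n}")
    return k


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ElasticNetConfig = ElasticNetConfig(),
    *,
    columns=None,
    preprocessor: Preprocessor | None = None,
) -> FitResult:
    """Fit with nested-CV selection of (rho, lambda) on preprocessed data.

    ``X`` must be fully observed (impute first); the per-rho path is anchored
    at lambda_max computed on all of (X, y), each point scored by inner CV,
    and the winner refit on everything.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ConfigError(f"need at least 3 samples to fit, got {n}")
    if np.isnan(X).any():
        raise ValueError("X has missing cells; apply a fitted preprocessor first")
    coef, intercept, rho, lam, inner_mse, fail = solver.nested_enet_fit(
        X, y, np.asarray(cfg.l1_ratio_grid, dtype=float),
        cfg.lambda_path_size, cfg.lambda_min_ratio, cfg.tolerance,
        cfg.max_iterations, _inner_k(cfg.inner_cv, n), cfg.tie_tolerance,
    )
    if fail:
        raise ConvergenceError(
            f"active-set search did not settle at rho={rho}, lambda={lam}",
            l1_ratio=float(rho), lam=float(lam),
        )
    return FitResult(
        intercept=float(intercept),
        coef=coef,
        l1_ratio=float(rho),
        lam=float(lam),
        columns=columns,
        preprocessor=preprocessor,
        inner_cv_mse=float(inner_mse),
    )


def predict(fit, X_new: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Apply the fit's stored preprocessor to raw features, then predict."""
    if isinstance(X_new, FeatureMatrix):
        if fit.preprocessor is None:
            raise SchemaError("fit carries no preprocessor; pass preprocessed arrays")
        X_new = fit.preprocessor.transform(X_new).values
    return fit.predict_preprocessed(np.asarray(X_new, dtype=float))


@dataclass(frozen=True)
class RandomForestConfig:
    n_trees: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")


@dataclass
class RandomForestFit:
    model: RandomForestRegressor
    columns: tuple | None = None
    preprocessor: Preprocessor | None = None

    def predict_preprocessed(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.atleast_2d(np.asarray(X, dtype=float)))


def fit_random_forest(X, y, cfg: RandomForestConfig = RandomForestConfig(),
                      *, columns=None, preprocessor=None) -> RandomForestFit:
    """Comparator regression forest; deterministic given ``cfg.seed``."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ConfigError("random forest needs at least 2 samples")
    model = RandomForestRegressor(n_estimators=cfg.n_trees, random_state=cfg.seed)
    model.fit(X, np.asarray(y, dtype=float))
    return RandomForestFit(model, columns, preprocessor)


@dataclass
class MeanFit:
    """Intercept-only baseline: predicts the training mean everywhere."""

    intercept: float
    columns: tuple | None = None
    preprocessor: Preprocessor | None = None

    def predict_preprocessed(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.full(X.shape[0], self.intercept)


def fit_mean(X, y, *, columns=None, preprocessor=None) -> MeanFit:
    return MeanFit(float(np.mean(y)), columns, preprocessor)
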