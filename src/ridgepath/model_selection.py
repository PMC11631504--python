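"""Inner k-fold cross-validation over a lambda grid.

The grid is built once from the full outer-training set (standardized with
its own statistics) and shared across inner folds, matching cv.glmnet's
behavior.  Within each inner fold the standardization is refit on the
inner-training block only, so validation rows never leak into the fitted
coefficients; validation predictions are back-transformed and scored on
the original phenotype scale.

Validation error per lambda is recorded both as the raw sum of squared
errors and as the per-observation mean; the fold average (``mean_mse``)
uses the per-observation mean so unequal fold sizes average correctly.
The selected lambda minimizes ``mean_mse``; exact ties resolve to the
largest (most regularized) lambda.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import preprocess
from .lambda_grids import LambdaGrid, conventional_grid, variance_ratio_grid
from .solver import PenalizedFit, fit_path, predict

__all__ = ["CVResult", "FittedModel", "make_folds", "inner_cv", "refit_full"]

GRID_BUILDERS = {
    "conventional": lambda Xs, ys, y, n_points: conventional_grid(Xs, ys, n_points),
    "variance_ratio": lambda Xs, ys, y, n_points: variance_ratio_grid(
        Xs, s_y2=float(np.var(y)), n_points=n_points
    ),
}


@dataclass
class CVResult:
    """Inner-CV losses over a grid and the selected penalty."""

    grid: LambdaGrid
    fold_mse: np.ndarray  # (k, n_lambda) per-observation validation MSE
    fold_sse: np.ndarray  # (k, n_lambda) raw sums of squared errors
    mean_mse: np.ndarray  # (n_lambda,)
    lambda_opt: float
    lambda_opt_index: int
    fold_assignment: np.ndarray
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.grid.method,
                "lambdas": self.grid.values.tolist(),
                "fold_mse": self.fold_mse.tolist(),
                "mean_mse": self.mean_mse.tolist(),
                "lambda_opt": self.lambda_opt,
                "lambda_opt_index": self.lambda_opt_index,
                "fold_assignment": self.fold_assignment.tolist(),
                "seed": self.seed,
            },
            sort_keys=True,
        )


@dataclass
class FittedModel:
    """A single-lambda fit together with its training standardization."""

    fit: PenalizedFit
    stats: preprocess.StandardizationStats
    lambda_opt: float
    alpha: float

    def predict(self, X_new) -> np.ndarray:
        """Predictions on the original phenotype scale."""
        Xs_new = preprocess.transform(X_new, stats=self.stats)
        ys_hat = predict(self.fit, Xs_new, lambda_index=0)
        return preprocess.inverse_transform_predictions(ys_hat, self.stats)


def make_folds(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random partition of ``range(n)`` into k folds with sizes differing <= 1.

    Returns an (n,) integer array of fold labels in 0..k-1, deterministic
    given ``seed``.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    return assignment


def _fit_fold(X, y, train_idx, grid, alpha, engine="auto", tol=1e-7,
              max_iter=100_000):
    """Standardize on the training rows only and fit the path.

    Split out so leakage is testable directly: only rows in ``train_idx``
    ever reach the standardizer or the solver.
    """
    stats = preprocess.fit_standardizer(X[train_idx], y[train_idx])
    Xs_tr, ys_tr = preprocess.transform(X[train_idx], y[train_idx], stats=stats)
    fit = fit_path(Xs_tr, ys_tr, grid, alpha=alpha, tol=tol, max_iter=max_iter,
                   engine=engine)
    return stats, fit


def inner_cv(
    X,
    y,
    grid_method: str = "variance_ratio",
    alpha: float = 0.0,
    k: int = 10,
    seed: int = 0,
    n_points: int = 100,
    engine: str = "auto",
    grid: LambdaGrid | None = None,
) -> CVResult:
    """Select lambda by k-fold CV on the (outer-)training data.

    ``grid_method`` is one of ``"conventional"`` / ``"variance_ratio"``;
    alternatively a prebuilt ``grid`` may be supplied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} inner folds")
    if n - int(np.ceil(n / k)) < 2:
        raise ValueError("inner training blocks need at least 2 samples")

    if grid is None:
        if grid_method not in GRID_BUILDERS:
            raise ValueError(f"unknown grid method {grid_method!r}")
        stats_full = preprocess.fit_standardizer(X, y)
        Xs_full, ys_full = preprocess.transform(X, y, stats=stats_full)
        grid = GRID_BUILDERS[grid_method](Xs_full, ys_full, y, n_points)

    assignment = make_folds(n, k, seed)
    L = grid.n_points
    fold_sse = np.zeros((k, L))
    fold_mse = np.zeros((k, L))
    for fold in range(k):
        val = np.flatnonzero(assignment == fold)
        tr = np.flatnonzero(assignment != fold)
        stats, fit = _fit_fold(X, y, tr, grid, alpha, engine=engine)
        Xs_val = preprocess.transform(X[val], stats=stats)
        preds_std = predict(fit, Xs_val)  # (n_val, L)
        preds = preprocess.inverse_transform_predictions(preds_std, stats)
        err = preds - y[val][:, None]
        fold_sse[fold] = np.einsum("ij,ij->j", err, err)
        fold_mse[fold] = fold_sse[fold] / val.size

    mean_mse = fold_mse.mean(axis=0)
    # grid is descending, argmin returns the first (largest-lambda) minimizer
    idx = int(np.argmin(mean_mse))
    return CVResult(
        grid=grid,
        fold_mse=fold_mse,
        fold_sse=fold_sse,
        mean_mse=mean_mse,
        lambda_opt=float(grid.values[idx]),
        lambda_opt_index=idx,
        fold_assignment=assignment,
        seed=seed,
    )


def refit_full(X, y, lambda_opt: float, alpha: float = 0.0,
               engine: str = "auto") -> FittedModel:
    """Refit at the selected lambda on the full (outer-)training set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    stats = preprocess.fit_standardizer(X, y)
    Xs, ys = preprocess.transform(X, y, stats=stats)
    fit = fit_path(Xs, ys, np.array([lambda_opt], dtype=float), alpha=alpha,
                   engine=engine)
    return FittedModel(fit=fit, stats=stats, lambda_opt=float(lambda_opt),
                       alpha=alpha)
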