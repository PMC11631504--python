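"""Elastic-net path solver under the glmnet objective convention.

For standardized data (Xs, ys) and mixing parameter alpha in [0, 1] the
objective minimized at each lambda is

    (1/(2n)) * sum_i (y_i - b0 - x_i'b)^2
        + lambda * [ (1-alpha)/2 * ||b||_2^2 + alpha * ||b||_1 ] .

The textbook penalized residual sum of squares with no 1/n factor,
RSS + lambda_PRSS * ||b||^2, corresponds to lambda_PRSS = n * lambda under
this convention (the factor 2 in 1/(2n) cancels against the ridge penalty's
1/2); both grid constructions presuppose the per-observation scale.

Two engines are available:

* ``svd`` (ridge only): one thin SVD of Xs, then the whole path in closed
  form, beta(lambda) = V diag(s_i / n / (s_i^2/n + lambda)) U'y.  This also
  realizes the dual/Woodbury route automatically when p >> n, since the
  economy SVD has rank min(n, p).
* ``cd``: cyclical coordinate descent with soft-thresholding updates and
  warm starts down the descending path — required for alpha > 0 and used
  as the cross-check route for ridge.

On standardized inputs the intercept is analytically zero; it is computed
from the column means (b0 = mean(y) - mean(x)'b) rather than estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .lambda_grids import LambdaGrid

logger = logging.getLogger(__name__)

__all__ = ["PenalizedFit", "fit_path", "predict", "elastic_net_objective"]


@dataclass
class PenalizedFit:
    """Coefficients along a lambda path for one mixing parameter.

    ``coefficients`` has shape (n_lambda, p) on the standardized scale;
    ``intercepts`` one value per lambda; ``n_iter`` and ``max_change``
    record per-lambda convergence (zeros for the closed-form engine).
    """

    alpha: float
    lambdas: np.ndarray
    intercepts: np.ndarray
    coefficients: np.ndarray
    n_iter: np.ndarray
    max_change: np.ndarray
    converged: np.ndarray
    engine: str = "svd"

    @property
    def n_lambda(self) -> int:
        return self.lambdas.size

    @property
    def p(self) -> int:
        return self.coefficients.shape[1]


def elastic_net_objective(Xs, ys, beta, b0: float, lam: float, alpha: float) -> float:
    """Value of the (1/(2n))RSS + penalty objective at (b0, beta)."""
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    r = ys - b0 - Xs @ beta
    n = ys.size
    pen = lam * ((1.0 - alpha) / 2.0 * float(beta @ beta)
                 + alpha * float(np.abs(beta).sum()))
    return float(r @ r) / (2.0 * n) + pen


def _ridge_path_svd(Xs, ys, lambdas):
    n = Xs.shape[0]
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    uty = U.T @ ys
    # beta(lam) = V diag( (s/n) / (s^2/n + lam) ) U'y
    d = (s[None, :] / n) / (s[None, :] ** 2 / n + np.asarray(lambdas)[:, None])
    return (d * uty[None, :]) @ Vt  # (n_lambda, p)


def _cd_path(Xs, ys, lambdas, alpha, tol, max_iter, warm_start):
    n, p = Xs.shape
    col_sq = np.einsum("ij,ij->j", Xs, Xs) / n  # (1/n)||x_j||^2; ~1 when standardized
    coefs = np.zeros((len(lambdas), p))
    n_iter = np.zeros(len(lambdas), dtype=int)
    max_change = np.zeros(len(lambdas))
    converged = np.zeros(len(lambdas), dtype=bool)

    beta = np.zeros(p)
    r = ys.copy()  # residual y - X beta
    for li, lam in enumerate(lambdas):
        if not warm_start:
            beta = np.zeros(p)
            r = ys.copy()
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for it in range(1, max_iter + 1):
            delta = 0.0
            for j in range(p):
                bj = beta[j]
                xj = Xs[:, j]
                z = xj @ r / n + col_sq[j] * bj
                if l1 > 0.0:
                    bj_new = np.sign(z) * max(abs(z) - l1, 0.0) / (col_sq[j] + l2)
                else:
                    bj_new = z / (col_sq[j] + l2)
                if bj_new != bj:
                    r += xj * (bj - bj_new)
                    beta[j] = bj_new
                    delta = max(delta, abs(bj_new - bj))
            if delta < tol:
                n_iter[li] = it
                max_change[li] = delta
                converged[li] = True
                break
        else:
            n_iter[li] = max_iter
            max_change[li] = delta
            logger.warning(
                "coordinate descent did not converge at lambda=%.4g "
                "(max change %.3g after %d sweeps)", lam, delta, max_iter
            )
        coefs[li] = beta
    return coefs, n_iter, max_change, converged


def fit_path(
    Xs,
    ys,
    grid: LambdaGrid | np.ndarray,
    alpha: float = 0.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    engine: str = "auto",
    warm_start: bool = True,
) -> PenalizedFit:
    """Fit the penalized regression along a descending lambda path.

    Parameters
    ----------
    Xs, ys : standardized training data.
    grid : LambdaGrid or descending array of penalties.
    alpha : elastic-net mixing parameter; 0 = ridge, 1 = lasso.
    engine : "svd" (closed-form ridge, alpha=0 only), "cd" (coordinate
        descent), or "auto" (svd when alpha == 0, else cd).
    """
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float).ravel()
    if Xs.ndim != 2 or Xs.shape[0] != ys.size:
        raise ValueError("Xs must be 2-D with rows matching ys")
    if not (np.isfinite(Xs).all() and np.isfinite(ys).all()):
        raise ValueError("non-finite values in training data")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")

    lambdas = grid.values if isinstance(grid, LambdaGrid) else np.asarray(grid, float)
    if lambdas.ndim != 1 or lambdas.size == 0:
        raise ValueError("empty lambda path")
    if (np.diff(lambdas) > 0).any():
        raise ValueError("lambda path must be non-increasing")
    if (lambdas < 0).any():
        raise ValueError("negative lambda")

    if engine == "auto":
        engine = "svd" if alpha == 0.0 else "cd"
    if engine == "svd":
        if alpha != 0.0:
            raise ValueError("svd engine is ridge-only (alpha = 0)")
        coefs = _ridge_path_svd(Xs, ys, lambdas)
        L = lambdas.size
        n_iter = np.zeros(L, dtype=int)
        max_change = np.zeros(L)
        converged = np.ones(L, dtype=bool)
    elif engine == "cd":
        coefs, n_iter, max_change, converged = _cd_path(
            Xs, ys, lambdas, alpha, tol, max_iter, warm_start
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")

    # intercept from the (near-zero) means of standardized data
    intercepts = ys.mean() - coefs @ Xs.mean(axis=0)
    return PenalizedFit(
        alpha=alpha,
        lambdas=np.asarray(lambdas, dtype=float),
        intercepts=intercepts,
        coefficients=coefs,
        n_iter=n_iter,
        max_change=max_change,
        converged=converged,
        engine=engine,
    )


def predict(fit: PenalizedFit, Xs_new, lambda_index: int | None = None) -> np.ndarray:
    """Standardized-scale predictions.

    With ``lambda_index`` given, returns an (n_new,) vector for that path
    position; otherwise an (n_new, n_lambda) matrix for the whole path.
    """
    Xs_new = np.asarray(Xs_new, dtype=float)
    if Xs_new.ndim != 2 or Xs_new.shape[1] != fit.p:
        raise ValueError(
            f"expected {fit.p} columns, got {Xs_new.shape[1] if Xs_new.ndim == 2 else 'non-2D'}"
        )
    if lambda_index is None:
        return Xs_new @ fit.coefficients.T + fit.intercepts[None, :]
    if not -fit.n_lambda <= lambda_index < fit.n_lambda:
        raise IndexError(f"lambda_index {lambda_index} out of range")
    return fit.intercepts[lambda_index] + Xs_new @ fit.coefficients[lambda_index]
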