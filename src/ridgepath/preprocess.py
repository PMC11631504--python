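"""Training-set standardization for penalized genomic regression.

Marker columns and the phenotype are centered and scaled using statistics
computed on the *training* partition only, with the population (1/n)
variance convention throughout.  This convention matters: the conventional
lambda-path construction and the variance-ratio grid both assume it, and
under it the squared column norms of the standardized matrix sum exactly
to the number of markers.

Zero-variance (monomorphic) marker columns are dropped rather than raising:
cross-validation subsampling of real marker panels routinely produces
monomorphic columns inside a fold.  The dropped indices are recorded so the
column map back to the original matrix is never lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationStats",
    "fit_standardizer",
    "transform",
    "inverse_transform_predictions",
]


@dataclass(frozen=True)
class StandardizationStats:
    """Per-column and response moments estimated on a training partition.

    Attributes
    ----------
    column_means : (p,) means of the retained marker columns.
    column_sds : (p,) standard deviations of the retained columns,
        computed with the 1/n_trn divisor (population convention).
    response_mean : training phenotype mean.
    response_sd : training phenotype SD, 1/n_trn divisor.
    n_trn : number of training samples the stats were fitted on.
    kept_columns : indices (into the original matrix) of columns retained.
    dropped_columns : indices of zero-variance columns that were excluded.
    n_columns_original : column count of the matrix the stats were fit on.
    """

    column_means: np.ndarray
    column_sds: np.ndarray
    response_mean: float
    response_sd: float
    n_trn: int
    kept_columns: np.ndarray
    dropped_columns: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_columns_original: int = 0


def _as_2d_float(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D marker matrix, got shape {X.shape}")
    return X


def fit_standardizer(X, y) -> StandardizationStats:
    """Estimate column/response moments on the training block.

    Variances use the 1/n_trn divisor (NOT 1/(n_trn - 1)).  Columns with
    zero variance are recorded in ``dropped_columns`` and excluded from the
    retained statistics.

    Raises
    ------
    ValueError
        If every column is constant ("no informative markers"), if the
        response is constant ("zero phenotypic variance"), if there are
        missing values, or if fewer than two training rows are supplied.
    """
    X = _as_2d_float(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("standardization requires at least 2 training samples")
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} entries")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("missing or non-finite values are not allowed here; "
                         "impute at the I/O layer first")

    means = X.mean(axis=0)
    sds = X.std(axis=0)  # numpy default ddof=0 == 1/n divisor
    kept = np.flatnonzero(sds > 0.0)
    dropped = np.flatnonzero(sds == 0.0)
    if kept.size == 0:
        raise ValueError("no informative markers: every column has zero variance")
    if dropped.size:
        logger.warning("dropping %d zero-variance marker column(s)", dropped.size)

    y_mean = float(y.mean())
    y_sd = float(y.std())
    if y_sd == 0.0:
        raise ValueError("zero phenotypic variance: response is constant")

    return StandardizationStats(
        column_means=means[kept],
        column_sds=sds[kept],
        response_mean=y_mean,
        response_sd=y_sd,
        n_trn=n,
        kept_columns=kept,
        dropped_columns=dropped,
        n_columns_original=p,
    )


def transform(X, y=None, *, stats: StandardizationStats):
    """Standardize a marker block (and optionally a response) with fitted stats.

    Columns listed in ``stats.dropped_columns`` are removed; remaining columns
    are mapped to ``(x - mean) / sd``.  ``y`` is mapped analogously.  The block
    may be training data or held-out data — the statistics are always the
    training ones carried by ``stats``.

    Returns ``Xs`` or ``(Xs, ys)`` depending on whether ``y`` was given.
    """
    X = _as_2d_float(X)
    if X.shape[1] != stats.n_columns_original:
        raise ValueError(
            f"column mismatch: stats were fit on {stats.n_columns_original} "
            f"columns, got {X.shape[1]}"
        )
    Xs = (X[:, stats.kept_columns] - stats.column_means) / stats.column_sds
    if y is None:
        return Xs
    y = np.asarray(y, dtype=float).ravel()
    ys = (y - stats.response_mean) / stats.response_sd
    return Xs, ys


def inverse_transform_predictions(ys_hat, stats: StandardizationStats) -> np.ndarray:
    """Map standardized-scale predictions back to the observed phenotype scale.

    ``y_hat = response_mean + response_sd * ys_hat``.  Applied so that
    correlation and normalized-RMSE metrics operate on observed-scale values.
    """
    ys_hat = np.asarray(ys_hat, dtype=float)
    return stats.response_mean + stats.response_sd * ys_hat
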