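"""Frequentist GBLUP: VanRaden genomic relationships + spectral REML.

The mixed model is y_i = mu + g_i + e_i with g ~ N(0, sigma_g^2 G) and
independent errors of variance sigma^2.  G is the VanRaden (method 1)
genomic relationship matrix

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),    Z = X - 2p,

with p_j the allele frequency estimated from the dosage column mean / 2.
Monomorphic columns contribute zero to Z and are excluded from the scale
constant.

Variance components are estimated by restricted maximum likelihood,
profiled down to a one-dimensional search over the variance ratio
delta = sigma^2 / sigma_g^2 on a log-scale bracket [1e-9, 1e9] after a
single eigendecomposition of the training-block G.  Predictions for
unphenotyped lines are the BLUPs

    g_hat_test = G[test, train] (G[train, train] + delta I)^{-1} (y - mu),

which coincide exactly with marker-ridge predictions on Z at the mapped
penalty (G = ZZ'/c implies the glmnet-scale lambda = delta * c / n), the
reparameterization that makes GBLUP and snp-BLUP two routes to the same
predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRelationship",
    "GblupFit",
    "vanraden_G",
    "reml_fit",
    "blup_predictions",
    "gblup_predict",
]

_DELTA_LOG_BRACKET = (np.log(1e-9), np.log(1e9))


@dataclass(frozen=True)
class GenomicRelationship:
    """VanRaden genomic relationship matrix with its construction pieces."""

    matrix: np.ndarray
    allele_freqs: np.ndarray
    scale_constant: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GblupFit:
    """REML variance components, GLS mean, and BLUPs for all lines."""

    mu: float
    sigma_g2: float
    sigma_e2: float
    delta: float
    blups: np.ndarray  # genetic values for ALL lines (train + unphenotyped)
    train_idx: np.ndarray
    reml_loglik: float

    @property
    def h2(self) -> float:
        """Estimated proportion of variance that is genetic."""
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def vanraden_G(X) -> GenomicRelationship:
    """VanRaden method-1 G from a lines x markers dosage matrix in [0, 2]."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D dosage matrix with at least 2 markers")
    if X.min() < 0 or X.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    p = X.mean(axis=0) / 2.0
    het = p * (1.0 - p)
    poly = het > 0
    if not poly.any():
        raise ValueError("all markers monomorphic: G undefined")
    c = 2.0 * float(het[poly].sum())
    Z = X - 2.0 * p  # monomorphic columns center to exactly zero
    G = (Z @ Z.T) / c
    return GenomicRelationship(matrix=G, allele_freqs=p, scale_constant=c)


def _stabilize(G: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(G)
    if w.min() < -1e-8:
        logger.warning(
            "G has eigenvalue %.3g below tolerance; adding 1e-6 ridge to diagonal",
            w.min(),
        )
        G = G + 1e-6 * np.eye(G.shape[0])
    return G


def reml_fit(y, G: GenomicRelationship | np.ndarray,
             train_idx=None) -> GblupFit:
    """Profile-REML fit of the GBLUP model.

    ``y`` holds phenotypes for the training lines (ordered as
    ``train_idx`` indexes into G; all lines when ``train_idx`` is None).
    The restricted likelihood, profiled over mu and sigma_g^2, is
    maximized over log(delta) by bounded scalar minimization.
    """
    Gm = G.matrix if isinstance(G, GenomicRelationship) else np.asarray(G, float)
    if not np.allclose(Gm, Gm.T, atol=1e-10):
        raise ValueError("G must be symmetric")
    n_all = Gm.shape[0]
    train_idx = (np.arange(n_all) if train_idx is None
                 else np.asarray(train_idx, dtype=int))
    y = np.asarray(y, dtype=float).ravel()
    if y.size != train_idx.size:
        raise ValueError("y length must match the number of training lines")

    Gm = _stabilize(Gm)
    Gtt = Gm[np.ix_(train_idx, train_idx)]
    w, U = np.linalg.eigh(Gtt)
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    ot = U.T @ np.ones_like(y)
    n = y.size

    def neg_restricted_loglik(log_delta: float) -> float:
        d = w + np.exp(log_delta)
        a = 1.0 / d
        mu = float((a * ot * yt).sum() / (a * ot * ot).sum())
        resid = yt - ot * mu
        q = float((a * resid * resid).sum())
        sg2 = q / (n - 1)
        return 0.5 * ((n - 1) * np.log(sg2) + np.log(d).sum()
                      + np.log((a * ot * ot).sum()) + (n - 1))

    res = minimize_scalar(neg_restricted_loglik, bounds=_DELTA_LOG_BRACKET,
                          method="bounded",
                          options={"xatol": 1e-8})
    delta = float(np.exp(res.x))

    d = w + delta
    a = 1.0 / d
    mu = float((a * ot * yt).sum() / (a * ot * ot).sum())
    resid = yt - ot * mu
    sigma_g2 = float((a * resid * resid).sum()) / (n - 1)
    sigma_e2 = sigma_g2 * delta
    blups = blup_predictions(Gm, y, train_idx, delta, mu)
    return GblupFit(
        mu=mu,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        blups=blups,
        train_idx=train_idx,
        reml_loglik=-float(res.fun),
    )


def blup_predictions(G, y_train, train_idx, delta: float, mu: float) -> np.ndarray:
    """BLUP genetic values for every line given a variance ratio delta.

    g_hat = G[:, train] (G[train, train] + delta I)^{-1} (y_train - mu).
    Exposed separately so shrinkage limits and the ridge equivalence can be
    exercised at arbitrary delta.
    """
    Gm = G.matrix if isinstance(G, GenomicRelationship) else np.asarray(G, float)
    train_idx = np.asarray(train_idx, dtype=int)
    y_train = np.asarray(y_train, dtype=float).ravel()
    Gtt = Gm[np.ix_(train_idx, train_idx)]
    rhs = np.linalg.solve(Gtt + delta * np.eye(train_idx.size), y_train - mu)
    return Gm[:, train_idx] @ rhs


def gblup_predict(fit: GblupFit, test_idx) -> np.ndarray:
    """Observed-scale predictions mu + g_hat for the indexed lines."""
    test_idx = np.asarray(test_idx, dtype=int)
    if test_idx.size and (test_idx.min() < 0 or test_idx.max() >= fit.blups.size):
        raise IndexError("unknown line index in test set")
    return fit.mu + fit.blups[test_idx]
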