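"""Outer cross-validation benchmark and metric aggregation.

The protocol is a nested 10-fold cross-validation: outer folds estimate
prediction accuracy, inner folds (within each outer training block) tune
the penalty.  Every compared method consumes identical outer folds and
identical per-fold inner seeds, so method comparisons are paired.

Metrics per outer fold, on the observed phenotype scale:

* ``Cor`` — Pearson correlation between observed and predicted test values.
* ``NRMSE`` — sqrt(mean squared error) / mean(observed).  The normalization
  by the observed mean makes errors comparable across traits with
  different scales, and is undefined for zero-mean responses.  A "plain"
  variant (MSE / mean, no square root) is exposed as a switch.

Aggregation mirrors the usual reporting layout for multi-trait,
multi-dataset benchmarks: per-trait fold means with across-fold SDs,
per-dataset means with across-trait SDs (zero for single-trait datasets),
and a grand across-dataset summary with the percent gain of the
variance-ratio grid over the conventional grid.  All SDs use the sample
(n-1) convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gblup import gblup_predict, reml_fit, vanraden_G
from .model_selection import inner_cv, make_folds, refit_full

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "pearson_cor",
    "nrmse",
    "outer_evaluate",
    "lambda_ratio_diagnostic",
    "aggregate",
]

GRID_METHODS = ("conventional", "variance_ratio")
KNOWN_METHODS = GRID_METHODS + ("gblup",)


@dataclass
class EvaluationReport:
    """Tidy per-fold benchmark results for one trait."""

    per_fold: pd.DataFrame  # columns: method, dataset, trait, fold, cor, nrmse, lambda_opt
    fold_assignment: np.ndarray
    seed: int
    dataset: str = "dataset"
    trait: str = "trait"

    def per_trait(self) -> pd.DataFrame:
        return aggregate([self])["per_trait"]


def pearson_cor(y_obs, y_pred) -> float:
    """Pearson product-moment correlation; NaN if either vector is constant."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_obs.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.std(y_obs) == 0.0 or np.std(y_pred) == 0.0:
        logger.warning("constant vector in correlation; returning NaN")
        return float("nan")
    return float(np.corrcoef(y_obs, y_pred)[0, 1])


def nrmse(y_obs, y_pred, variant: str = "sqrt") -> float:
    """Mean-normalized prediction error.

    ``variant="sqrt"`` (default): sqrt(MSE) / mean(y_obs) — a true
    normalized root mean squared error.  ``variant="plain"``: MSE /
    mean(y_obs), the un-rooted reading.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError("length mismatch")
    denom = float(y_obs.mean())
    if denom == 0.0:
        raise ValueError("NRMSE undefined for zero-mean response")
    mse = float(np.mean((y_obs - y_pred) ** 2))
    if variant == "sqrt":
        return float(np.sqrt(mse)) / denom
    if variant == "plain":
        return mse / denom
    raise ValueError(f"unknown NRMSE variant {variant!r}")


def _inner_seed(seed: int, fold: int) -> int:
    # deterministic per-fold inner seed shared by all methods; < 2**31
    return (seed * 1009 + fold * 7919 + 1) % (2**31 - 1)


def outer_evaluate(
    X,
    y,
    methods=("conventional", "variance_ratio"),
    alpha: float = 0.0,
    k_outer: int = 10,
    k_inner: int = 10,
    seed: int = 0,
    n_points: int = 100,
    nrmse_variant: str = "sqrt",
    g_mode: str = "train",
    dataset: str = "dataset",
    trait: str = "trait",
) -> EvaluationReport:
    """Run the outer-CV benchmark for the requested methods on one trait.

    ``g_mode`` controls GBLUP allele-frequency estimation: ``"train"``
    (default, leakage-controlled) centers markers with training-fold
    frequencies; ``"all"`` computes G once from every line.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    for m in methods:
        if m not in KNOWN_METHODS:
            raise ValueError(f"unknown method {m!r}")

    assignment = make_folds(n, k_outer, seed)
    G_all = vanraden_G(X) if ("gblup" in methods and g_mode == "all") else None

    rows = []
    for fold in range(k_outer):
        test = np.flatnonzero(assignment == fold)
        train = np.flatnonzero(assignment != fold)
        iseed = _inner_seed(seed, fold)
        for method in methods:
            if method == "gblup":
                preds, lam_opt = _gblup_fold(X, y, train, test, g_mode, G_all)
            else:
                cv = inner_cv(X[train], y[train], grid_method=method,
                              alpha=alpha, k=k_inner, seed=iseed,
                              n_points=n_points)
                model = refit_full(X[train], y[train], cv.lambda_opt, alpha=alpha)
                preds = model.predict(X[test])
                lam_opt = cv.lambda_opt
            obs = y[test]
            cor = pearson_cor(obs, preds) if np.std(obs) > 0 else float("nan")
            if np.isnan(cor):
                logger.warning("fold %d method %s: constant vector, Cor missing",
                               fold, method)
            err = nrmse(obs, preds, variant=nrmse_variant)
            rows.append({
                "method": method, "dataset": dataset, "trait": trait,
                "fold": fold, "cor": cor, "nrmse": err,
                "lambda_opt": lam_opt,
            })
    per_fold = pd.DataFrame(rows)
    return EvaluationReport(per_fold=per_fold, fold_assignment=assignment,
                            seed=seed, dataset=dataset, trait=trait)


def _gblup_fold(X, y, train, test, g_mode, G_all):
    if g_mode == "train":
        # center every line with training-fold allele frequencies
        p_hat = X[train].mean(axis=0) / 2.0
        het = p_hat * (1.0 - p_hat)
        poly = het > 0
        if not poly.any():
            raise ValueError("all markers monomorphic in training fold")
        c = 2.0 * float(het[poly].sum())
        Z = X - 2.0 * p_hat
        Z[:, ~poly] = 0.0
        G = (Z @ Z.T) / c
    elif g_mode == "all":
        G = G_all.matrix
    else:
        raise ValueError(f"unknown g_mode {g_mode!r}")
    fit = reml_fit(y[train], G, train_idx=train)
    return gblup_predict(fit, test), float("nan")


def lambda_ratio_diagnostic(report: EvaluationReport) -> pd.DataFrame:
    """Per-fold log(lambda_conventional / lambda_variance_ratio).

    Positive values mean the conventional glmnet path selected a stronger
    penalty than the variance-ratio grid on the same fold.
    """
    pf = report.per_fold
    present = set(pf["method"])
    if not set(GRID_METHODS) <= present:
        raise ValueError("both grid methods must be present in the report")
    wide = pf.pivot_table(index="fold", columns="method", values="lambda_opt")
    out = pd.DataFrame({
        "fold": wide.index,
        "log_ratio": np.log(wide["conventional"] / wide["variance_ratio"]).to_numpy(),
    }).reset_index(drop=True)
    out.attrs["n_positive"] = int((out["log_ratio"] > 0).sum())
    out.attrs["n_folds"] = int(len(out))
    return out


def _sd(x: pd.Series) -> float:
    # sample SD; a single observation has SD 0 by reporting convention
    return 0.0 if len(x) < 2 else float(x.std(ddof=1))


def aggregate(reports) -> dict[str, pd.DataFrame]:
    """Combine per-trait reports into per-trait / per-dataset / across tables.

    Returns a dict with keys ``per_trait`` (fold means, across-fold SD),
    ``per_dataset`` (across-trait means of fold means, across-trait SD),
    ``across_datasets`` (grand means, across-dataset SD), and ``gain``
    (percent Cor/NRMSE change of the variance-ratio grid relative to the
    conventional grid, per trait).
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    frames = [r.per_fold if isinstance(r, EvaluationReport) else r for r in reports]
    method_sets = {frozenset(f["method"]) for f in frames}
    if len(method_sets) != 1:
        raise ValueError("inconsistent method sets across reports")
    pf = pd.concat(frames, ignore_index=True)

    per_trait = (
        pf.groupby(["method", "dataset", "trait"], as_index=False)
        .agg(cor=("cor", "mean"), cor_sd=("cor", _sd),
             nrmse=("nrmse", "mean"), nrmse_sd=("nrmse", _sd))
    )
    per_dataset = (
        per_trait.groupby(["method", "dataset"], as_index=False)
        .agg(cor=("cor", "mean"), cor_sd=("cor", _sd),
             nrmse=("nrmse", "mean"), nrmse_sd=("nrmse", _sd))
    )
    across = (
        per_dataset.groupby(["method"], as_index=False)
        .agg(cor=("cor", "mean"), cor_sd=("cor", _sd),
             nrmse=("nrmse", "mean"), nrmse_sd=("nrmse", _sd))
    )

    gain = None
    if set(GRID_METHODS) <= set(pf["method"]):
        wide = per_trait.pivot_table(index=["dataset", "trait"],
                                     columns="method", values=["cor", "nrmse"])
        gain = pd.DataFrame({
            "cor_gain_pct": 100.0
            * (wide[("cor", "variance_ratio")] - wide[("cor", "conventional")])
            / wide[("cor", "conventional")],
            "nrmse_gain_pct": 100.0
            * (wide[("nrmse", "conventional")] - wide[("nrmse", "variance_ratio")])
            / wide[("nrmse", "conventional")],
        }).reset_index()

    out = {"per_trait": per_trait, "per_dataset": per_dataset,
           "across_datasets": across}
    if gain is not None:
        out["gain"] = gain
    return out
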