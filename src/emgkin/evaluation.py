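"""Scoring and experiment designs: R / NRMSE, block cross-validation,
feature-set comparison, and learning curves.

Two indices score each DOF: Pearson's correlation coefficient R (shape
agreement) and the root-mean-square error of the 0-1 normalized angles
(NRMSE; a fraction in machine-readable output, percent in summaries).
Cross-validation folds are contiguous temporal blocks because the 200 Hz
kinematic series is heavily autocorrelated and shuffled folds would leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .regression import (
    RidgeMap,
    standardize_apply,
    standardize_fit,
    subsample_fixed_interval,
    train_gp_bank,
    predict_bank,
    train_nn,
)

__all__ = [
    "EvaluationReport",
    "correlation_r",
    "nrmse",
    "block_folds",
    "five_fold_cv",
    "compare_feature_sets",
    "learning_curve",
    "make_regressor",
]


def correlation_r(actual: np.ndarray, estimated: np.ndarray) -> float:
    """Pearson correlation between an actual and an estimated series."""
    a = np.asarray(actual, dtype=float).ravel()
    b = np.asarray(estimated, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("series must have equal length >= 2")
    for name, x in (("actual", a), ("estimated", b)):
        if np.std(x) == 0:
            raise ValueError(f"{name} series has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def nrmse(actual: np.ndarray, estimated: np.ndarray) -> float:
    """Root-mean-square error of 0-1 normalized series (fraction)."""
    a = np.asarray(actual, dtype=float).ravel()
    b = np.asarray(estimated, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class EvaluationReport:
    """Per-fold, per-DOF scores plus aggregate summaries and metadata."""

    dof_labels: list[str]
    r_values: np.ndarray          # folds x DOFs
    nrmse_values: np.ndarray      # folds x DOFs (fractions)
    metadata: dict = field(default_factory=dict)
    flagged: list[tuple[int, str]] = field(default_factory=list)  # (fold, DOF)

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.r_values))

    @property
    def mean_nrmse(self) -> float:
        return float(np.nanmean(self.nrmse_values))

    def per_dof_mean_r(self) -> np.ndarray:
        return np.nanmean(self.r_values, axis=0)

    def per_dof_mean_nrmse(self) -> np.ndarray:
        return np.nanmean(self.nrmse_values, axis=0)

    def summary(self) -> dict:
        return {
            "mean_r": self.mean_r,
            "std_r": float(np.nanstd(self.r_values)),
            "mean_nrmse_percent": 100.0 * self.mean_nrmse,
            "std_nrmse_percent": 100.0 * float(np.nanstd(self.nrmse_values)),
            **self.metadata,
        }

    def to_rows(self) -> list[dict]:
        """Long-format rows: fold, DOF, metric, value."""
        rows = []
        for f in range(self.r_values.shape[0]):
            for i, lab in enumerate(self.dof_labels):
                rows.append({"fold": f, "dof": lab, "metric": "R",
                             "value": self.r_values[f, i]})
                rows.append({"fold": f, "dof": lab, "metric": "NRMSE",
                             "value": self.nrmse_values[f, i]})
        return rows


def block_folds(n_samples: int, n_folds: int = 5) -> list[np.ndarray]:
    """Partition sample indices into contiguous temporal blocks."""
    if n_samples < n_folds:
        raise ValueError("fewer samples than folds")
    edges = np.linspace(0, n_samples, n_folds + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_folds)]


def make_regressor(kind: str, seed: int = 0, **kw) -> tuple[Callable, Callable]:
    """(fit, predict) pair for 'ridge', 'nn' or 'gp' regressors.

    fit(X, Y) -> model; predict(model, X) -> Y_hat.  Keyword arguments are
    forwarded to the underlying trainer (e.g. gp_max_n, hidden_grid).
    """
    if kind == "ridge":
        lam = kw.get("ridge_lambda", 1e-3)

        def fit(X, Y):
            return RidgeMap(lam=lam).fit(X, Y)

        return fit, lambda m, X: m.predict(X)
    if kind == "nn":
        nn_kw = {k: v for k, v in kw.items()
                 if k in {"hidden_grid", "val_fraction", "max_iter", "patience"}}

        def fit(X, Y):
            return train_nn(X, Y, seed=seed, **nn_kw)

        return fit, lambda m, X: m.predict(X)
    if kind == "gp":
        max_n = kw.get("gp_max_n", 300)
        restarts = kw.get("gp_restarts", 2)

        def fit(X, Y):
            return train_gp_bank(X, Y, max_n=max_n, restarts=restarts, seed=seed)

        return fit, predict_bank
    raise ValueError(f"unknown regressor kind {kind!r}")


def _score_fold(Y_true: np.ndarray, Y_pred: np.ndarray,
                dof_labels: list[str], fold: int,
                flagged: list) -> tuple[np.ndarray, np.ndarray]:
    n_dof = Y_true.shape[1]
    r = np.full(n_dof, np.nan)
    e = np.empty(n_dof)
    for i in range(n_dof):
        e[i] = nrmse(Y_true[:, i], Y_pred[:, i])
        try:
            r[i] = correlation_r(Y_true[:, i], Y_pred[:, i])
        except ValueError:
            flagged.append((fold, dof_labels[i]))
    return r, e


def five_fold_cv(
    inputs: np.ndarray,
    targets: np.ndarray,
    dof_labels: list[str] | None = None,
    regressor: str = "gp",
    n_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
    **regressor_kw,
) -> EvaluationReport:
    """Contiguous-block k-fold cross-validation of input -> DOF regression.

    Per fold the standardization statistics and the regressor are fitted
    on the training blocks only.  DOFs with zero variance in a fold are
    flagged and excluded from the aggregate means (NaN in `r_values`).
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("inputs and targets must have the same row count")
    labels = dof_labels or [f"dof{i + 1}" for i in range(Y.shape[1])]
    folds = block_folds(X.shape[0], n_folds)
    fit, predict = make_regressor(regressor, seed=seed, **regressor_kw)
    r_all, e_all, flagged = [], [], []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
        Xtr, Xte = X[train_idx], X[test_idx]
        if standardize:
            stats = standardize_fit(Xtr)
            Xtr = standardize_apply(stats, Xtr)
            Xte = standardize_apply(stats, Xte)
        model = fit(Xtr, Y[train_idx])
        Y_pred = np.atleast_2d(predict(model, Xte))
        r, e = _score_fold(Y[test_idx], Y_pred, labels, f, flagged)
        r_all.append(r)
        e_all.append(e)
    return EvaluationReport(
        dof_labels=labels,
        r_values=np.array(r_all),
        nrmse_values=np.array(e_all),
        metadata={"regressor": regressor, "n_folds": n_folds, "seed": seed,
                  "n_samples": X.shape[0]},
        flagged=flagged,
    )


def compare_feature_sets(
    feature_sets: dict[str, np.ndarray],
    targets: np.ndarray,
    dof_labels: list[str] | None = None,
    regressor: str = "ridge",
    n_folds: int = 5,
    seed: int = 0,
    **regressor_kw,
) -> dict[str, EvaluationReport]:
    """Paired CV comparison of input representations under identical folds.

    Every feature matrix must be row-aligned to the same targets; fold
    boundaries, the regressor and the seed are shared so per-DOF
    differences between reports are paired.
    """
    n = targets.shape[0] if targets.ndim > 1 else targets.size
    for name, F in feature_sets.items():
        if np.atleast_2d(F).shape[0] != n:
            raise ValueError(f"feature set {name!r} is not row-aligned to targets")
    return {
        name: five_fold_cv(F, targets, dof_labels, regressor=regressor,
                           n_folds=n_folds, seed=seed, **regressor_kw)
        for name, F in feature_sets.items()
    }


def learning_curve(
    inputs: np.ndarray,
    targets: np.ndarray,
    sizes: list[int],
    regressors: tuple[str, ...] = ("nn", "gp"),
    test_fraction: float = 0.2,
    reps: int = 1,
    seed: int = 0,
    dof_labels: list[str] | None = None,
    **regressor_kw,
) -> list[dict]:
    """Mean test NRMSE versus training-set size for each regressor.

    The trailing `test_fraction` of the rows is a fixed held-out test
    block; the training pool is the remainder, reduced to each size by
    fixed-interval subsampling.  Returns long-format rows
    {regressor, size, rep, mean_nrmse, mean_r}.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    labels = dof_labels or [f"dof{i + 1}" for i in range(Y.shape[1])]
    split = int(X.shape[0] * (1 - test_fraction))
    X_pool, Y_pool = X[:split], Y[:split]
    X_test, Y_test = X[split:], Y[split:]
    if max(sizes) > X_pool.shape[0]:
        raise ValueError("requested size exceeds the training pool")
    rows = []
    for kind in regressors:
        for size in sizes:
            for rep in range(reps):
                rep_seed = seed + 1000 * rep
                Xs, Ys = subsample_fixed_interval(X_pool, Y_pool, size)
                stats = standardize_fit(Xs)
                fit, predict = make_regressor(kind, seed=rep_seed, **regressor_kw)
                model = fit(standardize_apply(stats, Xs), Ys)
                Y_pred = np.atleast_2d(predict(model, standardize_apply(stats, X_test)))
                flagged: list = []
                r, e = _score_fold(Y_test, Y_pred, labels, 0, flagged)
                rows.append({
                    "regressor": kind, "size": int(Xs.shape[0]), "rep": rep,
                    "mean_nrmse": float(np.mean(e)), "mean_r": float(np.nanmean(r)),
                })
    return rows
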