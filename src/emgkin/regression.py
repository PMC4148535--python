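"""Regressors mapping activation-space inputs to 15 normalized finger DOFs.

Two estimators are provided, mirroring the method comparison at the heart
of the package:

* a single multi-output feedforward neural network (one tanh hidden layer,
  linear output, hidden size selected on a validation split, early
  stopping), and
* a bank of 15 single-output exact-inference Gaussian-process regressors
  with a zero mean function, squared-exponential covariance

      k(v, v') = sigma_f^2 exp(-||v - v'||^2 / (2 l^2))

  and Gaussian observation noise sigma_n.  Hyperparameters are fitted by
  minimizing the negative log marginal likelihood

      NLL = 1/2 y^T K^-1 y + 1/2 ln|K| + N/2 ln 2pi,   K = K_f + sigma_n^2 I

  in log-space with multi-restart gradient search.  Exact inference keeps
  the dense Cholesky factorization; training cost is bounded by
  fixed-interval subsampling of the training rows.

Inputs are standardized to zero mean / unit variance on the training set;
test inputs reuse the training statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from sklearn.neural_network import MLPRegressor

__all__ = [
    "StandardizationStats",
    "standardize_fit",
    "standardize_apply",
    "subsample_fixed_interval",
    "NnModel",
    "train_nn",
    "GpModel",
    "GpBank",
    "gp_nll",
    "train_gp",
    "predict_gp",
    "train_gp_bank",
    "predict_bank",
    "RidgeMap",
]

DEFAULT_HIDDEN_GRID = (5, 10, 25, 50, 100, 200, 350)
DEFAULT_GP_CAP = 1500


# ---------------------------------------------------------------- scaling

@dataclass
class StandardizationStats:
    """Per-dimension mean/std learned on training data.

    Zero-variance dimensions are dropped (with a warning), recorded in
    `kept` so that apply() selects the same columns.
    """

    mean: np.ndarray
    std: np.ndarray
    kept: np.ndarray  # integer indices of retained input columns


def standardize_fit(train_inputs: np.ndarray) -> StandardizationStats:
    X = np.atleast_2d(np.asarray(train_inputs, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(std > 0)
    if kept.size < X.shape[1]:
        dropped = np.setdiff1d(np.arange(X.shape[1]), kept)
        warnings.warn(f"dropping zero-variance input dimension(s) {dropped.tolist()}")
    return StandardizationStats(mean=mean[kept], std=std[kept], kept=kept)


def standardize_apply(stats: StandardizationStats, inputs: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    return (X[:, stats.kept] - stats.mean) / stats.std


def subsample_fixed_interval(
    inputs: np.ndarray, targets: np.ndarray, max_n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Take every k-th row, k = ceil(N / max_n); the first row is kept.

    Preserves temporal order; identity when max_n >= N.
    """
    if max_n < 2:
        raise ValueError("max_n must be >= 2")
    N = inputs.shape[0]
    k = int(np.ceil(N / max_n))
    return inputs[::k], targets[::k]


# ---------------------------------------------------------------- ridge

@dataclass
class RidgeMap:
    """Deterministic closed-form ridge linear map (with intercept).

    Used as the fast inner estimator during activation-parameter fitting
    and as a cheap regressor for paired feature-set comparisons.
    """

    lam: float = 1e-3
    W: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RidgeMap":
        X = np.atleast_2d(X)
        Y = np.atleast_2d(Y)
        self.x_mean = X.mean(axis=0)
        self.y_mean = Y.mean(axis=0)
        Xc = X - self.x_mean
        G = Xc.T @ Xc + self.lam * np.eye(X.shape[1])
        self.W = np.linalg.solve(G, Xc.T @ (Y - self.y_mean))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.x_mean) @ self.W + self.y_mean


# ---------------------------------------------------------------- neural net

@dataclass
class NnModel:
    """Trained multi-output feedforward network plus selection metadata."""

    estimator: MLPRegressor
    hidden_size: int
    seed: int
    val_mse: float
    grid_val_mse: dict[int, float] = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(self.estimator.predict(X))


def train_nn(
    inputs: np.ndarray,
    targets: np.ndarray,
    hidden_grid: tuple[int, ...] = DEFAULT_HIDDEN_GRID,
    val_fraction: float = 0.2,
    seed: int = 0,
    max_iter: int = 2000,
    patience: int = 25,
) -> NnModel:
    """Grid-search the hidden-layer size; pick the smallest validation MSE.

    The validation split is the trailing `val_fraction` of the rows
    (temporal hold-out).  Each candidate trains with early stopping on its
    own internal validation fraction; training is deterministic given the
    seed.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    split = int(X.shape[0] * (1 - val_fraction))
    Xtr, Ytr = X[:split], Y[:split]
    Xva, Yva = X[split:], Y[split:]
    best: NnModel | None = None
    grid_mse: dict[int, float] = {}
    for h in hidden_grid:
        est = MLPRegressor(
            hidden_layer_sizes=(h,),
            activation="tanh",
            solver="adam",
            learning_rate_init=5e-3,
            max_iter=max_iter,
            early_stopping=True,
            n_iter_no_change=patience,
            tol=1e-6,
            validation_fraction=0.2,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xtr, Ytr)
        pred = np.atleast_2d(est.predict(Xva))
        mse = float(np.mean((pred - Yva) ** 2))
        if not np.isfinite(mse):
            raise RuntimeError(f"non-finite validation loss at hidden size {h}")
        grid_mse[h] = mse
        if best is None or mse < best.val_mse:
            best = NnModel(est, h, seed, mse)
    best.grid_val_mse = grid_mse
    return best


# ---------------------------------------------------------------- gaussian process

def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    a2 = np.sum(A**2, axis=1)[:, None]
    b2 = np.sum(B**2, axis=1)[None, :]
    return np.maximum(a2 + b2 - 2.0 * A @ B.T, 0.0)


def se_kernel(A: np.ndarray, B: np.ndarray, sigma_f: float, length: float) -> np.ndarray:
    """Squared-exponential covariance with one isotropic length-scale."""
    return sigma_f**2 * np.exp(-_sq_dists(A, B) / (2.0 * length**2))


def _chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    n = K.shape[0]
    base = np.trace(K) / n
    try:
        return linalg.cholesky(K, lower=True), 0.0
    except linalg.LinAlgError:
        pass
    jitter = 1e-10 * base
    while jitter <= 1e-4 * base:
        try:
            return linalg.cholesky(K + jitter * np.eye(n), lower=True), jitter
        except linalg.LinAlgError:
            jitter *= 10
    raise linalg.LinAlgError("kernel matrix not positive definite after jitter escalation")


@dataclass
class GpModel:
    """Exact-inference GP for one DOF.

    Stores the hyperparameters, retained training rows and the Cholesky
    factor of K + sigma_n^2 I for prediction.
    """

    sigma_f: float
    sigma_n: float
    length: float
    X: np.ndarray
    y: np.ndarray
    L: np.ndarray | None = None
    alpha: np.ndarray | None = None
    nll: float = np.nan

    def __post_init__(self) -> None:
        if min(self.sigma_f, self.sigma_n, self.length) <= 0:
            raise ValueError("GP hyperparameters must be positive")
        if self.L is None:
            K = se_kernel(self.X, self.X, self.sigma_f, self.length)
            K[np.diag_indices_from(K)] += self.sigma_n**2
            self.L, _ = _chol_with_jitter(K)
            self.alpha = linalg.cho_solve((self.L, True), self.y)


def gp_nll(
    hyperparams: tuple[float, float, float],
    inputs: np.ndarray,
    target: np.ndarray,
) -> float:
    """Negative log marginal likelihood of (sigma_f, sigma_n, length)."""
    sigma_f, sigma_n, length = hyperparams
    if min(sigma_f, sigma_n, length) <= 0:
        raise ValueError("hyperparameters must be positive")
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(target, dtype=float).ravel()
    n = X.shape[0]
    K = se_kernel(X, X, sigma_f, length)
    K[np.diag_indices_from(K)] += sigma_n**2
    L, _ = _chol_with_jitter(K)
    a = linalg.cho_solve((L, True), y)
    return float(
        0.5 * y @ a + np.sum(np.log(np.diag(L))) + 0.5 * n * np.log(2 * np.pi)
    )


def _nll_and_grad(log_h: np.ndarray, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    # gradient of the NLL w.r.t. log(sigma_f), log(sigma_n), log(l)
    sigma_f, sigma_n, length = np.exp(log_h)
    n = X.shape[0]
    D2 = _sq_dists(X, X)
    Kf = sigma_f**2 * np.exp(-D2 / (2 * length**2))
    K = Kf + sigma_n**2 * np.eye(n)
    L, _ = _chol_with_jitter(K)
    a = linalg.cho_solve((L, True), y)
    nll = 0.5 * y @ a + np.sum(np.log(np.diag(L))) + 0.5 * n * np.log(2 * np.pi)
    Kinv = linalg.cho_solve((L, True), np.eye(n))
    M = np.outer(a, a) - Kinv  # dNLL/dK = -1/2 M
    g_f = -0.5 * np.sum(M * (2.0 * Kf))
    g_n = -0.5 * np.sum(np.diag(M)) * 2.0 * sigma_n**2
    g_l = -0.5 * np.sum(M * (Kf * D2 / length**2))
    return float(nll), np.array([g_f, g_n, g_l])


def train_gp(
    inputs: np.ndarray,
    target: np.ndarray,
    init_hyperparams: tuple[float, float, float] | None = None,
    restarts: int = 3,
    seed: int = 0,
) -> GpModel:
    """Fit GP hyperparameters by multi-restart L-BFGS-B in log-space.

    Default initial values: sigma_f = target std, sigma_n = 0.1 * target
    std, length = median pairwise input distance; restarts perturb the
    initial log-values.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(target, dtype=float).ravel()
    if init_hyperparams is None:
        s = float(np.std(y))
        s = s if s > 0 else 1.0
        sub = X[:: max(1, X.shape[0] // 200)]
        med = float(np.median(np.sqrt(_sq_dists(sub, sub)[np.triu_indices(sub.shape[0], 1)])))
        med = med if med > 0 else 1.0
        init_hyperparams = (s, 0.1 * s, med)
    log0 = np.log(np.asarray(init_hyperparams, dtype=float))
    rng = np.random.default_rng(seed)
    bounds = [(np.log(1e-6), np.log(1e6))] * 3
    best = None
    failures = []
    for r in range(restarts):
        x0 = log0 if r == 0 else log0 + rng.normal(0, 0.5, 3)
        try:
            res = optimize.minimize(
                _nll_and_grad, x0, args=(X, y), jac=True,
                method="L-BFGS-B", bounds=bounds,
            )
        except linalg.LinAlgError as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all GP restarts failed: {failures}")
    sigma_f, sigma_n, length = np.exp(best.x)
    model = GpModel(sigma_f, sigma_n, length, X, y)
    model.nll = float(best.fun)
    return model


def predict_gp(model: GpModel, new_inputs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at new inputs.

    mean = k*^T (K + sigma_n^2 I)^-1 y; variance includes the noise term.
    """
    Xs = np.atleast_2d(np.asarray(new_inputs, dtype=float))
    if Xs.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"input dimension {Xs.shape[1]} != training dimension {model.X.shape[1]}"
        )
    Ks = se_kernel(Xs, model.X, model.sigma_f, model.length)
    mean = Ks @ model.alpha
    V = linalg.solve_triangular(model.L, Ks.T, lower=True)
    variance = model.sigma_f**2 + model.sigma_n**2 - np.sum(V**2, axis=0)
    return mean, np.maximum(variance, 0.0)


@dataclass
class GpBank:
    """One independently trained GP per DOF, in DOF-label order."""

    models: list[GpModel]
    dof_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.models) != len(self.dof_labels):
            raise ValueError("one model per DOF label required")


def train_gp_bank(
    inputs: np.ndarray,
    targets: np.ndarray,
    dof_labels: list[str] | None = None,
    max_n: int = DEFAULT_GP_CAP,
    restarts: int = 3,
    seed: int = 0,
) -> GpBank:
    """Train one GP per target column on fixed-interval-subsampled rows."""
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    labels = dof_labels or [f"dof{i + 1}" for i in range(Y.shape[1])]
    Xs, Ys = subsample_fixed_interval(np.atleast_2d(inputs), Y, max_n)
    models = []
    for i, lab in enumerate(labels):
        try:
            models.append(train_gp(Xs, Ys[:, i], restarts=restarts, seed=seed + i))
        except Exception as exc:
            raise RuntimeError(f"GP training failed for DOF {lab}: {exc}") from exc
    return GpBank(models, labels)


def predict_bank(bank: GpBank, inputs: np.ndarray) -> np.ndarray:
    """Stack the 15 posterior means: rows x len(bank.models)."""
    return np.column_stack([predict_gp(m, inputs)[0] for m in bank.models])
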