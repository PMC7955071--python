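"""Neighborhood component analysis feature selection (diagonal NCFS).

Learns a nonnegative weight per feature by maximizing the expected
leave-one-out accuracy of a stochastic nearest-neighbor rule under the
weighted L1 metric

    D_w(x_i, x_j) = sum_l w_l^2 |x_il - x_jl|,

with reference-point probabilities p_ij = softmax_j(-D_w(x_i, x_j))
(self excluded) and objective

    xi(w) = sum_i sum_{j != i, y_j = y_i} p_ij  -  lambda * sum_l w_l^2.

The regularizer lambda is tuned on a grid of equally spaced values in
[0, 15/n_train] by stratified inner cross-validation, scoring the 0/1 loss
of a 1-NN rule in the learned metric.  Features are then kept when their
weight reaches the relative threshold T = tau * max(w) with tau = 0.02.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "NCAConfig",
    "SelectionResult",
    "nca_weights",
    "tune_lambda",
    "select_features",
    "fit_select",
]


@dataclass(frozen=True)
class NCAConfig:
    """Tuning configuration for NCA feature selection."""

    n_lambda: int = 16  # grid size over [0, 15/n_train]
    inner_folds: int = 5
    tau: float = 0.02  # relative threshold multiplier
    standardize: bool = True
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _encode_labels(y: np.ndarray) -> np.ndarray:
    _, codes = np.unique(np.asarray(y).astype(str), return_inverse=True)
    return codes


def nca_weights(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 0.0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> np.ndarray:
    """Fit per-feature NCA weights by gradient-based ascent from w = 1.

    ``X`` is expected to be standardized.  Returns ``|w|`` at the local
    optimum found (weights enter the metric squared, so the sign is
    irrelevant).
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    codes = _encode_labels(y)
    if len(np.unique(codes)) < 2:
        raise ValueError("need at least two classes")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    n, d = X.shape
    # pairwise per-feature absolute differences, (n, n, d)
    diffs = np.abs(X[:, None, :] - X[None, :, :])
    same = (codes[:, None] == codes[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    def neg_obj_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        w2 = w * w
        D = diffs @ w2  # (n, n)
        A = -D
        np.fill_diagonal(A, -np.inf)
        A -= A.max(axis=1, keepdims=True)
        P = np.exp(A)
        P /= P.sum(axis=1, keepdims=True)
        p_i = (P * same).sum(axis=1)
        obj = p_i.sum() - lam * w2.sum()
        # per-row expected distance in each feature, then the NCFS gradient
        M = np.einsum("ij,ijl->il", P, diffs)
        term1 = p_i @ M
        term2 = np.einsum("ij,ijl->l", P * same, diffs)
        grad = 2.0 * w * (term1 - term2) - 2.0 * lam * w
        return -obj, -grad

    res = minimize(
        neg_obj_grad,
        x0=np.ones(d),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    return np.abs(res.x)


def _weighted_1nn_loss(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, y_test: np.ndarray,
    w: np.ndarray,
) -> float:
    """0/1 loss of a 1-NN rule under the learned weighted L1 metric."""
    w2 = w * w
    if not np.any(w2 > 0):
        # metric collapsed: every point equidistant, predict majority class
        vals, counts = np.unique(y_train, return_counts=True)
        pred = np.full(len(y_test), vals[np.argmax(counts)])
        return float(np.mean(pred != y_test))
    dist = cdist(X_test, X_train, metric="minkowski", p=1, w=w2)
    nn = np.argmin(dist, axis=1)
    return float(np.mean(y_train[nn] != y_test))


def tune_lambda(
    X: np.ndarray, y: np.ndarray, config: NCAConfig = NCAConfig()
) -> tuple[float, list[tuple[float, float]]]:
    """Pick the regularizer by stratified inner cross-validation.

    The grid is ``n_lambda`` equally spaced points spanning
    [0, 15/n_train].  Mean held-out 1-NN loss is computed per grid point;
    the argmin wins, ties broken toward the larger (sparser) lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    n = len(y)
    grid = np.linspace(0.0, 15.0 / n, config.n_lambda)
    skf = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=config.seed
    )
    folds = list(skf.split(X, y))
    losses = np.zeros((config.n_lambda, config.inner_folds))
    for fi, (tr, te) in enumerate(folds):
        mu, sd = _standardizer(X[tr]) if config.standardize else (0.0, 1.0)
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        for li, lam in enumerate(grid):
            w = nca_weights(Xtr, y[tr], lam, config.max_iter, config.tol)
            losses[li, fi] = _weighted_1nn_loss(Xtr, y[tr], Xte, y[te], w)
    mean_loss = losses.mean(axis=1)
    best = np.max(np.flatnonzero(mean_loss == mean_loss.min()))  # ties -> larger lam
    curve = list(zip(grid.tolist(), mean_loss.tolist()))
    return float(grid[best]), curve


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


@dataclass
class SelectionResult:
    """Learned weights, tuned lambda and the thresholded feature set."""

    weights: np.ndarray
    best_lambda: float
    best_loss: float
    loss_curve: list[tuple[float, float]]
    threshold_T: float
    selected: list[int]  # 0-based column indices, ascending
    tau: float
    column_names: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["weights"] = self.weights.tolist()
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        payload = json.loads(Path(path).read_text())
        payload["weights"] = np.asarray(payload["weights"], dtype=float)
        payload["loss_curve"] = [tuple(p) for p in payload["loss_curve"]]
        return cls(**payload)


def select_features(
    weights: np.ndarray,
    tau: float = 0.02,
    best_lambda: float = float("nan"),
    best_loss: float = float("nan"),
    loss_curve: list[tuple[float, float]] | None = None,
    column_names: list[str] | None = None,
) -> SelectionResult:
    """Threshold weights at T = tau * max(w); keep features with w >= T."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    wmax = weights.max() if weights.size else 0.0
    if wmax == 0.0:
        raise ValueError("all feature weights are zero (lambda too large?)")
    T = tau * wmax
    selected = np.flatnonzero(weights >= T).tolist()
    return SelectionResult(
        weights=weights,
        best_lambda=best_lambda,
        best_loss=best_loss,
        loss_curve=loss_curve or [],
        threshold_T=float(T),
        selected=selected,
        tau=tau,
        column_names=column_names or [],
    )


def fit_select(
    X: np.ndarray,
    y: np.ndarray,
    config: NCAConfig = NCAConfig(),
    column_names: list[str] | None = None,
) -> SelectionResult:
    """Full selection: tune lambda, refit weights on all rows, threshold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    best_lambda, curve = tune_lambda(X, y, config)
    best_loss = min(l for _, l in curve)
    if config.standardize:
        mu, sd = _standardizer(X)
        Xs = (X - mu) / sd
    else:
        Xs = X
    w = nca_weights(Xs, y, best_lambda, config.max_iter, config.tol)
    return select_features(
        w, config.tau, best_lambda, best_loss, curve, column_names
    )


def plot_weights(result: SelectionResult, ax=None):
    """Bar plot of per-feature weights with the threshold line (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    idx = np.arange(1, len(result.weights) + 1)
    ax.bar(idx, result.weights, color="steelblue")
    ax.axhline(result.threshold_T, color="crimson", ls="--",
               label=f"T = {result.threshold_T:.4f}")
    ax.set_xlabel("feature index")
    ax.set_ylabel("NCA weight")
    ax.legend()
    return ax
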