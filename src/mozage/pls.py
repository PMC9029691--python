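"""PLS1 regression by NIPALS for age-from-spectra calibration.

The classical single-response NIPALS recursion: each factor's weight vector
is the (normalised) covariance direction X'y, scores t = Xw, loadings
p = X't/t't, q = y't/t't, with rank-one deflation of X and y between factors.
The equivalent regression coefficients are b = W (P'W)^-1 q on centred data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import PreprocessConfig

__all__ = [
    "PLSModel",
    "SplitPlan",
    "split_calibration_test",
    "fit_pls1",
    "predict_pls",
    "select_n_factors",
    "save_model_json",
    "load_model_json",
]


@dataclass
class PLSModel:
    """A fitted PLS1 model (factor form plus derived coefficient vector)."""

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # p' x A
    x_loadings: np.ndarray   # p' x A
    y_loadings: np.ndarray   # A
    coefficients: np.ndarray  # p'
    preprocess: PreprocessConfig | None = None
    training_grid: np.ndarray | None = None
    seed: int | None = None

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coefficients)


@dataclass(frozen=True)
class SplitPlan:
    """A reproducible calibration/test partition of sample ids."""

    calibration_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        cal, test = set(self.calibration_ids), set(self.test_ids)
        if cal & test:
            raise ValueError("calibration and test ids overlap")


def split_calibration_test(
    ids: Sequence[str], fraction: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Uniform random calibration/test split without replacement.

    The calibration set receives floor(fraction * n) samples; both sets must
    be non-empty.
    """
    ids = list(ids)
    n = len(ids)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_cal = int(np.floor(fraction * n))
    if n_cal == 0 or n_cal == n:
        raise ValueError("fraction leaves an empty calibration or test set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = tuple(ids[i] for i in sorted(perm[:n_cal]))
    test = tuple(ids[i] for i in sorted(perm[n_cal:]))
    return SplitPlan(cal, test, fraction, seed)


def fit_pls1(X: np.ndarray, y: np.ndarray, n_factors: int) -> PLSModel:
    """Fit PLS1 by NIPALS with the requested number of latent factors.

    Stops early (with a warning) if a deflated X'y weight vector has zero
    norm, i.e. the residual response is orthogonal to the residual spectra.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y sizes disagree")
    if n_factors < 1 or n_factors > min(n - 1, p):
        raise ValueError(f"n_factors must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise ValueError("y is constant")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    A = 0
    for a in range(n_factors):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12 * max(1.0, np.abs(Xd).max() * np.abs(yd).max()):
            warnings.warn(
                f"NIPALS stopped after {a} factors: residual y orthogonal to X", stacklevel=2
            )
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        p_a = Xd.T @ t / tt
        q_a = yd @ t / tt
        Xd -= np.outer(t, p_a)
        yd -= q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        A += 1
    if A == 0:
        raise ValueError("no PLS factor could be extracted (y orthogonal to X)")
    W, P, q = W[:, :A], P[:, :A], q[:A]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_factors=A,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
    )


def predict_pls(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses: intercept + X_new @ b."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X has {X_new.shape[1]} columns; model was trained on {model.x_mean.size}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.coefficients


def predict_pls_scores(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Prediction via the sequential factor-score path (internal equivalence
    check against the coefficient path)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Xd = X_new - model.x_mean
    yhat = np.full(X_new.shape[0], model.y_mean)
    for a in range(model.n_factors):
        t = Xd @ model.weights[:, a]
        yhat += model.y_loadings[a] * t
        Xd = Xd - np.outer(t, model.x_loadings[:, a])
    return yhat


def cv_rmsep(
    X: np.ndarray, y: np.ndarray, max_factors: int, k_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """k-fold cross-validated RMSEP for factor counts 1..max_factors.

    One NIPALS fit at max_factors per fold; predictions at every smaller
    factor count fall out of the sequential score path for free.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % k_folds
    press = np.zeros(max_factors)
    for k in range(k_folds):
        test = fold == k
        model = fit_pls1(X[~test], y[~test], max_factors)
        Xd = X[test] - model.x_mean
        yhat = np.full(test.sum(), model.y_mean)
        for a in range(model.n_factors):
            t = Xd @ model.weights[:, a]
            yhat = yhat + model.y_loadings[a] * t
            Xd = Xd - np.outer(t, model.x_loadings[:, a])
            press[a] += np.sum((y[test] - yhat) ** 2)
        # early NIPALS stop: later factor counts inherit the last prediction
        for a in range(model.n_factors, max_factors):
            press[a] += np.sum((y[test] - yhat) ** 2)
    return np.sqrt(press / n)


def select_n_factors(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    k_folds: int = 10,
    seed: int = 0,
    parsimony: float = 1.02,
) -> int:
    """Choose the factor count by k-fold CV with a parsimony band.

    Returns the smallest A whose cross-validated RMSEP is within
    ``parsimony`` (default 2%) of the minimum over 1..max_factors.
    """
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    n = np.asarray(y).size
    limit = min(n - int(np.ceil(n / k_folds)) - 1, np.asarray(X).shape[1])
    if max_factors > limit:
        raise ValueError(f"max_factors {max_factors} exceeds CV-feasible limit {limit}")
    rmsep = cv_rmsep(X, y, max_factors, k_folds=k_folds, seed=seed)
    best = rmsep.min()
    return int(np.argmax(rmsep <= parsimony * best) + 1)


def save_model_json(model: PLSModel, path) -> None:
    d = {
        "n_factors": model.n_factors,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coefficients": model.coefficients.tolist(),
        "preprocess": None if model.preprocess is None else model.preprocess.to_dict(),
        "training_grid": None if model.training_grid is None else model.training_grid.tolist(),
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(d))


def load_model_json(path) -> PLSModel:
    d = json.loads(Path(path).read_text())
    return PLSModel(
        n_factors=d["n_factors"],
        x_mean=np.asarray(d["x_mean"], dtype=float),
        y_mean=float(d["y_mean"]),
        weights=np.asarray(d["weights"], dtype=float),
        x_loadings=np.asarray(d["x_loadings"], dtype=float),
        y_loadings=np.asarray(d["y_loadings"], dtype=float),
        coefficients=np.asarray(d["coefficients"], dtype=float),
        preprocess=None if d["preprocess"] is None else PreprocessConfig.from_dict(d["preprocess"]),
        training_grid=None if d["training_grid"] is None else np.asarray(d["training_grid"], dtype=float),
        seed=d.get("seed"),
    )
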