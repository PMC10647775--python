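"""The five growth predictors: stepwise MRA, LASSO, RBFN, MLP and GBDT.

Every fitter consumes a :class:`~cephgrowth.datasets.SupervisedDataset`
(features = measurement items over the input age window, targets = the
same items at the target age) and returns a fitted-model object whose
``predict`` works in natural units (mm / degrees): any standardization is
applied and inverted internally. All fits are deterministic given
(data, configuration, seed), and every model serializes to JSON text with
bit-identical predictions after a save/load round trip.

Conventions
-----------
* MRA: forward-backward stepwise selection scored by adjusted R²; the
  final model is ordinary least squares on the selected features. Ties
  break to the first feature in schema order; candidate steps that would
  make the regression underdetermined are skipped.
* LASSO: sklearn coordinate descent, objective (1/(2n))·RSS + λ‖A‖₁ with
  unpenalized intercept on z-scored features; λ picked by inner-CV mean
  squared prediction error; coefficients reported on the original scale.
* RBFN: Gaussian basis functions centred on fuzzy c-means centroids with
  one shared width σ; output weights (no bias — the model is a pure
  linear combination of the bases) trained by full-batch momentum SGD
  (lr 1e-4, momentum 0.9); (M, σ) selected by seeded random search over
  M ∈ [2, 20], σ ∈ [0.1, 10] scored on a held-out validation split.
* MLP: two 64-unit ReLU hidden layers, linear output, full-batch momentum
  SGD (lr 0.01, momentum 0.9) on MSE, Glorot-uniform init from the seed.
* GBDT: LightGBM regression per target, single-threaded and seeded;
  hyperparameters picked by seeded random search with early stopping on a
  validation split.

RBFN and MLP fit all requested targets jointly (their output layers are
written multi-output); MRA, LASSO and GBDT fit one model per target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .datasets import SupervisedDataset
from .errors import ConfigurationError, DataError, NumericalError

__all__ = [
    "LinearFit",
    "RBFNFit",
    "MLPFit",
    "GBDTFit",
    "fit_mra_stepwise",
    "fit_lasso",
    "fit_rbfn",
    "fit_mlp",
    "fit_gbdt",
    "predict",
    "default_lambda_grid",
    "save_model",
    "load_model",
]

_ZERO_TOL = 1e-10  # |standardized coefficient| below this counts as excluded


def _is_constant(y: np.ndarray) -> bool:
    """Constant to numerical precision (SD below 1e-12 of the value scale)."""
    return y.std() <= 1e-12 * max(1.0, float(np.abs(y).max()))


# ---------------------------------------------------------------------------
# standardization helpers

def _column_stats(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and SDs; constant columns get SD 1 so they z-score to 0."""
    mean = A.mean(axis=0)
    sd = A.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return mean, sd


def _check_schema(model_features: Sequence[str], given: Sequence[str] | None) -> None:
    if given is None:
        return
    if list(given) != list(model_features):
        for i, (a, b) in enumerate(zip(model_features, given)):
            if a != b:
                raise DataError(f"feature schema mismatch at column {i}: model expects {a!r}, got {b!r}")
        raise DataError(
            f"feature schema mismatch: model expects {len(model_features)} columns, got {len(given)}"
        )


def _as_matrix(X: np.ndarray, p: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != p:
        raise DataError(f"X has {X.shape[1]} columns; model expects {p}")
    return X


# ---------------------------------------------------------------------------
# fitted-model containers

@dataclass
class LinearFit:
    """A linear predictor Y = A0 + Σ Ai·Xi (stepwise MRA or LASSO)."""

    method: str  # "MRA" | "LASSO"
    target: str
    feature_names: list[str]
    intercept: float
    coef: np.ndarray  # original (natural-unit) scale, full length p
    selected: list[int]  # indices of retained features
    extras: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
        _check_schema(self.feature_names, feature_names)
        X = _as_matrix(X, len(self.feature_names))
        return self.intercept + X @ self.coef

    def to_dict(self) -> dict:
        return {
            "kind": "linear",
            "method": self.method,
            "target": self.target,
            "feature_names": self.feature_names,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "selected": list(self.selected),
            "extras": _jsonable(self.extras),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearFit":
        return cls(
            method=d["method"],
            target=d["target"],
            feature_names=list(d["feature_names"]),
            intercept=float(d["intercept"]),
            coef=np.asarray(d["coef"], dtype=float),
            selected=list(d["selected"]),
            extras=d.get("extras", {}),
        )


@dataclass
class RBFNFit:
    """Radial basis function network: Yj = Σk wjk·exp(−‖X−ak‖²/(2σ²))."""

    method: str
    targets: list[str]
    feature_names: list[str]
    centroids: np.ndarray  # (M, p) in standardized feature space
    sigma: float
    weights: np.ndarray  # (M, q)
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def activations(self, X: np.ndarray) -> np.ndarray:
        Xs = (_as_matrix(X, len(self.feature_names)) - self.x_mean) / self.x_sd
        d2 = ((Xs[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.sigma**2))

    def predict(self, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
        _check_schema(self.feature_names, feature_names)
        return self.activations(X) @ self.weights * self.y_sd + self.y_mean

    def to_dict(self) -> dict:
        return {
            "kind": "rbfn",
            "method": self.method,
            "targets": self.targets,
            "feature_names": self.feature_names,
            "centroids": self.centroids.tolist(),
            "sigma": self.sigma,
            "weights": self.weights.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_sd": self.y_sd.tolist(),
            "seed": self.seed,
            "extras": _jsonable(self.extras),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFNFit":
        return cls(
            method=d["method"],
            targets=list(d["targets"]),
            feature_names=list(d["feature_names"]),
            centroids=np.asarray(d["centroids"], dtype=float),
            sigma=float(d["sigma"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=np.asarray(d["y_mean"], dtype=float),
            y_sd=np.asarray(d["y_sd"], dtype=float),
            seed=int(d.get("seed", 0)),
            extras=d.get("extras", {}),
        )


@dataclass
class MLPFit:
    """Multilayer perceptron: ReLU hidden layers, linear output."""

    method: str
    targets: list[str]
    feature_names: list[str]
    weights: list[np.ndarray]  # per layer, (fan_in, fan_out)
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def _forward_standardized(self, Xs: np.ndarray) -> np.ndarray:
        h = Xs
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.weights[-1] + self.biases[-1]

    def predict(self, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
        _check_schema(self.feature_names, feature_names)
        Xs = (_as_matrix(X, len(self.feature_names)) - self.x_mean) / self.x_sd
        return self._forward_standardized(Xs) * self.y_sd + self.y_mean

    def to_dict(self) -> dict:
        return {
            "kind": "mlp",
            "method": self.method,
            "targets": self.targets,
            "feature_names": self.feature_names,
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_sd": self.y_sd.tolist(),
            "seed": self.seed,
            "extras": _jsonable(self.extras),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPFit":
        return cls(
            method=d["method"],
            targets=list(d["targets"]),
            feature_names=list(d["feature_names"]),
            weights=[np.asarray(W, dtype=float) for W in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=np.asarray(d["y_mean"], dtype=float),
            y_sd=np.asarray(d["y_sd"], dtype=float),
            seed=int(d.get("seed", 0)),
            extras=d.get("extras", {}),
        )


@dataclass
class GBDTFit:
    """A LightGBM regression ensemble for one target."""

    method: str
    target: str
    feature_names: list[str]
    booster: object  # lightgbm.Booster
    params: dict
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
        _check_schema(self.feature_names, feature_names)
        X = _as_matrix(X, len(self.feature_names))
        return np.asarray(self.booster.predict(X))

    def to_dict(self) -> dict:
        return {
            "kind": "gbdt",
            "method": self.method,
            "target": self.target,
            "feature_names": self.feature_names,
            "model_str": self.booster.model_to_string(),
            "params": _jsonable(self.params),
            "seed": self.seed,
            "extras": _jsonable(self.extras),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GBDTFit":
        import lightgbm as lgb

        return cls(
            method=d["method"],
            target=d["target"],
            feature_names=list(d["feature_names"]),
            booster=lgb.Booster(model_str=d["model_str"]),
            params=d.get("params", {}),
            seed=int(d.get("seed", 0)),
            extras=d.get("extras", {}),
        )


_MODEL_KINDS = {"linear": LinearFit, "rbfn": RBFNFit, "mlp": MLPFit, "gbdt": GBDTFit}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path: str | Path):
    d = json.loads(Path(path).read_text())
    try:
        cls = _MODEL_KINDS[d["kind"]]
    except KeyError:
        raise DataError(f"unknown model kind {d.get('kind')!r} in {path}") from None
    return cls.from_dict(d)


def predict(model, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
    """Predict with any fitted model; validates the feature schema if given."""
    return model.predict(X, feature_names=feature_names)


# ---------------------------------------------------------------------------
# stepwise multiple regression

def _adjusted_r2(X: np.ndarray, y: np.ndarray, cols: Sequence[int]) -> float:
    """Adjusted R² of OLS of y on X[:, cols] with intercept."""
    n = len(y)
    k = len(cols)
    tss = float(((y - y.mean()) ** 2).sum())
    A = np.column_stack([np.ones(n), X[:, list(cols)]]) if k else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((y - A @ coef) ** 2).sum())
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def fit_mra_stepwise(
    data: SupervisedDataset,
    target: str,
    *,
    trace: list | None = None,
) -> LinearFit:
    """Forward-backward stepwise OLS scored by adjusted R².

    Starts from the empty model; repeatedly adds the single candidate
    feature that most improves adjusted R², then removes any selected
    feature whose removal improves it, until neither step improves. Exact
    ties break to the earliest feature in schema order. Candidate steps
    that would leave fewer than two residual degrees of freedom are
    skipped. A constant target yields the intercept-only model. If
    ``trace`` is a list, every accepted step is appended as a dict with
    the state before the step, the action and the new score.
    """
    X, y = data.X, np.asarray(data.target_column(target), dtype=float)
    n, p = X.shape
    if n < 3:
        raise DataError(f"need at least 3 training subjects, got {n}")
    if p < 1:
        raise DataError("need at least one candidate feature")

    if _is_constant(y):
        return LinearFit(
            method="MRA", target=target, feature_names=list(data.feature_names),
            intercept=float(y.mean()), coef=np.zeros(p), selected=[],
            extras={"constant_target": True},
        )

    selected: list[int] = []
    current = 0.0  # adjusted R² of the intercept-only model
    while True:
        improved = False
        # forward: best single addition, if it would remain determined
        if n - (len(selected) + 1) - 1 >= 1:
            best, best_j = current, None
            for j in range(p):
                if j in selected:
                    continue
                score = _adjusted_r2(X, y, selected + [j])
                if score > best:
                    best, best_j = score, j
            if best_j is not None:
                selected.append(best_j)
                if trace is not None:
                    trace.append(
                        {"state": selected[:-1].copy(), "action": "add",
                         "feature": best_j, "adj_r2": best}
                    )
                current = best
                improved = True
        # backward: keep removing while it improves
        while selected:
            best, best_j = current, None
            for j in selected:
                score = _adjusted_r2(X, y, [c for c in selected if c != j])
                if score > best:
                    best, best_j = score, j
            if best_j is None:
                break
            state = selected.copy()
            selected.remove(best_j)
            if trace is not None:
                trace.append(
                    {"state": state, "action": "remove", "feature": best_j, "adj_r2": best}
                )
            current = best
            improved = True
        if not improved:
            break

    coef = np.zeros(p)
    if selected:
        A = np.column_stack([np.ones(n), X[:, selected]])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        intercept = float(sol[0])
        coef[selected] = sol[1:]
    else:
        intercept = float(y.mean())
    return LinearFit(
        method="MRA", target=target, feature_names=list(data.feature_names),
        intercept=intercept, coef=coef, selected=sorted(selected),
        extras={"adj_r2": current},
    )


# ---------------------------------------------------------------------------
# LASSO

def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, *, n_lambdas: int = 16, eps: float = 1e-5
) -> np.ndarray:
    """Log-spaced grid from λ_max (all-zero solution) down to eps·λ_max.

    λ_max = max|Xs'(y − ȳ)|/n on z-scored features — the smallest λ for
    which every coefficient is zero under the (1/(2n))·RSS + λ‖A‖₁
    objective.
    """
    mean, sd = _column_stats(X)
    Xs = (X - mean) / sd
    lam_max = float(np.abs(Xs.T @ (y - y.mean())).max() / len(y))
    if lam_max == 0.0:
        lam_max = 1.0
    return lam_max * np.logspace(0.0, math.log10(eps), n_lambdas)


def fit_lasso(
    data: SupervisedDataset,
    target: str,
    lambda_grid: Sequence[float] | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    *,
    n_lambdas: int = 16,
    eps: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> LinearFit:
    """L1-penalized least squares with λ chosen by inner cross-validation.

    Features are z-scored with training statistics (intercept unpenalized);
    the reported coefficients are mapped back to the original feature
    scale. Features whose standardized coefficient magnitude exceeds 1e-10
    form the selected set.
    """
    from sklearn.linear_model import Lasso, LassoCV
    from sklearn.model_selection import KFold

    X, y = data.X, np.asarray(data.target_column(target), dtype=float)
    n, p = X.shape
    mean, sd = _column_stats(X)

    if _is_constant(y):
        return LinearFit(
            method="LASSO", target=target, feature_names=list(data.feature_names),
            intercept=float(y.mean()), coef=np.zeros(p), selected=[],
            extras={"constant_target": True},
        )

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y, n_lambdas=n_lambdas, eps=eps)
    grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or not np.all(np.isfinite(grid)):
        raise ConfigurationError("lambda_grid must be nonempty with positive finite values")

    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    Xs = (X - mean) / sd
    # path fits at loose tolerance may stop at max_iter; the returned fit is
    # still optimal to within `tol`, which the KKT tests bound directly
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        if grid.size == 1:
            est = Lasso(alpha=float(grid[0]), tol=tol, max_iter=max_iter)
            est.fit(Xs, y)
            alpha = float(grid[0])
        else:
            inner_folds = min(inner_folds, n)
            cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
            est = LassoCV(alphas=grid, cv=cv, tol=tol, max_iter=max_iter)
            est.fit(Xs, y)
            alpha = float(est.alpha_)

    coef_std = np.asarray(est.coef_, dtype=float)
    selected = [int(j) for j in np.flatnonzero(np.abs(coef_std) > _ZERO_TOL)]
    coef = coef_std / sd
    intercept = float(est.intercept_ - (coef * mean).sum())
    return LinearFit(
        method="LASSO", target=target, feature_names=list(data.feature_names),
        intercept=intercept, coef=coef, selected=selected,
        extras={
            "lambda": alpha,
            "lambda_grid": grid.tolist(),
            "coef_std": coef_std.tolist(),
            "x_mean": mean.tolist(),
            "x_sd": sd.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# RBFN

def _fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    *,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fuzzy c-means (Bezdek updates): returns (centroids, memberships, converged).

    Memberships are initialized uniformly at random and renormalized;
    distances are floored at 1e-12 to keep the update defined when a point
    coincides with a centroid. Non-convergence within ``max_iter`` returns
    the best iterate with ``converged=False`` (callers emit a warning).
    """
    n = X.shape[0]
    U = rng.random((n, c))
    U /= U.sum(axis=1, keepdims=True)
    exponent = 2.0 / (m - 1.0)
    converged = False
    centroids = X[:c].copy()
    for _ in range(max_iter):
        Um = U**m
        centroids = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d = np.sqrt(((X[:, None, :] - centroids[None]) ** 2).sum(axis=2))
        d = np.maximum(d, 1e-12)
        inv = d ** (-exponent)
        U_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(U_new - U).max() < tol:
            U = U_new
            converged = True
            break
        U = U_new
    return centroids, U, converged


def _train_linear_sgd(
    F: np.ndarray,
    Y: np.ndarray,
    *,
    epochs: int,
    lr: float,
    momentum: float,
) -> np.ndarray:
    """Minimize mean squared error of F @ W vs Y by full-batch momentum SGD."""
    n = F.shape[0]
    W = np.zeros((F.shape[1], Y.shape[1]))
    v = np.zeros_like(W)
    for epoch in range(epochs):
        grad = (2.0 / n) * F.T @ (F @ W - Y)
        v = momentum * v - lr * grad
        W = W + v
        if not np.all(np.isfinite(W)):
            raise NumericalError(f"RBFN weight training diverged at epoch {epoch} (lr={lr})")
    return W


def fit_rbfn(
    data: SupervisedDataset,
    targets: Sequence[str] | None = None,
    search_budget: int = 20,
    seed: int = 0,
    *,
    epochs: int = 2000,
    lr: float = 1e-4,
    momentum: float = 0.9,
    n_clusters: int | None = None,
    sigma: float | None = None,
    val_fraction: float = 0.2,
    warn: Callable[[str], None] | None = None,
) -> RBFNFit:
    """Fit a Gaussian RBF network to all requested targets jointly.

    Fuzzy c-means (fuzzifier 2, tol 1e-5, ≤300 iterations) on z-scored
    features supplies the M centroids; activations use one shared width σ;
    output weights minimize the summed squared error by full-batch
    momentum SGD. If ``n_clusters``/``sigma`` are not given, (M, σ) is
    selected by ``search_budget`` seeded random-search trials over
    M ∈ [2, 20], σ ∈ [0.1, 10] (log-uniform), scored by MSE on a held-out
    fraction of the training subjects, then refit on all training data.
    """
    if search_budget < 1:
        raise ConfigurationError("search_budget must be >= 1")
    target_names = list(targets) if targets is not None else list(data.target_names)
    t_idx = [data.target_names.index(t) for t in target_names]
    X = data.X
    Y = data.Y[:, t_idx]
    n = X.shape[0]
    x_mean, x_sd = _column_stats(X)
    y_mean, y_sd = _column_stats(Y)
    Xs = (X - x_mean) / x_sd
    Ys = (Y - y_mean) / y_sd

    def _fit(Xf, Yf, M, sig, rng):
        if M > Xf.shape[0]:
            return None
        centroids, _, ok = _fuzzy_cmeans(Xf, M, rng=rng)
        if not ok and warn is not None:
            warn(f"fuzzy c-means did not converge within 300 iterations (M={M})")
        d2 = ((Xf[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        F = np.exp(-d2 / (2.0 * sig**2))
        W = _train_linear_sgd(F, Yf, epochs=epochs, lr=lr, momentum=momentum)
        return centroids, W

    if n_clusters is None or sigma is None:
        rng = np.random.default_rng([seed, 0])
        n_val = max(1, int(round(val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        best = None
        for trial in range(search_budget):
            M = int(rng.integers(2, 21))
            sig = float(10.0 ** rng.uniform(-1.0, 1.0))
            res = _fit(Xs[fit_idx], Ys[fit_idx], M, sig, np.random.default_rng([seed, 1, trial]))
            if res is None:
                continue
            centroids, W = res
            d2 = ((Xs[val_idx][:, None, :] - centroids[None]) ** 2).sum(axis=2)
            pred = np.exp(-d2 / (2.0 * sig**2)) @ W
            mse = float(((pred - Ys[val_idx]) ** 2).mean())
            if best is None or mse < best[0]:
                best = (mse, M, sig)
        if best is None:
            raise ConfigurationError("no RBFN search trial was feasible (all M exceeded n)")
        _, n_clusters, sigma = best
    if n_clusters > n:
        raise ConfigurationError(f"n_clusters={n_clusters} exceeds training size n={n}")

    centroids, W = _fit(Xs, Ys, n_clusters, sigma, np.random.default_rng([seed, 2]))
    return RBFNFit(
        method="RBFN", targets=target_names, feature_names=list(data.feature_names),
        centroids=centroids, sigma=float(sigma), weights=W,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd, seed=seed,
        extras={"n_clusters": int(n_clusters), "epochs": epochs, "lr": lr},
    )


# ---------------------------------------------------------------------------
# MLP

def _glorot_init(
    rng: np.random.Generator, sizes: Sequence[int]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def fit_mlp(
    data: SupervisedDataset,
    targets: Sequence[str] | None = None,
    epochs: int = 2000,
    seed: int = 0,
    *,
    lr: float = 0.01,
    momentum: float = 0.9,
    hidden: Sequence[int] = (64, 64),
) -> MLPFit:
    """Train a ReLU MLP (default two 64-unit hidden layers, linear output).

    Features and targets are z-scored with training statistics; training is
    full-batch momentum SGD on mean squared error. ``epochs=0`` returns the
    Glorot-initialized network untrained (useful as a randomized control).
    A non-finite loss aborts with the epoch and learning rate.
    """
    target_names = list(targets) if targets is not None else list(data.target_names)
    t_idx = [data.target_names.index(t) for t in target_names]
    X = data.X
    Y = data.Y[:, t_idx]
    n, p = X.shape
    q = Y.shape[1]
    x_mean, x_sd = _column_stats(X)
    y_mean, y_sd = _column_stats(Y)
    Xs = (X - x_mean) / x_sd
    Ys = (Y - y_mean) / y_sd

    rng = np.random.default_rng([seed, 0])
    weights, biases = _glorot_init(rng, [p, *hidden, q])
    vel_w = [np.zeros_like(W) for W in weights]
    vel_b = [np.zeros_like(b) for b in biases]

    # overflow during divergence is caught via the loss check below
    def errstate():
        return np.errstate(over="ignore", invalid="ignore")

    for epoch in range(epochs):
        # forward
        acts = [Xs]
        h = Xs
        with errstate():
            for W, b in zip(weights[:-1], biases[:-1]):
                h = np.maximum(h @ W + b, 0.0)
                acts.append(h)
            out = h @ weights[-1] + biases[-1]
            delta = 2.0 * (out - Ys) / (n * q)
            loss = float(((out - Ys) ** 2).mean())
        if not math.isfinite(loss):
            raise NumericalError(f"MLP training diverged: non-finite loss at epoch {epoch} (lr={lr})")
        # backward
        with errstate():
            grads_w, grads_b = [], []
            for layer in range(len(weights) - 1, -1, -1):
                grads_w.append(acts[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (acts[layer] > 0)
            grads_w.reverse()
            grads_b.reverse()
            for i in range(len(weights)):
                vel_w[i] = momentum * vel_w[i] - lr * grads_w[i]
                vel_b[i] = momentum * vel_b[i] - lr * grads_b[i]
                weights[i] = weights[i] + vel_w[i]
                biases[i] = biases[i] + vel_b[i]

    return MLPFit(
        method="MLP", targets=target_names, feature_names=list(data.feature_names),
        weights=weights, biases=biases,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd, seed=seed,
        extras={"epochs": epochs, "lr": lr, "momentum": momentum, "hidden": list(hidden)},
    )


# ---------------------------------------------------------------------------
# GBDT

_GBDT_FIXED = {
    "objective": "regression",
    "metric": "l2",
    "verbosity": -1,
    "num_threads": 1,
    "deterministic": True,
    "force_row_wise": True,
    "min_data_in_bin": 1,
}


def fit_gbdt(
    data: SupervisedDataset,
    target: str,
    tuner_budget: int = 20,
    seed: int = 0,
    *,
    max_rounds: int = 300,
    params: dict | None = None,
) -> GBDTFit:
    """Gradient-boosted regression trees (LightGBM) for one target.

    Unless ``params`` is given, hyperparameters (learning rate, leaves,
    depth, minimum leaf size) are chosen by ``tuner_budget`` seeded
    random-search trials, each trained with early stopping against a
    held-out 20% of the training subjects; the winner is refit on all
    training rows at its early-stopped round count. Single-threaded and
    fully seeded for reproducibility.
    """
    import lightgbm as lgb

    if tuner_budget < 1:
        raise ConfigurationError("tuner_budget must be >= 1")
    X, y = data.X, np.asarray(data.target_column(target), dtype=float)
    n = X.shape[0]

    if params is None:
        rng = np.random.default_rng([seed, 0])
        n_val = max(1, int(round(0.2 * n)))
        perm = rng.permutation(n)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        best = None
        for trial in range(tuner_budget):
            trial_params = {
                **_GBDT_FIXED,
                "seed": seed,
                "learning_rate": float(10.0 ** rng.uniform(-2.0, math.log10(0.3))),
                "num_leaves": int(rng.integers(2, 32)),
                "max_depth": int(rng.choice([-1, 2, 3, 4, 5, 6])),
                "min_child_samples": int(rng.choice([2, 5, 10, 20])),
            }
            train_set = lgb.Dataset(X[fit_idx], label=y[fit_idx], params={"min_data_in_bin": 1})
            val_set = lgb.Dataset(X[val_idx], label=y[val_idx], reference=train_set)
            booster = lgb.train(
                trial_params,
                train_set,
                num_boost_round=max_rounds,
                valid_sets=[val_set],
                callbacks=[lgb.early_stopping(30, verbose=False)],
            )
            score = booster.best_score["valid_0"]["l2"]
            rounds = booster.best_iteration or max_rounds
            if best is None or score < best[0]:
                best = (score, trial_params, rounds)
        _, params, rounds = best
    else:
        params = {**_GBDT_FIXED, "seed": seed, **params}
        rounds = params.pop("num_boost_round", max_rounds)

    booster = lgb.train(
        params, lgb.Dataset(X, label=y, params={"min_data_in_bin": 1}), num_boost_round=rounds
    )
    return GBDTFit(
        method="GBDT", target=target, feature_names=list(data.feature_names),
        booster=booster, params=dict(params), seed=seed,
        extras={"num_boost_round": rounds},
    )
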