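"""Vector-based regression block: boosted trees, an MLP, and simplex weighting.

Components train on the concatenated tabular features (fingerprint bits,
descriptors, engineered features).  Their predictions are combined with
nonnegative weights summing to one, fitted by constrained least squares on a
validation set — so the combined RMSE can never exceed the best single
component on that set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

DEFAULT_COMPONENTS = ("gbdt_a", "gbdt_b", "mlp")


@dataclass
class TabularModelSpec:
    kind: str  # gbdt_a (LightGBM) | gbdt_b (XGBoost) | mlp
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in DEFAULT_COMPONENTS:
            raise ValueError(f"unknown component kind {self.kind!r}")


@dataclass
class SimplexWeights:
    names: list[str]
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < -1e-9) or abs(self.w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be nonnegative and sum to 1")
        self.w = np.clip(self.w, 0.0, None)
        self.w = self.w / self.w.sum()

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.w.tolist()))


class _ConstantGuardRegressor(BaseEstimator, RegressorMixin):
    """Wraps an estimator; degenerate constant-label fits short-circuit to
    the constant (iterative solvers need not converge there)."""

    def __init__(self, base):
        self.base = base

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            self.constant_ = float(y[0])
            return self
        self.constant_ = None
        self.base_ = self.base.fit(X, y)
        return self

    def predict(self, X):
        if self.constant_ is not None:
            return np.full(len(X), self.constant_)
        return self.base_.predict(X)


def _build_component(spec: TabularModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.kind == "gbdt_a":
        from lightgbm import LGBMRegressor

        defaults = dict(
            n_estimators=400, learning_rate=0.05, num_leaves=63, min_child_samples=5,
            n_jobs=1, random_state=spec.seed, deterministic=True, force_row_wise=True, verbose=-1,
        )
        defaults.update(hp)
        return _ConstantGuardRegressor(LGBMRegressor(**defaults))
    if spec.kind == "gbdt_b":
        from xgboost import XGBRegressor

        defaults = dict(
            n_estimators=400, learning_rate=0.05, max_depth=6, n_jobs=1,
            random_state=spec.seed, tree_method="hist", verbosity=0,
        )
        defaults.update(hp)
        return _ConstantGuardRegressor(XGBRegressor(**defaults))
    # plain two-hidden-layer perceptron with early stopping
    defaults = dict(
        hidden_layer_sizes=(128, 64), max_iter=300, early_stopping=True,
        n_iter_no_change=15, random_state=spec.seed, learning_rate_init=1e-3,
    )
    defaults.update(hp)
    return _ConstantGuardRegressor(make_pipeline(StandardScaler(), MLPRegressor(**defaults)))


def fit_component(features, labels, spec: TabularModelSpec):
    """Train one tabular component; deterministic given spec.seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 samples")
    return _build_component(spec).fit(X, y)


def fit_simplex_weights(component_predictions, labels, names=None) -> SimplexWeights:
    """Least-squares weights on the probability simplex.

    Minimizes RMSE of the weighted combination over w >= 0, sum(w) = 1.
    Components with identical prediction vectors receive equal weight
    (uniform tie-break over the optimal set).
    """
    P = np.asarray(component_predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if P.ndim != 2:
        raise ValueError("component_predictions must be (n, k)")
    n, k = P.shape
    if n < 1 or len(y) != n:
        raise ValueError("degenerate inputs")
    if names is None:
        names = [f"c{i}" for i in range(k)]
    if k == 1:
        return SimplexWeights(list(names), np.array([1.0]))

    def obj(w):
        r = P @ w - y
        return float(r @ r) / n

    def grad(w):
        return 2.0 / n * P.T @ (P @ w - y)

    w0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        obj, w0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(k)}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    # uniform tie-break: equalize weights across identical-prediction components
    groups: dict[bytes, list[int]] = {}
    for i in range(k):
        groups.setdefault(np.round(P[:, i], 9).tobytes(), []).append(i)
    for idxs in groups.values():
        if len(idxs) > 1:
            w[idxs] = w[idxs].sum() / len(idxs)
    return SimplexWeights(list(names), w)


def predict_weighted(models, weights: SimplexWeights, features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    P = np.column_stack([m.predict(X) for m in models])
    return P @ weights.w


class TabularEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Simplex-weighted ensemble of boosted trees and an MLP.

    ``fit`` holds out a seeded validation split to fit the component weights
    (intra-category weighted ensemble); components themselves train on the
    remaining data.  With ``val_fraction=0`` the weights are fit on the
    training data itself.

    Fitted attributes: ``models_``, ``weights_`` (:class:`SimplexWeights`),
    ``component_names_``.
    """

    def __init__(self, components=DEFAULT_COMPONENTS, val_fraction: float = 0.2, seed: int = 0):
        self.components = components
        self.val_fraction = val_fraction
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        n = len(X)
        if self.val_fraction > 0 and n >= 20:
            order = rng.permutation(n)
            n_val = max(2, int(self.val_fraction * n))
            val, tr = order[:n_val], order[n_val:]
        else:
            tr = val = np.arange(n)
        self.component_names_ = list(self.components)
        self.models_ = [
            fit_component(X[tr], y[tr], TabularModelSpec(kind=c, seed=self.seed))
            for c in self.component_names_
        ]
        P_val = np.column_stack([m.predict(X[val]) for m in self.models_])
        self.weights_ = fit_simplex_weights(P_val, y[val], self.component_names_)
        return self

    def predict(self, X):
        return predict_weighted(self.models_, self.weights_, X)

    def predict_components(self, X) -> dict[str, np.ndarray]:
        X = np.asarray(X, dtype=float)
        return {n: m.predict(X) for n, m in zip(self.component_names_, self.models_)}
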