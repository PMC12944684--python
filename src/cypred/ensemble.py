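"""Test-time augmentation pooling and the hybrid graph/tabular ensemble.

Intra-model: a predictor is evaluated on the canonical SMILES plus N
randomized serializations of the same molecule and the predictions are
averaged (TTA mean pooling) — a no-op for serialization-invariant predictors
such as the graph model, useful for string-sensitive embedding models.

Inter-model: the tabular block and the graph block are combined with simplex
weights fitted on validation-set predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemio import StandardMolecule, standardize_structure, enumerate_random_smiles
from .featurize import MoleculeFeaturizer
from .graph_model import RingGNNRegressor
from .metrics import EvalReport, evaluate
from .tabular_ml import SimplexWeights, TabularEnsembleRegressor, fit_simplex_weights
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split


@dataclass
class TTAConfig:
    n_variants: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")


@dataclass
class PredictionBundle:
    molecule_key: str
    per_variant: list[tuple[str, float]] = field(default_factory=list)
    tta_mean: float = float("nan")
    per_component: dict[str, float] = field(default_factory=dict)
    final: float = float("nan")


def tta_predict(predictor, mol: StandardMolecule | str, config: TTAConfig) -> PredictionBundle:
    """Evaluate ``predictor`` on canonical + N randomized SMILES and average.

    ``predictor`` is any callable mapping a SMILES string to a number.
    """
    if not isinstance(mol, StandardMolecule):
        mol = standardize_structure(mol)
    variants = enumerate_random_smiles(mol, config.n_variants, config.seed)
    per_variant = [(s, float(predictor(s))) for s in variants]
    return PredictionBundle(
        molecule_key=mol.canonical,
        per_variant=per_variant,
        tta_mean=float(np.mean([p for _, p in per_variant])),
    )


def hybrid_predict(component_values: dict[str, float], weights: SimplexWeights) -> float:
    """Weighted combination of named component predictions."""
    if set(component_values) != set(weights.names):
        raise ValueError("component names do not match weight names")
    wd = weights.as_dict()
    return float(sum(wd[k] * v for k, v in component_values.items()))


class HybridInhibitionRegressor(BaseEstimator, RegressorMixin):
    """Hybrid of the tabular ensemble and the ring-aware graph regressor.

    With ``n_folds=1`` a seeded validation split is held out from the
    training data, both blocks train on the remainder, and the inter-model
    simplex weights are fitted on the blocks' validation predictions.  With
    ``n_folds>=2`` both blocks are trained per fold and the weights are
    fitted on out-of-fold predictions; inference averages the fold models.
    Test labels are never consulted before final evaluation.

    Fitted attributes: ``ml_models_``, ``gnn_models_``, ``weights_``,
    ``validation_rmse_`` (per block and combined, on the weight-fitting set).
    """

    def __init__(
        self,
        components=("gbdt_a", "gbdt_b", "mlp"),
        val_fraction: float = 0.2,
        n_folds: int = 1,
        tta_n: int = 0,
        gnn_params: dict | None = None,
        seed: int = 0,
    ):
        self.components = components
        self.val_fraction = val_fraction
        self.n_folds = n_folds
        self.tta_n = tta_n
        self.gnn_params = gnn_params
        self.seed = seed

    def _fit_blocks(self, s_tr, y_tr, fold_seed):
        F_tr = self.featurizer_.transform(s_tr)
        ml = TabularEnsembleRegressor(components=self.components, seed=fold_seed)
        ml.fit(F_tr, y_tr)
        gnn_kwargs = dict(self.gnn_params or {})
        gnn_kwargs.setdefault("seed", fold_seed)
        gnn = RingGNNRegressor(**gnn_kwargs)
        gnn.fit(s_tr, y_tr)
        return ml, gnn

    def fit(self, X, y):
        smiles = [x.canonical if isinstance(x, StandardMolecule) else str(x) for x in X]
        y = np.asarray(y, dtype=float)
        self.featurizer_ = MoleculeFeaturizer().fit(smiles)
        idx = np.arange(len(smiles))
        self.ml_models_, self.gnn_models_ = [], []
        if self.n_folds >= 2:
            from sklearn.model_selection import KFold

            p_ml = np.full(len(idx), np.nan)
            p_gnn = np.full(len(idx), np.nan)
            kf = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
            for fold, (tr, va) in enumerate(kf.split(idx)):
                ml, gnn = self._fit_blocks([smiles[i] for i in tr], y[tr], self.seed + fold)
                s_va = [smiles[i] for i in va]
                p_ml[va] = ml.predict(self.featurizer_.transform(s_va))
                p_gnn[va] = gnn.predict(s_va)
                self.ml_models_.append(ml)
                self.gnn_models_.append(gnn)
            y_fit = y
        else:
            tr, va = train_test_split(
                idx, test_size=max(self.val_fraction, 2 / len(idx)), random_state=self.seed
            )
            ml, gnn = self._fit_blocks([smiles[i] for i in tr], y[tr], self.seed)
            self.ml_models_.append(ml)
            self.gnn_models_.append(gnn)
            s_va = [smiles[i] for i in va]
            p_ml = ml.predict(self.featurizer_.transform(s_va))
            p_gnn = gnn.predict(s_va)
            y_fit = y[va]
        P = np.column_stack([p_ml, p_gnn])
        self.weights_ = fit_simplex_weights(P, y_fit, names=["ml", "gnn"])
        combined = P @ self.weights_.w
        self.validation_rmse_ = {
            "ml": float(np.sqrt(np.mean((p_ml - y_fit) ** 2))),
            "gnn": float(np.sqrt(np.mean((p_gnn - y_fit) ** 2))),
            "hybrid": float(np.sqrt(np.mean((combined - y_fit) ** 2))),
        }
        return self

    # backwards-convenient single-model views
    @property
    def ml_(self):
        return self.ml_models_[0]

    @property
    def gnn_(self):
        return self.gnn_models_[0]

    def _component_predictions(self, smiles: list[str]) -> tuple[np.ndarray, np.ndarray]:
        F = self.featurizer_.transform(smiles)
        p_ml = np.mean([m.predict(F) for m in self.ml_models_], axis=0)
        if self.tta_n > 0:
            cfg = TTAConfig(n_variants=self.tta_n, seed=self.seed)

            def gnn_point(s: str) -> float:
                return float(np.mean([g.predict([s])[0] for g in self.gnn_models_]))

            p_gnn = np.array([tta_predict(gnn_point, s, cfg).tta_mean for s in smiles])
        else:
            p_gnn = np.mean([g.predict(smiles) for g in self.gnn_models_], axis=0)
        return p_ml, p_gnn

    def predict(self, X) -> np.ndarray:
        smiles = [x.canonical if isinstance(x, StandardMolecule) else str(x) for x in X]
        p_ml, p_gnn = self._component_predictions(smiles)
        out = np.column_stack([p_ml, p_gnn]) @ self.weights_.w
        return np.clip(out, 0.0, 100.0)

    def predict_bundles(self, X) -> list[PredictionBundle]:
        smiles = [x.canonical if isinstance(x, StandardMolecule) else str(x) for x in X]
        p_ml, p_gnn = self._component_predictions(smiles)
        bundles = []
        for s, a, b in zip(smiles, p_ml, p_gnn):
            comp = {"ml": float(a), "gnn": float(b)}
            bundles.append(
                PredictionBundle(
                    molecule_key=standardize_structure(s).canonical,
                    per_component=comp,
                    tta_mean=float(b),
                    final=float(np.clip(hybrid_predict(comp, self.weights_), 0.0, 100.0)),
                )
            )
        return bundles


def evaluate_pipeline(
    smiles,
    labels,
    test_fraction: float = 0.2,
    seed: int = 0,
    label_range: float = 100.0,
    **hybrid_kwargs,
) -> tuple[EvalReport, list[PredictionBundle], HybridInhibitionRegressor]:
    """Train the hybrid model and evaluate on a held-out split.

    The held-out test set is carved off before any training; the hybrid's
    internal validation split (weight fitting) uses training data only.
    """
    smiles = list(smiles)
    y = np.asarray(labels, dtype=float)
    idx = np.arange(len(smiles))
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed)
    model = HybridInhibitionRegressor(seed=seed, **hybrid_kwargs)
    model.fit([smiles[i] for i in tr], y[tr])
    bundles = model.predict_bundles([smiles[i] for i in te])
    yhat = np.array([b.final for b in bundles])
    report = evaluate(y[te], yhat, label_range)
    return report, bundles, model
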