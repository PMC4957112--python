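"""Scikit-learn style estimators wrapping the full pipeline.

``fit`` standardizes the features, builds the boosted random-bit pool,
packs the training bits, and grows the bit forest; ``predict`` applies the
stored scaler, evaluates every pool network on the new rows, packs, and
averages the trees.  Everything downstream of the input data is a pure
function of ``random_state``, so refitting with the same data and seed
reproduces the model exactly.

Both estimators compose with sklearn pipelines and model selection
(``get_params``/``set_params``/``clone`` work as usual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .bitstore import pack
from .boost import BoostConfig, build_pool
from .forest import ForestConfig, fit_forest, predict_forest

__all__ = [
    "FeatureScaler",
    "RandomBitsForestClassifier",
    "RandomBitsForestRegressor",
]


@dataclass
class FeatureScaler:
    """Per-feature standardization: subtract mean, divide by sample sd.

    The sd uses the n-1 (sample) convention.  A zero-variance feature gets
    sd 1, mapping it to an all-zero column — harmless, since no hidden node
    can split on a constant.
    """

    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=np.float64)
        means = X.mean(axis=0)
        if X.shape[0] > 1:
            sds = X.std(axis=0, ddof=1)
        else:
            sds = np.zeros(X.shape[1])
        sds = np.where(sds == 0.0, 1.0, sds)
        return cls(means, sds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.means.size:
            raise ValueError(
                f"expected {self.means.size} features, got {X.shape[1]}"
            )
        return (X - self.means) / self.sds


def _default_bits_per_tree(pool_size: int) -> int:
    return math.ceil(math.sqrt(pool_size)) * 8


class _BaseRandomBitsForest(BaseEstimator):
    """Shared fitting machinery; see the concrete classifier/regressor."""

    _task: str = ""  # set by subclasses

    def __init__(
        self,
        n_chains: int = 256,
        n_steps: int = 40,
        n_candidates: int = 128,
        twist1: int = 3,
        twist2: int = 3,
        n_trees: int = 500,
        bits_per_tree: int | None = None,
        sample_fraction: float = 1.0,
        min_node_size: int | None = None,
        random_state: int | None = None,
    ):
        self.n_chains = n_chains
        self.n_steps = n_steps
        self.n_candidates = n_candidates
        self.twist1 = twist1
        self.twist2 = twist2
        self.n_trees = n_trees
        self.bits_per_tree = bits_per_tree
        self.sample_fraction = sample_fraction
        self.min_node_size = min_node_size
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _fit_common(self, X: np.ndarray, y_work: np.ndarray, y_forest: np.ndarray) -> None:
        seed = 0 if self.random_state is None else int(self.random_state)
        boost_seed, forest_seed = np.random.SeedSequence(seed).generate_state(2)

        self.scaler_ = FeatureScaler.fit(X)
        X_std = self.scaler_.transform(X)

        boost_cfg = BoostConfig(
            B=self.n_chains,
            S=self.n_steps,
            C=self.n_candidates,
            twist1=self.twist1,
            twist2=self.twist2,
            seed=int(boost_seed),
        )
        self.pool_, self.train_bits_, self.chain_sse_ = build_pool(y_work, X_std, boost_cfg)
        self.boost_config_ = boost_cfg

        pool_size = boost_cfg.pool_size
        bpt = self.bits_per_tree
        if bpt is None:
            bpt = _default_bits_per_tree(pool_size)
        mns = self.min_node_size
        if mns is None:
            mns = 1 if self._task == "classification" else 5
        forest_cfg = ForestConfig(
            n_trees=self.n_trees,
            bits_per_tree=bpt,
            sample_fraction=self.sample_fraction,
            min_node_size=mns,
            task=self._task,
            seed=int(forest_seed),
        )
        self.forest_ = fit_forest(self.train_bits_, y_forest, forest_cfg)
        self.forest_config_ = forest_cfg

    def _raw_predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.n_features_in_}"
            )
        X_std = self.scaler_.transform(X)
        bits = pack(self.pool_.evaluate(X_std).astype(np.uint8))
        return predict_forest(self.forest_, bits)


class RandomBitsForestRegressor(RegressorMixin, _BaseRandomBitsForest):
    """Random Bits Forest regressor.

    Parameters mirror the pipeline stages: ``n_chains`` (B) boosting chains
    of ``n_steps`` (S) steps with ``n_candidates`` (C) competing networks
    per step build a pool of ``B * S`` bits; ``twist1``/``twist2`` size the
    sparse 3-layer networks; the remaining parameters configure the bit
    forest (``bits_per_tree`` defaults to ``ceil(sqrt(pool_size)) * 8`` and
    ``min_node_size`` to 5 for regression).  ``random_state=None`` is
    treated as 0 — fitting is always deterministic.
    """

    _task = "regression"

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64, y_numeric=True)
        self.n_features_in_ = X.shape[1]
        self._fit_common(X, y, y)
        return self

    def predict(self, X):
        return self._raw_predict(X)


class RandomBitsForestClassifier(ClassifierMixin, _BaseRandomBitsForest):
    """Random Bits Forest binary classifier.

    The binary target enters the boosting stage recentred to {-0.5, +0.5}
    (the selection is least-squares on a residual); class probabilities
    come from the forest by averaging leaf class-1 fractions, and
    ``predict`` thresholds the probability at 0.5 (ties go to class 1).
    Only binary targets are supported.  See
    :class:`RandomBitsForestRegressor` for the shared parameters
    (``min_node_size`` defaults to 1 for classification).
    """

    _task = "classification"

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_ = np.unique(y)
        if len(self.classes_) > 2:
            raise ValueError(
                f"only binary classification is supported; got "
                f"{len(self.classes_)} classes"
            )
        self.n_features_in_ = X.shape[1]
        y01 = (y == self.classes_[-1]).astype(np.float64)
        self._fit_common(X, y01 - 0.5, y01)
        return self

    def predict_proba(self, X):
        p1 = np.clip(self._raw_predict(X), 0.0, 1.0)
        if len(self.classes_) == 1:
            return np.ones((len(p1), 1))
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self._raw_predict(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        if proba.shape[1] == 1:
            return np.full(proba.shape[0], self.classes_[0])
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]
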