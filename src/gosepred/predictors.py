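"""Uniform predictor contract.

Every model — proportional-odds regression, random forest, neural network,
and the trivial baselines — is fitted through :func:`fit_predictor` and
exposes ``predict_proba`` returning an (n, 8) probability matrix, so all
experiments are model-agnostic.

The tree and network models are delegated to scikit-learn behind this
contract; their recorded hyperparameter defaults are one predictor sampled
per split (mtry=1), 500 trees and Gini impurity for the forest, and hidden
layers (1600, 800, 200, 100) with ReLU, softmax output, batch size 64 and
24 epochs for the network. The network backend trains with Adam (the
closest available optimizer) and expects one-hot inputs with standardized
age. Argmax ties are broken toward the lower (worse) GOSE category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from gosepred._rng import substream
from gosepred.cohort import GOSE_LEVELS, DesignMatrix
from gosepred.polr import PolrFit, polr_fit_reduced, polr_predict

__all__ = [
    "PREDICTOR_KINDS",
    "PredictorSpec",
    "FittedPredictor",
    "PredictionSet",
    "fit_predictor",
    "predict_set",
    "argmax_labels",
]

N_CATEGORIES = len(GOSE_LEVELS)

PREDICTOR_KINDS = ("polr", "random_forest", "neural_net", "majority_class", "uniform_random")

RF_DEFAULTS: dict = {
    "n_estimators": 500,
    "max_features": 1,
    "criterion": "gini",
    "min_samples_split": 2,
    "min_samples_leaf": 1,
}

NN_DEFAULTS: dict = {
    "hidden_layer_sizes": (1600, 800, 200, 100),
    "activation": "relu",
    "batch_size": 64,
    "max_iter": 24,
}


@dataclass(frozen=True)
class PredictorSpec:
    """Declarative model choice: kind + hyperparameter overrides + seed."""

    kind: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PREDICTOR_KINDS:
            raise ValueError(f"unknown predictor kind {self.kind!r}; choose from {PREDICTOR_KINDS}")


@dataclass
class FittedPredictor:
    """Fitted model exposing an (n, 8) ``predict_proba``."""

    spec: PredictorSpec
    tag: str
    _predict_proba: Callable[[np.ndarray], np.ndarray]
    fit_object: object = None
    #: optional override for point predictions (uniform_random samples its
    #: labels instead of taking a degenerate argmax over constant vectors)
    _predict_labels: Callable[[np.ndarray], np.ndarray] | None = None

    def predict_proba(self, design: DesignMatrix | np.ndarray) -> np.ndarray:
        X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        probs = self._predict_proba(X)
        return np.asarray(probs, dtype=float)

    def predict_labels(self, design: DesignMatrix | np.ndarray) -> np.ndarray:
        probs = self.predict_proba(design)
        if self._predict_labels is not None:
            X = design.X if isinstance(design, DesignMatrix) else np.asarray(design)
            return self._predict_labels(X)
        return argmax_labels(probs)


@dataclass
class PredictionSet:
    """Aligned observed labels, point predictions, and probability vectors."""

    observed: np.ndarray
    predicted: np.ndarray
    probabilities: np.ndarray
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=int)
        self.predicted = np.asarray(self.predicted, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        n = self.observed.size
        if self.predicted.size != n or self.probabilities.shape[0] != n:
            raise ValueError("observed/predicted/probabilities lengths differ")
        if n and self.probabilities.shape[1] != N_CATEGORIES:
            raise ValueError("probability vectors must have 8 components")
        if n:
            sums = self.probabilities.sum(axis=1)
            if np.any(self.probabilities < -1e-12) or np.any(np.abs(sums - 1) > 1e-9):
                raise ValueError("probability vectors must be non-negative and sum to 1")

    def __len__(self) -> int:
        return self.observed.size


def argmax_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax over categories; ties resolve to the lower (worse) GOSE."""
    return np.argmax(probs, axis=1) + 1  # np.argmax returns the first maximum


def _expand_to_8(probs: np.ndarray, classes: np.ndarray) -> np.ndarray:
    out = np.zeros((probs.shape[0], N_CATEGORIES))
    for k, c in enumerate(classes):
        out[:, int(c) - 1] = probs[:, k]
    return out


def fit_predictor(
    spec: PredictorSpec,
    design: DesignMatrix | np.ndarray,
    labels: Sequence[int],
) -> FittedPredictor:
    """Fit a model of the requested kind on an encoded design.

    polr, majority_class and uniform_random are deterministic given the
    seed; the forest is seeded through its backing implementation; network
    determinism is per the backing implementation and never relied on by
    tests.
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    hp = dict(spec.hyperparameters)

    if spec.kind == "polr":
        fit: PolrFit = polr_fit_reduced(design, y, **hp)
        return FittedPredictor(
            spec=spec,
            tag="polr",
            _predict_proba=lambda Xn, f=fit: polr_predict(f, Xn),
            fit_object=fit,
        )

    if spec.kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        params = {**RF_DEFAULTS, **hp}
        model = RandomForestClassifier(random_state=spec.seed, **params)
        model.fit(X, y)
        return FittedPredictor(
            spec=spec,
            tag="random_forest",
            _predict_proba=lambda Xn, m=model: _expand_to_8(m.predict_proba(Xn), m.classes_),
            fit_object=model,
        )

    if spec.kind == "neural_net":
        from sklearn.neural_network import MLPClassifier

        params = {**NN_DEFAULTS, **hp}
        import warnings as _warnings

        model = MLPClassifier(random_state=spec.seed, **params)
        with _warnings.catch_warnings():
            # 24 epochs is the configured budget, not a convergence failure
            _warnings.simplefilter("ignore")
            model.fit(X, y)
        return FittedPredictor(
            spec=spec,
            tag="neural_net",
            _predict_proba=lambda Xn, m=model: _expand_to_8(m.predict_proba(Xn), m.classes_),
            fit_object=model,
        )

    if spec.kind == "majority_class":
        values, counts = np.unique(y, return_counts=True)
        mode = int(values[np.argmax(counts)])  # lowest label wins ties
        vec = np.zeros(N_CATEGORIES)
        vec[mode - 1] = 1.0
        return FittedPredictor(
            spec=spec,
            tag="majority_class",
            _predict_proba=lambda Xn, v=vec: np.tile(v, (Xn.shape[0], 1)),
            fit_object=mode,
        )

    if spec.kind == "uniform_random":
        rng = substream(spec.seed, "uniform_random")

        def sample_labels(Xn: np.ndarray, rng=rng) -> np.ndarray:
            return rng.integers(1, N_CATEGORIES + 1, size=Xn.shape[0])

        return FittedPredictor(
            spec=spec,
            tag="uniform_random",
            _predict_proba=lambda Xn: np.full((Xn.shape[0], N_CATEGORIES), 1.0 / N_CATEGORIES),
            _predict_labels=sample_labels,
        )

    raise ValueError(f"unknown predictor kind {spec.kind!r}")  # pragma: no cover


def predict_set(
    model: FittedPredictor,
    design: DesignMatrix | np.ndarray,
    observed: Sequence[int],
) -> PredictionSet:
    """Score a design matrix into a :class:`PredictionSet`.

    Point predictions are the probability argmax with ties broken toward
    the lower GOSE category (the uniform-random baseline samples instead).
    """
    obs = np.asarray(observed, dtype=int)
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != obs.size:
        raise ValueError("design and observed lengths differ")
    if obs.size == 0:
        return PredictionSet(
            observed=np.empty(0, dtype=int),
            predicted=np.empty(0, dtype=int),
            probabilities=np.empty((0, N_CATEGORIES)),
            model_tag=model.tag,
        )
    probs = model.predict_proba(design)
    labels = model.predict_labels(design)
    return PredictionSet(
        observed=obs, predicted=labels, probabilities=probs, model_tag=model.tag
    )
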