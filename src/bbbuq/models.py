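"""Classical permeability classifiers: random forests and MLPs.

Four named presets pair a model family with a representation: RF(ECFP),
RF(PCP), MLP(ECFP) and MLP(PCP), each with the hyperparameters tuned for
that pairing. Descriptor inputs are z-scored inside the MLP pipeline (fit
on the training split only); random forests take raw features; fingerprint
bits enter both as 0/1 reals.

The MLP additionally exposes two things the uncertainty scorers need and
scikit-learn does not surface: stochastic forward passes with dropout active
at inference (masks applied to each hidden layer's activations, inverted
scaling) and the post-activation output of the last hidden layer ("latent"
representation). Both run through a manual forward pass over the fitted
weights; with dropout off it reproduces ``predict_proba`` exactly, which the
test suite asserts. The networks are trained without dropout (regularization
as specified); the dropout rate only shapes inference-time perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .exceptions import (
    DropoutUnsupported,
    DuplicateSeeds,
    LatentUnsupported,
    ShapeMismatch,
    SingleClassTraining,
    UnknownPreset,
)

#: labels are encoded 0 = negative (BBB-), 1 = positive (BBB+)
LABEL_TO_INT = {"negative": 0, "positive": 1}


@dataclass
class ModelSpec:
    """Model family + representation + hyperparameters + training seed."""

    family: str  # "rf" | "mlp"
    feature_kind: str  # "ecfp4" | "pcp"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    dropout_rate: float = 0.1  # mlp only; used at inference for MC-dropout


_PRESETS: dict[str, ModelSpec] = {
    "rf_ecfp": ModelSpec(
        family="rf",
        feature_kind="ecfp4",
        hyperparameters={"n_estimators": 100, "max_depth": 50, "criterion": "entropy"},
    ),
    "rf_pcp": ModelSpec(
        family="rf",
        feature_kind="pcp",
        hyperparameters={"n_estimators": 250, "max_depth": 20, "criterion": "gini"},
    ),
    "mlp_ecfp": ModelSpec(
        family="mlp",
        feature_kind="ecfp4",
        hyperparameters={
            "hidden_layer_sizes": (1000, 500),
            "max_iter": 3000,
            "batch_size": 64,
            "learning_rate_init": 0.0001,
        },
    ),
    "mlp_pcp": ModelSpec(
        family="mlp",
        feature_kind="pcp",
        hyperparameters={
            "hidden_layer_sizes": (1500, 1000, 500),
            "max_iter": 1000,
            "batch_size": 16,
            "learning_rate_init": 0.0001,
        },
    ),
}


def make_preset(name: str, **overrides) -> ModelSpec:
    """Return a copy of a named preset, optionally overriding fields.

    Hyperparameter overrides (e.g. scaled-down hidden sizes for small
    studies) are merged into the preset's map.
    """
    if name not in _PRESETS:
        raise UnknownPreset(f"{name!r}; known: {sorted(_PRESETS)}")
    spec = _PRESETS[name]
    hp = dict(spec.hyperparameters)
    hp.update(overrides.pop("hyperparameters", {}))
    return replace(spec, hyperparameters=hp, **overrides)


@dataclass
class PredictionSet:
    """Class-probability pairs and the derived hard labels for one batch."""

    probabilities: np.ndarray  # (n, 2): columns (p_negative, p_positive)
    model_id: str
    seed: int

    @property
    def p_positive(self) -> np.ndarray:
        return self.probabilities[:, 1]

    @property
    def hard_labels(self) -> np.ndarray:
        """1 (positive) iff p_positive >= 0.5."""
        return (self.probabilities[:, 1] >= 0.5).astype(int)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything the uncertainty scorers need."""

    spec: ModelSpec
    estimator: object
    scaler: StandardScaler | None
    train_features: np.ndarray  # kept by reference for distance-based scores

    @property
    def supports_dropout_inference(self) -> bool:
        return self.spec.family == "mlp"

    @property
    def supports_latent(self) -> bool:
        return self.spec.family == "mlp"

    @property
    def model_id(self) -> str:
        return f"{self.spec.family}_{self.spec.feature_kind}_seed{self.spec.seed}"


def _as_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        arr = np.array([LABEL_TO_INT[str(v)] for v in arr])
    return arr.astype(int)


def train_classifier(spec: ModelSpec, features, labels, seed: int | None = None) -> TrainedModel:
    """Fit one classifier; deterministic given (spec, data, seed).

    Training features are retained by reference so distance-based
    applicability-domain scores can be computed later without re-supplying
    the training set.
    """
    X = np.asarray(features, dtype=np.float64)
    y = _as_labels(labels)
    if X.shape[0] != y.shape[0]:
        raise ShapeMismatch(f"{X.shape[0]} feature rows vs {y.shape[0]} labels")
    if np.unique(y).size < 2:
        raise SingleClassTraining("training labels contain a single class")
    if seed is None:
        seed = spec.seed
    spec = replace(spec, seed=seed)
    scaler = None
    if spec.family == "rf":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **spec.hyperparameters)
        est.fit(X, y)
    elif spec.family == "mlp":
        if spec.feature_kind == "pcp":
            scaler = StandardScaler().fit(X)
            X = scaler.transform(X)
        est = MLPClassifier(
            random_state=seed,
            early_stopping=False,
            **spec.hyperparameters,
        )
        est.fit(X, y)
    else:
        raise UnknownPreset(f"unknown family {spec.family!r}")
    return TrainedModel(spec=spec, estimator=est, scaler=scaler, train_features=np.asarray(features, dtype=np.float64))


_ACTIVATIONS = {
    "relu": lambda z: np.maximum(z, 0.0),
    "tanh": np.tanh,
    "logistic": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "identity": lambda z: z,
}


def _mlp_forward(
    est: MLPClassifier,
    X: np.ndarray,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    return_latent: bool = False,
) -> np.ndarray:
    """Forward pass over fitted MLP weights.

    With ``dropout_rate`` > 0 and an rng, each hidden layer's activations are
    masked Bernoulli(1 - rate) and rescaled by 1/(1 - rate) (inverted
    dropout), making the pass a deterministic function of the rng state.
    """
    act = _ACTIVATIONS[est.activation]
    a = X
    n_layers = len(est.coefs_)
    for i, (W, b) in enumerate(zip(est.coefs_, est.intercepts_)):
        z = a @ W + b
        if i < n_layers - 1:
            a = act(z)
            if dropout_rate > 0.0 and rng is not None:
                mask = rng.random(a.shape) >= dropout_rate
                a = a * mask / (1.0 - dropout_rate)
        else:
            if return_latent:
                return np.asarray(a, dtype=np.float64)
            # binary output head: logistic over a single logit
            p_pos = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack([1.0 - p_pos, p_pos])
    raise AssertionError("unreachable")


def predict_probabilities(
    model: TrainedModel,
    features,
    dropout_active: bool = False,
    pass_seed: int | None = None,
) -> PredictionSet:
    """Class probabilities for a feature batch.

    ``dropout_active`` runs one stochastic dropout pass seeded by
    ``pass_seed``; it requires an MLP. With the model's dropout rate at 0 the
    pass degenerates to the deterministic forward.
    """
    X = np.asarray(features, dtype=np.float64)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    if dropout_active:
        if not model.supports_dropout_inference:
            raise DropoutUnsupported("dropout inference requires an MLP")
        rng = np.random.default_rng(pass_seed)
        probs = _mlp_forward(model.estimator, X, dropout_rate=model.spec.dropout_rate, rng=rng)
    elif model.spec.family == "mlp":
        probs = _mlp_forward(model.estimator, X)
    else:
        probs = model.estimator.predict_proba(X)
    return PredictionSet(
        probabilities=np.asarray(probs, dtype=np.float64),
        model_id=model.model_id,
        seed=model.spec.seed if pass_seed is None else pass_seed,
    )


def extract_latent(model: TrainedModel, features) -> np.ndarray:
    """Post-activation outputs of the last hidden layer (no dropout)."""
    if not model.supports_latent:
        raise LatentUnsupported("latent extraction requires an MLP")
    X = np.asarray(features, dtype=np.float64)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    return _mlp_forward(model.estimator, X, return_latent=True)


def train_replicates(
    spec: ModelSpec, features, labels, seeds: Sequence[int]
) -> list[TrainedModel]:
    """Train one model per seed (independent initializations), order kept."""
    seeds = list(seeds)
    if len(seeds) < 2:
        raise DuplicateSeeds("need at least 2 replicate seeds")
    if len(set(seeds)) != len(seeds):
        raise DuplicateSeeds(f"seeds not distinct: {seeds}")
    return [train_classifier(spec, features, labels, seed=s) for s in seeds]
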