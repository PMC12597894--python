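"""The four discriminator families behind one estimator surface.

A discriminator is a binary classifier separating target-like from decoy-like
sub-score vectors. Four families are supported:

``lda``
    Closed-form pooled-covariance linear discriminant, with a tiny shrinkage
    term (default 1e-6) on the covariance for rank safety.
``svm``
    Linear soft-margin SVM (hinge loss, C=1). Linear because sub-score tables
    run to hundreds of features and millions of rows.
``gbt``
    Gradient-boosted trees (XGBoost): 100 rounds, depth 6, learning rate 0.1,
    full subsampling, seeded. Known to be hyperparameter-sensitive.
``mlp_ensemble``
    An ensemble (default 12 members) of small feed-forward networks with
    tapering hidden layers (default 25-20-15-5, logistic activations), each
    member trained on a random half of the training rows, discriminant
    scores averaged over members. This mirrors the DIA-NN-style ensemble
    design; every number is a configuration key.

All families consume features standardized with training-set mean/sd; the
scaler is part of the fitted model, so no test-set statistics leak into it.
``decision_scores`` returns one real number per row, larger = more
target-like. Rank order is what downstream q-value estimation consumes, so
only the ordering of scores matters, not their scale: lda/svm emit a signed
distance, gbt the boosting margin, mlp_ensemble a mean member probability —
each a strictly monotone link of the family's internal discriminant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .exceptions import (
    ConfigError,
    DegenerateTrainingError,
    InsufficientDataError,
    ShapeError,
)

FAMILIES = ("lda", "svm", "gbt", "mlp_ensemble")

_DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "lda": {"shrinkage": 1e-6},
    "svm": {"C": 1.0, "max_iter": 20000, "tol": 1e-4},
    "gbt": {
        "n_estimators": 100,
        "max_depth": 6,
        "learning_rate": 0.1,
        "subsample": 1.0,
        "reg_lambda": 1.0,
        "min_child_weight": 1,
    },
    "mlp_ensemble": {
        "n_members": 12,
        "hidden_layer_sizes": (25, 20, 15, 5),
        "activation": "logistic",
        "sample_fraction": 0.5,
        "learning_rate_init": 1e-3,
        "batch_size": 50,
    },
}


@dataclass
class ClassifierSpec:
    """Declarative description of one discriminator.

    Unknown hyperparameter keys for the chosen family are rejected at
    construction so configuration typos fail loudly.
    """

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(
                f"unknown classifier family {self.family!r}; choose from {FAMILIES}"
            )
        allowed = set(_DEFAULT_HYPERPARAMETERS[self.family])
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise ConfigError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)} "
                f"(allowed: {sorted(allowed)})"
            )

    def resolved(self) -> dict[str, Any]:
        """Family defaults overlaid with the spec's overrides."""
        hp = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        hp.update(self.hyperparameters)
        return hp

    def build(self, epochs: int = 1, seed: int | None = None) -> "DiscriminantModel":
        return DiscriminantModel(
            family=self.family,
            hyperparameters=dict(self.hyperparameters),
            seed=self.seed if seed is None else seed,
            epochs=epochs,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ClassifierSpec":
        return cls(
            family=d["family"],
            hyperparameters=dict(d.get("hyperparameters", {})),
            seed=int(d.get("seed", 0)),
        )


class MLPEnsemble(BaseEstimator):
    """Bagged ensemble of small multilayer perceptrons.

    Each member is trained on a seeded random half of the training rows
    (sampled per class so both classes are always present) for ``epochs``
    passes of Adam; the ensemble score is the mean member probability of the
    positive class. An ensemble of size 1 is exactly its single member.
    """

    def __init__(
        self,
        n_members: int = 12,
        hidden_layer_sizes: tuple[int, ...] = (25, 20, 15, 5),
        activation: str = "logistic",
        sample_fraction: float = 0.5,
        learning_rate_init: float = 1e-3,
        batch_size: int = 50,
        epochs: int = 10,
        random_state: int = 0,
    ):
        self.n_members = n_members
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.sample_fraction = sample_fraction
        self.learning_rate_init = learning_rate_init
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        ss = np.random.SeedSequence(self.random_state)
        member_seeds = [int(s) % (2**31) for s in ss.generate_state(self.n_members)]
        rng = np.random.default_rng(ss.spawn(1)[0])
        self.members_ = []
        for mseed in member_seeds:
            idx = self._subsample(y, rng)
            net = MLPClassifier(
                hidden_layer_sizes=tuple(self.hidden_layer_sizes),
                activation=self.activation,
                solver="adam",
                learning_rate_init=self.learning_rate_init,
                batch_size=min(self.batch_size, idx.size),
                max_iter=max(1, int(self.epochs)),
                n_iter_no_change=max(10, int(self.epochs)),
                tol=0.0,
                random_state=mseed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                net.fit(X[idx], y[idx])
            self.members_.append(net)
        return self

    def _subsample(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # per-class halves: keeps the target:decoy balance inside each member
        parts = []
        for cls in np.unique(y):
            rows = np.flatnonzero(y == cls)
            k = max(1, int(round(self.sample_fraction * rows.size)))
            parts.append(rng.choice(rows, size=k, replace=False))
        return np.sort(np.concatenate(parts))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        probs = [net.predict_proba(X)[:, 1] for net in self.members_]
        return np.mean(probs, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


class DiscriminantModel(BaseEstimator, ClassifierMixin):
    """One fitted discriminator of any family, scaler included.

    ``epochs`` counts passes over the training data for iterative learners
    (the MLP ensemble members); closed-form or convex fits (lda, svm, gbt's
    fixed boosting schedule) note and ignore it.
    """

    def __init__(
        self,
        family: str = "lda",
        hyperparameters: dict[str, Any] | None = None,
        seed: int = 0,
        epochs: int = 1,
    ):
        self.family = family
        self.hyperparameters = hyperparameters
        self.seed = seed
        self.epochs = epochs

    # -- internals ---------------------------------------------------------
    def _spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            family=self.family,
            hyperparameters=dict(self.hyperparameters or {}),
            seed=self.seed,
        )

    def _make_core(self, hp: dict[str, Any]):
        if self.family == "lda":
            return LinearDiscriminantAnalysis(
                solver="eigen", shrinkage=hp["shrinkage"]
            )
        if self.family == "svm":
            return LinearSVC(
                C=hp["C"],
                loss="hinge",
                dual=True,
                max_iter=hp["max_iter"],
                tol=hp["tol"],
                random_state=self.seed % (2**31),
            )
        if self.family == "gbt":
            return XGBClassifier(
                n_estimators=hp["n_estimators"],
                max_depth=hp["max_depth"],
                learning_rate=hp["learning_rate"],
                subsample=hp["subsample"],
                reg_lambda=hp["reg_lambda"],
                min_child_weight=hp["min_child_weight"],
                random_state=self.seed % (2**31),
                n_jobs=1,
                tree_method="hist",
                eval_metric="logloss",
            )
        return MLPEnsemble(
            n_members=hp["n_members"],
            hidden_layer_sizes=hp["hidden_layer_sizes"],
            activation=hp["activation"],
            sample_fraction=hp["sample_fraction"],
            learning_rate_init=hp["learning_rate_init"],
            batch_size=hp["batch_size"],
            epochs=self.epochs,
            random_state=self.seed % (2**31),
        )

    # -- estimator surface -------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "DiscriminantModel":
        spec = self._spec()  # validates family + hyperparameter keys
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2:
            raise ShapeError("X must be a 2-D score matrix")
        if X.shape[0] != y.shape[0]:
            raise ShapeError("X and y row counts differ")
        if X.shape[0] < 2:
            raise InsufficientDataError("need at least 2 training rows")
        if np.unique(y).size < 2:
            raise DegenerateTrainingError(
                "training labels contain a single class"
            )
        self.scaler_ = StandardScaler().fit(X)
        self.core_ = self._make_core(spec.resolved())
        Xs = self.scaler_.transform(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.core_.fit(Xs, y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Real-valued discriminant, one per row; larger = more target-like."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ShapeError(
                f"expected {self.n_features_in_} features, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        Xs = self.scaler_.transform(X)
        if self.family == "gbt":
            return np.asarray(self.core_.predict(Xs, output_margin=True), dtype=float)
        return np.asarray(self.core_.decision_function(Xs), dtype=float)

    # sklearn-compatible aliases
    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.decision_scores(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        thr = 0.5 if self.family in ("mlp_ensemble",) else 0.0
        return (self.decision_scores(X) >= thr).astype(int)


def fit(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, epochs: int = 1
) -> DiscriminantModel:
    """Fit one discriminator described by ``spec``; see DiscriminantModel."""
    return spec.build(epochs=epochs).fit(X, y)


def decision_scores(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    return model.decision_scores(X)


def build_classifier(classifier, seed: int, epochs: int):
    """Resolve a family name / ClassifierSpec / estimator into a fresh model.

    Estimator instances (anything with fit + decision_function) are cloned,
    which lets callers inject custom scorers; their own random_state, if any,
    is left untouched.
    """
    if isinstance(classifier, str):
        classifier = ClassifierSpec(family=classifier)
    if isinstance(classifier, ClassifierSpec):
        return classifier.build(epochs=epochs, seed=seed)
    return clone(classifier)
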