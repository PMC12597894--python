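"""The three discriminator-training frameworks.

All three treat decoys as negatives and differ in which targets serve as
positives and which rows each fitted model is allowed to score:

semi-supervised ("train on part, predict all")
    Starts from the single best sub-score column, takes targets passing a
    confidence cut as positives, fits, rescores *every* row, recomputes
    q-values, and iterates. Train and test overlap.
fully supervised ("train on all, predict all")
    All targets are positives in one single fit (default one training epoch),
    and that model scores every row. Train and test overlap completely.
K-fold ("train on part, predict rest")
    Rows are split into label-stratified folds; each fold is scored only by
    the model fitted on the other folds, so no row is ever scored by a model
    that saw it. With the default 5 folds, each training partition holds 80%
    of the targets. By default decoys are scored out-of-fold exactly like
    targets; ``decoy_scoring="ensemble_mean"`` instead averages all K models
    on the decoy rows.

The overlap (or strict separation) of train and test is the whole point:
overfitting an overlapping framework makes the decoy-based q-values
anti-conservative, which the entrapment-based external FDR exposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    CollapseError,
    ConfigError,
    InitializationError,
    StratificationError,
)
from .fdr import qvalues_from_scores
from .models import ClassifierSpec, build_classifier
from .table import ScoreTable

logger = logging.getLogger(__name__)

FRAMEWORKS = ("semi_supervised", "fully_supervised", "kfold")


def _child_seed(seed: int, k: int) -> int:
    """Deterministic sub-seed; stable across frameworks so that reductions
    (e.g. one semi-supervised iteration with all targets positive == fully
    supervised) hold bit-for-bit."""
    return int(np.random.SeedSequence([int(seed), int(k)]).generate_state(1)[0]) % (
        2**31
    )


def _scores_of(model, X: np.ndarray) -> np.ndarray:
    fn = getattr(model, "decision_scores", None) or model.decision_function
    return np.asarray(fn(X), dtype=float)


def _decoy_zscore(scores: np.ndarray, is_target: np.ndarray) -> np.ndarray:
    """Standardize a score block on its decoy sub-population.

    A strictly increasing affine map, so rank order within the block is
    untouched; falls back to sd=1 for degenerate (constant) decoy scores.
    """
    d = scores[~is_target]
    if d.size < 2:
        return scores
    sd = float(d.std())
    return (scores - float(d.mean())) / (sd if sd > 0 else 1.0)


@dataclass
class FrameworkParams:
    """Knobs of the three frameworks; only the relevant subset applies.

    ``epochs=None`` resolves to 1 for the fully supervised framework (its
    single-epoch rule is part of the design, guarding against overfitting on
    the fully overlapping train/test set) and to 10 elsewhere. Overriding
    epochs > 1 under fully supervised is allowed but logged as off-design.
    """

    framework: str = "kfold"
    n_folds: int = 5
    n_iterations: int = 10
    q_init: float = 0.15
    q_learn: float = 0.02
    epochs: int | None = None
    decoy_scoring: str = "out_of_fold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.framework not in FRAMEWORKS:
            raise ConfigError(
                f"unknown framework {self.framework!r}; choose from {FRAMEWORKS}"
            )
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if not (0.0 < self.q_learn <= self.q_init < 0.5):
            raise ConfigError("need 0 < q_learn <= q_init < 0.5")
        if self.decoy_scoring not in ("out_of_fold", "ensemble_mean"):
            raise ConfigError("decoy_scoring must be out_of_fold or ensemble_mean")
        if self.epochs is not None and self.epochs < 1:
            raise ConfigError("epochs must be >= 1")

    def resolved_epochs(self) -> int:
        if self.epochs is None:
            return 1 if self.framework == "fully_supervised" else 10
        if self.framework == "fully_supervised" and self.epochs != 1:
            logger.warning(
                "fully supervised training with epochs=%d (single-epoch is the "
                "framework's design)",
                self.epochs,
            )
        return self.epochs


@dataclass
class DiscriminantResult:
    """Per-row discriminant scores and q-values from one framework run.

    ``qvalues`` carries the decoy-based q for every row; only target rows'
    entries are the estimator proper (decoy entries are diagnostics).
    ``provenance`` records the framework, classifier, seed, and — where
    applicable — the fold assignment and the per-iteration positive-set
    trace.
    """

    scores: np.ndarray
    qvalues: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)


def select_initial_direction(
    table: ScoreTable, q_init: float = 0.15
) -> tuple[int, int]:
    """The single best sub-score column and orientation.

    Scans every (column, sign) pair, using the signed column alone as the
    discriminant, and returns the pair maximizing the number of targets with
    q <= q_init. Ties break toward the lowest column index, +1 before -1.
    """
    table.require_both_classes()
    best: tuple[int, int] | None = None
    best_count = 0
    for j in range(table.n_features):
        for sign in (1, -1):
            q = qvalues_from_scores(sign * table.scores[:, j], table.is_target)
            count = int((q[table.is_target] <= q_init).sum())
            if count > best_count:
                best, best_count = (j, sign), count
    if best is None:
        raise InitializationError(
            f"no single sub-score selects any target at q <= {q_init}; "
            "consider a larger q_init"
        )
    return best


class _BaseRescorer(BaseEstimator):
    """Shared fit plumbing; subclasses implement ``_run``."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaseRescorer":
        """Fit on a score matrix ``X`` and boolean target mask ``y``.

        Sets ``scores_`` and ``qvalues_`` (one entry per row) plus
        framework-specific attributes.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if X.shape[0] != y.shape[0]:
            raise ConfigError("X and y row counts differ")
        self._run(X, y)
        return self

    def fit_table(self, table: ScoreTable) -> "_BaseRescorer":
        table.require_both_classes()
        return self.fit(table.scores, table.is_target)

    def result(self) -> DiscriminantResult:
        return DiscriminantResult(
            scores=self.scores_,
            qvalues=self.qvalues_,
            provenance=self._provenance(),
        )

    def _classifier_desc(self) -> Any:
        c = self.classifier
        return c.to_dict() if isinstance(c, ClassifierSpec) else repr(c)


class SemiSupervisedRescorer(_BaseRescorer):
    """Iterative confidence-expansion training (mProphet-style).

    Iteration i takes as positives the targets whose current q-value is
    <= ``q_learn`` (q-values start from the best single sub-score column,
    chosen at ``q_init``), fits a fresh classifier against all decoys,
    rescores every row and recomputes q. The positive set typically grows
    across iterations on real signal; an empty positive set raises
    :class:`CollapseError`.
    """

    def __init__(
        self,
        classifier="lda",
        n_iterations: int = 10,
        q_init: float = 0.15,
        q_learn: float = 0.02,
        epochs: int = 10,
        seed: int = 0,
    ):
        self.classifier = classifier
        self.n_iterations = n_iterations
        self.q_init = q_init
        self.q_learn = q_learn
        self.epochs = epochs
        self.seed = seed

    def _run(self, X: np.ndarray, y: np.ndarray) -> None:
        if not (0.0 < self.q_learn <= self.q_init < 0.5):
            raise ConfigError("need 0 < q_learn <= q_init < 0.5")
        table = _matrix_table(X, y)
        j, sign = select_initial_direction(table, self.q_init)
        self.initial_direction_ = (j, sign)
        scores = sign * X[:, j]
        q = qvalues_from_scores(scores, y)
        trace: list[int] = []
        decoy_rows = np.flatnonzero(~y)
        for it in range(self.n_iterations):
            positives = np.flatnonzero(y & (q <= self.q_learn))
            if positives.size == 0:
                raise CollapseError(it)
            trace.append(int(positives.size))
            train = np.concatenate([positives, decoy_rows])
            y_train = np.concatenate(
                [np.ones(positives.size, int), np.zeros(decoy_rows.size, int)]
            )
            model = build_classifier(
                self.classifier, seed=_child_seed(self.seed, it), epochs=self.epochs
            )
            model.fit(X[train], y_train)
            scores = _scores_of(model, X)
            q = qvalues_from_scores(scores, y)
        self.scores_ = scores
        self.qvalues_ = q
        self.iteration_trace_ = trace

    def _provenance(self) -> dict[str, Any]:
        return {
            "framework": "semi_supervised",
            "classifier": self._classifier_desc(),
            "seed": self.seed,
            "initial_direction": self.initial_direction_,
            "iteration_trace": self.iteration_trace_,
        }


class FullySupervisedRescorer(_BaseRescorer):
    """Single fit with every target as a positive, scoring every row.

    Train and test coincide by design; the default single epoch is the
    conventional guard against the resulting leakage.
    """

    def __init__(self, classifier="lda", epochs: int = 1, seed: int = 0):
        self.classifier = classifier
        self.epochs = epochs
        self.seed = seed

    def _run(self, X: np.ndarray, y: np.ndarray) -> None:
        model = build_classifier(
            self.classifier, seed=_child_seed(self.seed, 0), epochs=self.epochs
        )
        model.fit(X, y.astype(int))
        self.model_ = model
        self.scores_ = _scores_of(model, X)
        self.qvalues_ = qvalues_from_scores(self.scores_, y)
        self.training_size_ = int(X.shape[0])

    def _provenance(self) -> dict[str, Any]:
        return {
            "framework": "fully_supervised",
            "classifier": self._classifier_desc(),
            "seed": self.seed,
            "training_size": self.training_size_,
        }


class KFoldRescorer(_BaseRescorer):
    """Out-of-fold scoring with label-stratified folds.

    Every row — target and decoy alike — is assigned to exactly one test
    fold by a seeded stratified shuffle and scored only by the model fitted
    on the other folds. ``fold_assignment_`` and ``scored_by_`` record the
    partition and which model scored each row, enabling an explicit leakage
    audit (:meth:`leakage_pairs`). With ``decoy_scoring="ensemble_mean"``,
    decoy rows are instead scored by the mean of all K models
    (``scored_by_`` = -1 for those rows).

    The K fold models emit discriminants on slightly different scales
    (means, intercepts and covariances are re-estimated per fold), so raw
    out-of-fold scores do not pool into one clean ranking. By default each
    fold's scores are therefore standardized on that fold's *decoy* score
    distribution before pooling (``fold_normalization="decoy_zscore"``, the
    usual merge step of cross-validated rescoring); decoys carry no signal,
    so this aligns the null across folds without touching rank order within
    a fold. ``fold_normalization="none"`` pools raw scores.
    """

    def __init__(
        self,
        classifier="lda",
        n_folds: int = 5,
        epochs: int = 10,
        decoy_scoring: str = "out_of_fold",
        fold_normalization: str = "decoy_zscore",
        seed: int = 0,
    ):
        self.classifier = classifier
        self.n_folds = n_folds
        self.epochs = epochs
        self.decoy_scoring = decoy_scoring
        self.fold_normalization = fold_normalization
        self.seed = seed

    def _run(self, X: np.ndarray, y: np.ndarray) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.decoy_scoring not in ("out_of_fold", "ensemble_mean"):
            raise ConfigError("decoy_scoring must be out_of_fold or ensemble_mean")
        if self.fold_normalization not in ("decoy_zscore", "none"):
            raise ConfigError("fold_normalization must be decoy_zscore or none")
        n = X.shape[0]
        counts = np.bincount(y.astype(int), minlength=2)
        if counts.min() < self.n_folds:
            raise StratificationError(
                f"cannot stratify {counts.min()} rows of one class into "
                f"{self.n_folds} folds; use fewer folds"
            )
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.seed % (2**32 - 1)
        )
        fold_of = np.full(n, -1, dtype=int)
        scores = np.full(n, np.nan)
        scored_by = np.full(n, -1, dtype=int)
        models = []
        decoy_rows = np.flatnonzero(~y)
        decoy_preds = []
        for f, (train_idx, test_idx) in enumerate(skf.split(X, y.astype(int))):
            if np.unique(y[train_idx]).size < 2:
                raise StratificationError(
                    f"training partition of fold {f} lost a class; use fewer folds"
                )
            model = build_classifier(
                self.classifier, seed=_child_seed(self.seed, f), epochs=self.epochs
            )
            model.fit(X[train_idx], y[train_idx].astype(int))
            models.append(model)
            fold_of[test_idx] = f
            fold_scores = _scores_of(model, X[test_idx])
            if self.fold_normalization == "decoy_zscore":
                fold_scores = _decoy_zscore(fold_scores, y[test_idx])
            scores[test_idx] = fold_scores
            scored_by[test_idx] = f
            if self.decoy_scoring == "ensemble_mean":
                dp = _scores_of(model, X[decoy_rows])
                if self.fold_normalization == "decoy_zscore":
                    dp = _decoy_zscore(dp, np.zeros(dp.size, dtype=bool))
                decoy_preds.append(dp)
        if self.decoy_scoring == "ensemble_mean":
            scores[decoy_rows] = np.mean(decoy_preds, axis=0)
            scored_by[decoy_rows] = -1
        self.models_ = models
        self.fold_assignment_ = fold_of
        self.scored_by_ = scored_by
        self.scores_ = scores
        self.qvalues_ = qvalues_from_scores(scores, y)

    def leakage_pairs(self) -> list[tuple[int, int]]:
        """(row, model) pairs where the scoring model's training fold
        included the row; an empty list certifies leakage-freedom."""
        out = []
        for i, f in enumerate(self.scored_by_):
            if f >= 0 and self.fold_assignment_[i] != f:
                out.append((i, int(f)))
        return out

    def _provenance(self) -> dict[str, Any]:
        return {
            "framework": "kfold",
            "classifier": self._classifier_desc(),
            "seed": self.seed,
            "n_folds": self.n_folds,
            "decoy_scoring": self.decoy_scoring,
            "fold_normalization": self.fold_normalization,
            "fold_assignment": self.fold_assignment_.tolist(),
        }


def _matrix_table(X: np.ndarray, y: np.ndarray) -> ScoreTable:
    """Wrap a bare matrix + label mask for operations that want a table."""
    n = X.shape[0]
    return ScoreTable(
        ids=np.array([str(i) for i in range(n)], dtype=object),
        is_target=y,
        entrapment=np.zeros(n, dtype=bool),
        scores=X,
        feature_names=[f"f{j}" for j in range(X.shape[1])],
    )


# -- functional wrappers ----------------------------------------------------

def run_semi_supervised(
    table: ScoreTable, clf, params: FrameworkParams
) -> DiscriminantResult:
    if params.framework != "semi_supervised":
        raise ConfigError("params.framework must be 'semi_supervised'")
    r = SemiSupervisedRescorer(
        classifier=clf,
        n_iterations=params.n_iterations,
        q_init=params.q_init,
        q_learn=params.q_learn,
        epochs=params.resolved_epochs(),
        seed=params.seed,
    ).fit_table(table)
    return r.result()


def run_fully_supervised(
    table: ScoreTable, clf, params: FrameworkParams
) -> DiscriminantResult:
    if params.framework != "fully_supervised":
        raise ConfigError("params.framework must be 'fully_supervised'")
    r = FullySupervisedRescorer(
        classifier=clf, epochs=params.resolved_epochs(), seed=params.seed
    ).fit_table(table)
    return r.result()


def run_kfold(table: ScoreTable, clf, params: FrameworkParams) -> DiscriminantResult:
    if params.framework != "kfold":
        raise ConfigError("params.framework must be 'kfold'")
    r = KFoldRescorer(
        classifier=clf,
        n_folds=params.n_folds,
        epochs=params.resolved_epochs(),
        decoy_scoring=params.decoy_scoring,
        seed=params.seed,
    ).fit_table(table)
    return r.result()


def run_framework(table: ScoreTable, clf, params: FrameworkParams) -> DiscriminantResult:
    """Dispatch on ``params.framework``."""
    runner = {
        "semi_supervised": run_semi_supervised,
        "fully_supervised": run_fully_supervised,
        "kfold": run_kfold,
    }[params.framework]
    return runner(table, clf, params)
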