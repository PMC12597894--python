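"""Shared test utilities: independent oracles and probe classifiers."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from tdbench import ScoreTable


def brute_force_qvalues(scores: np.ndarray, is_target: np.ndarray) -> np.ndarray:
    """O(n^2) reference q-values: explicit double loop over thresholds.

    For each target, minimize over every distinct score value at or below
    its own the ratio (#decoys >= s) / max(1, #targets >= s), clipped to 1.
    """
    scores = np.asarray(scores, float)
    is_target = np.asarray(is_target, bool)
    tgt = scores[is_target]
    dec = scores[~is_target]
    out = np.empty(tgt.size)
    thresholds = np.unique(scores)
    for k, si in enumerate(tgt):
        best = np.inf
        for s in thresholds:
            if s <= si:
                d = int((dec >= s).sum())
                t = int((tgt >= s).sum())
                best = min(best, min(1.0, d / max(1, t)))
        out[k] = best
    return out


class FirstFeatureScorer(BaseEstimator):
    """Degenerate classifier: ignores training, scores rows by feature 0."""

    def fit(self, X, y):
        return self

    def decision_function(self, X):
        return np.asarray(X, float)[:, 0]


#: audit trails of RecordingScorer instances, keyed by token; sklearn clones
#: deep-copy constructor params, so the shared state lives here instead
RECORDING_LOGS: dict[str, list] = {}


class RecordingScorer(BaseEstimator):
    """Logs which row ids (feature 0) each model trains on and scores."""

    def __init__(self, token="default"):
        self.token = token

    def fit(self, X, y):
        self.entry_ = {"trained": set(np.asarray(X)[:, 0].tolist()), "scored": set()}
        RECORDING_LOGS.setdefault(self.token, []).append(self.entry_)
        return self

    def decision_function(self, X):
        X = np.asarray(X, float)
        self.entry_["scored"].update(X[:, 0].tolist())
        return X[:, 0]


def separable_table(n_per_class: int = 50, gap: float = 8.0, seed: int = 0) -> ScoreTable:
    """Targets and decoys fully separated along feature 0."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    scores = rng.standard_normal((n, 2)) * 0.3
    scores[:n_per_class, 0] += gap
    is_target = np.zeros(n, bool)
    is_target[:n_per_class] = True
    return ScoreTable(
        ids=np.array([f"r{i}" for i in range(n)], object),
        is_target=is_target,
        entrapment=np.zeros(n, bool),
        scores=scores,
        feature_names=["f0", "f1"],
    )
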