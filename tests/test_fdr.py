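"""Decoy-based q-values and entrapment-based external FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdbench import (
    ScoreTable,
    calibration_curve,
    compute_qvalues,
    entrapment_fdr,
    ids_at_external_fdr,
    qvalues_from_scores,
)
from tdbench.exceptions import (
    ConfigError,
    ContractError,
    EstimatorUndefinedError,
    UndefinedMetricError,
)
from helpers import brute_force_qvalues


def _mk_table(is_target, entrapment, scores=None):
    n = len(is_target)
    return ScoreTable(
        ids=np.array([f"r{i}" for i in range(n)], object),
        is_target=np.asarray(is_target, bool),
        entrapment=np.asarray(entrapment, bool),
        scores=np.asarray(scores if scores is not None else np.zeros((n, 1))),
        feature_names=["s"],
    )


def test_worked_qvalue_example():
    scores = np.array([5.0, 4.0, 3.0, 4.5, 2.0])
    is_target = np.array([1, 1, 1, 0, 0], bool)
    q = qvalues_from_scores(scores, is_target)
    assert np.allclose(q[:3], [0.0, 1 / 3, 1 / 3])


def test_separated_scores_give_zero_qvalues():
    scores = np.array([10.0, 9.0, 8.0, 1.0, 0.5])
    q = qvalues_from_scores(scores, np.array([1, 1, 1, 0, 0], bool))
    assert np.all(q[:3] == 0.0)


def test_all_tied_scores_give_decoy_target_ratio():
    q = qvalues_from_scores(np.zeros(6), np.array([1, 1, 1, 0, 0, 0], bool))
    assert np.all(q == 1.0)
    # 2 decoys vs 4 targets: ratio 0.5
    q = qvalues_from_scores(np.zeros(6), np.array([1, 1, 1, 1, 0, 0], bool))
    assert np.allclose(q[:4], 0.5)


def test_no_decoys_is_estimator_undefined():
    with pytest.raises(EstimatorUndefinedError):
        qvalues_from_scores(np.arange(3.0), np.ones(3, bool))


@settings(max_examples=60, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(4, 60), st.booleans())
def test_qvalues_match_bruteforce_oracle(seed, n, with_ties):
    """Exact agreement with the O(n^2) double-loop reference, ties included."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=n)
    if with_ties:
        scores = np.round(scores, 1)  # force tied score blocks
    is_target = rng.random(n) < 0.5
    is_target[0], is_target[1] = True, False  # both classes present
    q = qvalues_from_scores(scores, is_target)
    assert np.array_equal(q[is_target], brute_force_qvalues(scores, is_target))
    # invariants: range and monotonicity in score among targets
    assert np.all((q >= 0) & (q <= 1))
    order = np.argsort(-scores[is_target])
    assert np.all(np.diff(q[is_target][order]) >= 0)


def test_compute_qvalues_reports_sort_order():
    qv = compute_qvalues(np.array([1.0, 3.0, 2.0]), np.array([1, 1, 0], bool))
    assert qv.score_order.tolist() == [1, 2, 0]


def test_entrapment_fdr_ratios():
    t = _mk_table([True] * 100, [True, True] + [False] * 98)
    assert entrapment_fdr(np.arange(100), t) == pytest.approx(0.02)
    assert entrapment_fdr(np.arange(2, 52), t) == 0.0
    assert entrapment_fdr(np.arange(2), t) == 1.0
    assert entrapment_fdr(np.zeros(100, bool), t) == 0.0  # empty set floor
    # permutation invariance
    rng = np.random.default_rng(0)
    idx = rng.permutation(60)
    assert entrapment_fdr(idx, t) == entrapment_fdr(np.sort(idx), t)


def test_entrapment_fdr_rejects_decoys():
    t = _mk_table([True, False], [False, False])
    with pytest.raises(ContractError):
        entrapment_fdr(np.array([0, 1]), t)


def test_calibration_curve_full_acceptance_limit_and_monotonicity():
    rng = np.random.default_rng(3)
    n = 200
    is_target = np.r_[np.ones(100, bool), np.zeros(100, bool)]
    entrap = np.r_[rng.random(100) < 0.3, np.zeros(100, bool)]
    scores = rng.normal(size=(n, 1))
    scores[:100] += 2.0
    t = _mk_table(is_target, entrap, scores)
    q = qvalues_from_scores(scores[:, 0], is_target)
    curve = calibration_curve(q, t, grid=[0.01, 0.02, 0.05, 1.0])
    df = curve.to_frame()
    assert np.all(np.diff(df.n_ids) >= 0)  # non-decreasing identifications
    # grid point 100%: everything accepted, external = overall entrapment share
    full = curve.at(1.0)
    assert full[1] == pytest.approx(entrap.sum() / 100)
    assert full[2] == 100 - entrap.sum()


def test_calibration_curve_separated_construction():
    # true targets on top, then all decoys, entrapment targets at the bottom:
    # entrapment rows outscored by every decoy never reach a small q
    is_target = np.r_[np.ones(60, bool), np.zeros(40, bool)]
    entrap = np.r_[np.zeros(30, bool), np.ones(30, bool), np.zeros(40, bool)]
    scores = np.r_[np.linspace(10, 9, 30), np.linspace(2, 1, 30), np.linspace(5, 4, 40)]
    t = _mk_table(is_target, entrap, scores[:, None])
    q = qvalues_from_scores(scores, is_target)
    curve = calibration_curve(q, t)
    assert all(p[1] == 0.0 for p in curve.points)


def test_calibration_curve_empty_grid_rejected(tiny_table):
    with pytest.raises(ConfigError):
        calibration_curve(np.zeros(4), tiny_table, grid=[])


def test_ids_at_external_fdr():
    # 50 true targets on top, then interleaved entrapment/null targets, decoys low
    is_target = np.r_[np.ones(80, bool), np.zeros(80, bool)]
    entrap = np.r_[np.zeros(50, bool), np.ones(30, bool), np.zeros(80, bool)]
    scores = np.r_[np.linspace(20, 19, 50), np.linspace(5, 4, 30), np.linspace(1, 0, 80)]
    t = _mk_table(is_target, entrap, scores[:, None])
    assert ids_at_external_fdr(scores, t, level=0.01) == 50  # exactly the true set
    assert ids_at_external_fdr(scores, t, level=1.0) == 50  # all non-entrapment
    # bound infeasible at every threshold: the single top row is entrapment
    t2 = _mk_table([True, True], [True, False])
    assert ids_at_external_fdr(np.array([2.0, 1.0]), t2, level=0.01) == 0


def test_ids_at_external_fdr_needs_entrapment(tiny_table):
    t = _mk_table([True, True, False], [False] * 3)
    with pytest.raises(UndefinedMetricError):
        ids_at_external_fdr(np.arange(3.0), t)
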