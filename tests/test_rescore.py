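"""The three training frameworks: initialization, reductions, folds, leakage."""

import numpy as np
import pytest

from tdbench import (
    FrameworkParams,
    FullySupervisedRescorer,
    KFoldRescorer,
    ScoreTable,
    SemiSupervisedRescorer,
    SyntheticConfig,
    generate_table,
    qvalues_from_scores,
    run_framework,
    select_initial_direction,
)
from tdbench.exceptions import (
    CollapseError,
    ConfigError,
    InitializationError,
    StratificationError,
)
from helpers import (
    RECORDING_LOGS,
    FirstFeatureScorer,
    RecordingScorer,
    separable_table,
)


def _table(scores, is_target):
    n = len(is_target)
    return ScoreTable(
        ids=np.array([str(i) for i in range(n)], object),
        is_target=np.asarray(is_target, bool),
        entrapment=np.zeros(n, bool),
        scores=np.asarray(scores, float),
        feature_names=[f"f{j}" for j in range(np.asarray(scores).shape[1])],
    )


# -- framework params ------------------------------------------------------

def test_framework_params_validation():
    with pytest.raises(ConfigError):
        FrameworkParams(framework="bootstrap")
    with pytest.raises(ConfigError):
        FrameworkParams(q_init=0.02, q_learn=0.15)  # q_learn > q_init
    with pytest.raises(ConfigError):
        FrameworkParams(n_folds=1)
    assert FrameworkParams(framework="fully_supervised").resolved_epochs() == 1
    assert FrameworkParams(framework="kfold").resolved_epochs() == 10


# -- initial direction -----------------------------------------------------

def test_initial_direction_exhaustive_scan_oracle():
    """Feature 1 separates, feature 0 is noise; brute-force scan agrees."""
    rng = np.random.default_rng(0)
    n = 100
    scores = rng.standard_normal((2 * n, 2))
    scores[:n, 1] += 4.0
    is_target = np.r_[np.ones(n, bool), np.zeros(n, bool)]
    t = _table(scores, is_target)
    assert select_initial_direction(t, q_init=0.15) == (1, 1)

    # independent oracle: count selected targets for every (column, sign)
    best, best_count = None, 0
    for j in range(2):
        for sign in (1, -1):
            q = qvalues_from_scores(sign * scores[:, j], is_target)
            c = int((q[is_target] <= 0.15).sum())
            if c > best_count:
                best, best_count = (j, sign), c
    assert best == (1, 1)

    t_neg = _table(scores * np.array([1, -1.0]), is_target)
    assert select_initial_direction(t_neg, q_init=0.15) == (1, -1)


def test_initial_direction_failure_on_decoy_dominated_table():
    # decoys sandwich the targets in both orientations: no column selects
    scores = np.array([[1.0], [2.0], [0.0], [10.0]])
    t = _table(scores, [True, True, False, False])
    with pytest.raises(InitializationError):
        select_initial_direction(t, q_init=0.15)


# -- semi-supervised -------------------------------------------------------

def test_semi_supervised_reduces_to_fully_supervised():
    """One iteration with every target confidently positive == one full fit."""
    t = separable_table(n_per_class=60, seed=1)
    semi = SemiSupervisedRescorer(
        "lda", n_iterations=1, q_init=0.45, q_learn=0.4, epochs=1, seed=5
    ).fit_table(t)
    assert semi.iteration_trace_ == [60]  # all targets were positives
    full = FullySupervisedRescorer("lda", epochs=1, seed=5).fit_table(t)
    np.testing.assert_allclose(semi.scores_, full.scores_)


def test_semi_supervised_positive_set_expands_on_signal():
    """On strong half-true signal the confidence set grows from its seed and
    never materially shrinks (once saturated at the true-target count, the
    selected size may jitter by a couple of rows between refits)."""
    grew = 0
    for rep in range(10):
        cfg = SyntheticConfig(
            n_targets=2000, pi_true=0.5, n_features=15, n_informative=5,
            effect_size=3.0, seed=300 + rep, with_sequences=False,
        )
        table, _ = generate_table(cfg)
        r = SemiSupervisedRescorer("lda", n_iterations=5, seed=rep).fit_table(table)
        trace = np.array(r.iteration_trace_)
        tol = 0.005 * cfg.n_targets
        grew += bool(trace[-1] > trace[0] and np.all(np.diff(trace) >= -tol))
    assert grew >= 9


def test_semi_supervised_collapse_or_null_on_no_signal():
    cfg = SyntheticConfig(
        n_targets=300, pi_true=0.0, effect_size=0.0, n_features=8,
        n_informative=0, seed=17, with_sequences=False,
    )
    table, _ = generate_table(cfg)
    try:
        r = SemiSupervisedRescorer("lda", n_iterations=3, seed=0).fit_table(table)
    except (CollapseError, InitializationError):
        return  # an accepted outcome on pure noise
    # train-on-test selection on pure noise admits a trickle of false
    # positives, never a substantial identification list
    accepted = table.is_target & (r.qvalues_ <= 0.01)
    assert accepted.sum() <= 0.05 * table.n_targets


# -- fully supervised ------------------------------------------------------

def test_fully_supervised_trains_on_everything_and_is_deterministic(signal_table):
    table, _ = signal_table
    r1 = FullySupervisedRescorer("lda", seed=3).fit_table(table)
    assert r1.training_size_ == len(table)
    r2 = FullySupervisedRescorer("lda", seed=3).fit_table(table)
    np.testing.assert_array_equal(r1.scores_, r2.scores_)
    np.testing.assert_array_equal(r1.qvalues_, r2.qvalues_)


def test_fully_supervised_beats_single_feature_on_multifeature_signal():
    cfg = SyntheticConfig(
        n_targets=800, pi_true=0.5, n_features=15, n_informative=5,
        effect_size=1.5, seed=8, with_sequences=False,
    )
    table, _ = generate_table(cfg)
    j, sign = select_initial_direction(table, 0.15)
    q1 = qvalues_from_scores(sign * table.scores[:, j], table.is_target)
    ids_single = int((q1[table.is_target] <= 0.01).sum())
    r = FullySupervisedRescorer("mlp_ensemble", seed=4).fit_table(table)
    ids_model = int((r.qvalues_[table.is_target] <= 0.01).sum())
    assert ids_model > ids_single


# -- k-fold ----------------------------------------------------------------

def test_kfold_partition_and_training_fraction():
    cfg = SyntheticConfig(
        n_targets=1000, pi_true=0.3, n_features=6, n_informative=3,
        seed=21, with_sequences=False,
    )
    table, _ = generate_table(cfg)
    r = KFoldRescorer("lda", n_folds=5, seed=2).fit_table(table)
    folds = r.fold_assignment_
    assert np.all(folds >= 0)  # every row in exactly one test fold
    for f in range(5):
        train_targets = int((table.is_target & (folds != f)).sum())
        assert train_targets == 800  # 80% of 1000 targets per training partition


def test_kfold_passthrough_classifier_recovers_feature_zero(signal_table):
    table, _ = signal_table
    r = KFoldRescorer(
        FirstFeatureScorer(), n_folds=4, fold_normalization="none", seed=1
    ).fit_table(table)
    np.testing.assert_array_equal(r.scores_, table.scores[:, 0])
    # under the default per-fold decoy normalization, rank order within a
    # fold is preserved and the pooled ranking stays essentially feature 0
    rz = KFoldRescorer(FirstFeatureScorer(), n_folds=4, seed=1).fit_table(table)
    rho = np.corrcoef(
        np.argsort(np.argsort(rz.scores_)), np.argsort(np.argsort(table.scores[:, 0]))
    )[0, 1]
    assert rho > 0.99


def test_kfold_leakage_audit_with_recording_classifier():
    """Independent audit: no model ever scores a row it trained on."""
    cfg = SyntheticConfig(
        n_targets=200, pi_true=0.3, n_features=4, n_informative=2,
        seed=5, with_sequences=False,
    )
    table, _ = generate_table(cfg)
    # feature 0 re-purposed as a row id visible to the recording classifier
    table.scores[:, 0] = np.arange(len(table))
    for n_folds in (2, 3, 5):
        for decoy_scoring in ("out_of_fold", "ensemble_mean"):
            token = f"audit-{n_folds}-{decoy_scoring}"
            r = KFoldRescorer(
                RecordingScorer(token=token), n_folds=n_folds,
                decoy_scoring=decoy_scoring, fold_normalization="none", seed=9,
            ).fit_table(table)
            log = RECORDING_LOGS.pop(token)
            assert r.leakage_pairs() == []
            assert len(log) == n_folds
            if decoy_scoring == "out_of_fold":
                for entry in log:
                    assert not (entry["trained"] & entry["scored"])
            else:
                decoy_ids = set(np.flatnonzero(~table.is_target).tolist())
                for entry in log:
                    # targets stay leakage-free; only decoys may be re-scored
                    assert not (entry["trained"] & (entry["scored"] - decoy_ids))


def test_kfold_stratification_error_on_tiny_input():
    t = separable_table(n_per_class=3)
    with pytest.raises(StratificationError):
        KFoldRescorer("lda", n_folds=5).fit_table(t)


def test_run_framework_dispatch_and_determinism(signal_table):
    table, _ = signal_table
    params = FrameworkParams(framework="kfold", n_folds=3, epochs=2, seed=11)
    a = run_framework(table, "lda", params)
    b = run_framework(table, "lda", params)
    np.testing.assert_array_equal(a.scores, b.scores)
    assert a.provenance["fold_assignment"] == b.provenance["fold_assignment"]
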