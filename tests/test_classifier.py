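"""MLP protocol: normalization, training dynamics, CV hygiene and
permutation importance."""

import numpy as np
import pytest

from reachkin.classifier import (ClassifierConfig, bce_loss,
                                 column_permuted_loss, cross_validate,
                                 minmax_normalize, permutation_importance,
                                 train_mlp)
from reachkin.errors import ConfigError

N_FEAT = 9


def gaussian_problem(rng, n_per_class=200, separation=4.0, informative=(2,)):
    X = rng.normal(0.0, 1.0, (2 * n_per_class, N_FEAT))
    y = np.r_[np.zeros(n_per_class), np.ones(n_per_class)].astype(int)
    for j in informative:
        X[y == 1, j] += separation
    return X, y


def split(rng, X, y, frac=0.8):
    idx = rng.permutation(len(y))
    cut = int(frac * len(y))
    return idx[:cut], idx[cut:]


# ------------------------------------------------------------ normalization

def test_minmax_examples():
    Xn, params = minmax_normalize(np.array([[-1.0], [0.0], [3.0]]))
    np.testing.assert_allclose(Xn.ravel(), [0.0, 0.25, 1.0])
    # re-applying stored bounds to the training extrema gives exactly 0 / 1
    np.testing.assert_allclose(params.apply(np.array([[-1.0], [3.0]])).ravel(),
                               [0.0, 1.0])


def test_minmax_constant_column_flagged_and_centered():
    X = np.column_stack([np.arange(4.0), np.full(4, 7.0)])
    Xn, params = minmax_normalize(X)
    np.testing.assert_allclose(Xn[:, 1], 0.5)
    np.testing.assert_array_equal(params.constant_mask, [False, True])


# ----------------------------------------------------------------- training

def test_training_is_deterministic_given_seed():
    rng = np.random.default_rng(0)
    X, y = gaussian_problem(rng, n_per_class=40)
    Xn, _ = minmax_normalize(X)
    tr, va = split(rng, X, y)
    cfg = ClassifierConfig(epochs=30, seed=5)
    r1 = train_mlp(Xn[tr], y[tr], cfg, Xn[va], y[va])
    r2 = train_mlp(Xn[tr], y[tr], cfg, Xn[va], y[va])
    np.testing.assert_array_equal(r1.validation_loss, r2.validation_loss)
    np.testing.assert_array_equal(r1.train_accuracy, r2.train_accuracy)
    assert r1.best_epoch == r2.best_epoch


def test_separable_clouds_reach_switch_and_high_accuracy():
    """4-sd-separated clouds: training accuracy reaches the 95% LR-switch
    threshold within 200 epochs under the default schedule."""
    rng = np.random.default_rng(0)
    X, y = gaussian_problem(rng, n_per_class=200, separation=4.0)
    Xn, _ = minmax_normalize(X)
    tr, va = split(rng, X, y)
    res = train_mlp(Xn[tr], y[tr], ClassifierConfig(seed=1), Xn[va], y[va],
                    seed=2)
    assert res.lr_switch_epoch is not None
    assert res.train_accuracy[-1] >= 0.95
    acc = np.mean(res.best_model().predict(Xn[va]) == y[va])
    assert acc >= 0.9


def test_label_permutation_sits_at_chance():
    rng = np.random.default_rng(1)
    X, y = gaussian_problem(rng, n_per_class=100, separation=4.0)
    Xn, _ = minmax_normalize(X)
    accs = []
    for seed in range(10):
        rs = np.random.default_rng(seed)
        yp = rs.permutation(y)
        tr, va = split(rs, X, yp)
        res = train_mlp(Xn[tr], yp[tr], ClassifierConfig(epochs=100, seed=seed),
                        Xn[va], yp[va])
        accs.append(np.mean(res.best_model().predict(Xn[va]) == yp[va]))
    assert 0.35 <= np.mean(accs) <= 0.65


def test_training_input_validation():
    rng = np.random.default_rng(0)
    X, y = gaussian_problem(rng, n_per_class=20)
    with pytest.raises(ConfigError):
        train_mlp(X, y + 1, ClassifierConfig(), X, y)   # labels not 0/1
    with pytest.raises(ConfigError):
        train_mlp(X[:, :5], y, ClassifierConfig(), X[:, :5], y)


# --------------------------------------------------------- cross-validation

def test_cv_requires_enough_samples():
    rng = np.random.default_rng(0)
    X, y = gaussian_problem(rng, n_per_class=4)  # n=8 < 10 folds
    with pytest.raises(ConfigError):
        cross_validate(X, y, ClassifierConfig())


def test_cv_accuracy_self_consistency_and_confusion_totals():
    rng = np.random.default_rng(2)
    X, y = gaussian_problem(rng, n_per_class=30)
    cfg = ClassifierConfig(epochs=20, n_folds=5, seed=3)
    cv = cross_validate(X, y, cfg)
    for f in cv.folds:
        pred = f.model.predict(f.X_val)
        assert f.accuracy == pytest.approx(1.0 - np.mean(np.abs(pred - f.y_val)))
    assert cv.confusion.sum() == len(y)
    assert cv.mean_accuracy == pytest.approx(cv.fold_accuracies.mean())


def test_grouped_folds_never_split_a_subject():
    rng = np.random.default_rng(4)
    X, y = gaussian_problem(rng, n_per_class=30)
    subjects = np.repeat(np.arange(12), 5)
    cfg = ClassifierConfig(epochs=5, n_folds=4, seed=1)
    cv = cross_validate(X, y, cfg, groups=subjects)
    for f in cv.folds:
        val_subj = set(subjects[f.val_indices])
        train_subj = set(subjects) - val_subj
        assert val_subj.isdisjoint(train_subj)


def test_per_fold_normalization_excludes_held_out_rows():
    """Leakage audit: an extreme outlier in a held-out fold must not
    shrink the training normalization (its normalized value blows up),
    while whole-dataset scope absorbs it into [0, 1]."""
    rng = np.random.default_rng(5)
    X, y = gaussian_problem(rng, n_per_class=25)
    outlier_idx = 7
    X[outlier_idx, 0] = 1e6
    for scope, expect_big in (("per_fold_train", True), ("whole_dataset", False)):
        cfg = ClassifierConfig(epochs=2, n_folds=5, seed=2,
                               normalization_scope=scope)
        cv = cross_validate(X, y, cfg)
        fold = next(f for f in cv.folds if outlier_idx in f.val_indices)
        row = np.flatnonzero(fold.val_indices == outlier_idx)[0]
        assert (fold.X_val[row, 0] > 10) == expect_big
        assert np.all(fold.X_val[:, 0] <= 1.0 + 1e-12) or expect_big


# --------------------------------------------------------------- importance

def test_identity_permutation_has_exactly_zero_importance():
    rng = np.random.default_rng(6)
    X, y = gaussian_problem(rng, n_per_class=30)
    Xn, _ = minmax_normalize(X)
    tr, va = split(rng, X, y)
    res = train_mlp(Xn[tr], y[tr], ClassifierConfig(epochs=10, seed=1),
                    Xn[va], y[va])
    model = res.best_model()
    base = bce_loss(model.predict_proba(Xn[va]), y[va])
    for j in range(N_FEAT):
        loss = column_permuted_loss(model, Xn[va], y[va], j,
                                    np.arange(len(va)))
        assert loss == base


def test_informative_feature_outranks_noise():
    rng = np.random.default_rng(7)
    X, y = gaussian_problem(rng, n_per_class=150, separation=4.0,
                            informative=(2,))
    Xn, _ = minmax_normalize(X)
    tr, va = split(rng, X, y)
    res = train_mlp(Xn[tr], y[tr], ClassifierConfig(seed=3), Xn[va], y[va])
    imp = permutation_importance(res.best_model(), Xn[va], y[va],
                                 [f"f{i}" for i in range(N_FEAT)],
                                 repeats=10, seed=9)
    assert imp.ranked_features()[0] == "f2"
    assert imp.importances[2] > 0
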