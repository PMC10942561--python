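"""MLP classification protocol for kinematic feature tables.

Implements min-max normalization, a four-layer fully connected network
(three hidden layers each followed by batch normalization and leaky ReLU,
a sigmoid output), binary cross-entropy optimized with Adam whose learning
rate drops permanently from 1e-5 to 1e-6 at the first epoch whose training
accuracy reaches 95%, 200 epochs of training, stratified 10-fold
cross-validation, and permutation feature importance measured as the
increase in validation loss when one feature column is shuffled.

The network, batch-norm statistics, back-propagation and Adam updates are
implemented directly on NumPy arrays: the model is small (nine inputs,
hidden widths 64/32/16) and a self-contained implementation keeps every
run bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .errors import ConfigError

__all__ = [
    "DEFAULT_FEATURES",
    "ClassifierConfig",
    "NormalizationParams",
    "minmax_normalize",
    "MLP",
    "TrainResult",
    "train_mlp",
    "FoldResult",
    "CVResult",
    "cross_validate",
    "ImportanceResult",
    "permutation_importance",
    "column_permuted_loss",
    "cv_permutation_importance",
    "bce_loss",
]

#: The nine-parameter default feature set used for classification.
DEFAULT_FEATURES = (
    "reaction_time", "total_distance", "avg_velocity", "max_velocity",
    "time_to_peak_velocity", "avg_acceleration", "max_acceleration",
    "time_to_peak_acceleration", "mu_type2_rms",
)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_ADAM_BETAS = (0.9, 0.999)
_ADAM_EPS = 1e-8


@dataclass(frozen=True)
class ClassifierConfig:
    """Training protocol settings (defaults follow the study protocol;
    quantities the protocol leaves open -- hidden widths, batch size,
    loss, output-layer init -- are fixed as documented package defaults)."""

    feature_set: tuple = DEFAULT_FEATURES
    hidden_sizes: tuple = (64, 32, 16)
    leaky_slope: float = 0.01
    epochs: int = 200
    lr_initial: float = 1e-5
    lr_reduced: float = 1e-6
    lr_switch_train_acc: float = 0.95
    n_folds: int = 10
    batch_size: Optional[int] = 8
    seed: int = 0
    normalization_scope: str = "whole_dataset"

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not 0 < self.lr_reduced <= self.lr_initial:
            raise ConfigError("need 0 < lr_reduced <= lr_initial")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.batch_size is not None and self.batch_size < 2:
            raise ConfigError("batch_size must be >= 2 (batch norm) or None")
        if self.normalization_scope not in ("whole_dataset", "per_fold_train"):
            raise ConfigError(
                "normalization_scope must be whole_dataset or per_fold_train")


@dataclass(frozen=True)
class NormalizationParams:
    """Stored per-feature (min, max) of a min-max normalization."""

    mins: np.ndarray
    maxs: np.ndarray
    constant_mask: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        out = np.empty_like(np.asarray(X, float))
        safe = ~self.constant_mask
        out[:, safe] = (X[:, safe] - self.mins[safe]) / span[safe]
        out[:, self.constant_mask] = 0.5
        return out


def minmax_normalize(X: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Min-max normalize columns to [0, 1]; constant columns map to 0.5."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ConfigError("features must be finite for normalization")
    mins, maxs = X.min(axis=0), X.max(axis=0)
    params = NormalizationParams(mins=mins, maxs=maxs,
                                 constant_mask=(maxs == mins))
    return params.apply(X), params


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clipping."""
    p = np.clip(np.asarray(p, float).ravel(), 1e-7, 1.0 - 1e-7)
    y = np.asarray(y, float).ravel()
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class MLP:
    """Four-layer batch-normalized MLP with a sigmoid output.

    Layer stack: FC(d->h1)-BN-LeakyReLU-FC(h1->h2)-BN-LeakyReLU-
    FC(h2->h3)-BN-LeakyReLU-FC(h3->1)-sigmoid.  Hidden weights use
    He-normal initialization; the output layer starts near zero so the
    decision direction is learned rather than inherited from the random
    init (relevant at the protocol's very small learning rate).
    """

    def __init__(self, n_in: int, hidden: Sequence[int], leaky_slope: float,
                 rng: np.random.Generator):
        self.leaky_slope = float(leaky_slope)
        sizes = [n_in, *hidden]
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        for i in range(3):
            fan_in, fan_out = sizes[i], sizes[i + 1]
            self.params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                              size=(fan_in, fan_out))
            self.params[f"b{i}"] = np.zeros(fan_out)
            self.params[f"g{i}"] = np.ones(fan_out)
            self.params[f"beta{i}"] = np.zeros(fan_out)
            self.running[f"mean{i}"] = np.zeros(fan_out)
            self.running[f"var{i}"] = np.ones(fan_out)
        self.params["W3"] = rng.normal(0.0, 1e-2, size=(sizes[3], 1))
        self.params["b3"] = np.zeros(1)

    # ---- forward -----------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool):
        cache = {"X": X}
        h = X
        for i in range(3):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                n = z.shape[0]
                self.running[f"mean{i}"] = ((1 - _BN_MOMENTUM) * self.running[f"mean{i}"]
                                            + _BN_MOMENTUM * mu)
                var_unbiased = var * n / (n - 1) if n > 1 else var
                self.running[f"var{i}"] = ((1 - _BN_MOMENTUM) * self.running[f"var{i}"]
                                           + _BN_MOMENTUM * var_unbiased)
            else:
                mu = self.running[f"mean{i}"]
                var = self.running[f"var{i}"]
            ivar = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z - mu) * ivar
            a = self.params[f"g{i}"] * xhat + self.params[f"beta{i}"]
            h_next = np.where(a > 0, a, self.leaky_slope * a)
            cache[f"h{i}"] = h
            cache[f"xhat{i}"] = xhat
            cache[f"ivar{i}"] = ivar
            cache[f"a{i}"] = a
            h = h_next
        logits = h @ self.params["W3"] + self.params["b3"]
        p = 1.0 / (1.0 + np.exp(-logits))
        cache["h3"] = h
        cache["p"] = p
        return p.ravel(), cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p, _ = self._forward(np.asarray(X, float), training=False)
        return p

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    # ---- backward ----------------------------------------------------
    def _backward(self, cache, y: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        p = cache["p"]
        n = p.shape[0]
        dz = (p - y.reshape(-1, 1)) / n  # dL/dlogits for sigmoid + BCE
        grads["W3"] = cache["h3"].T @ dz
        grads["b3"] = dz.sum(axis=0)
        dh = dz @ self.params["W3"].T
        for i in range(2, -1, -1):
            a = cache[f"a{i}"]
            da = dh * np.where(a > 0, 1.0, self.leaky_slope)
            xhat = cache[f"xhat{i}"]
            grads[f"g{i}"] = (da * xhat).sum(axis=0)
            grads[f"beta{i}"] = da.sum(axis=0)
            dxhat = da * self.params[f"g{i}"]
            m = a.shape[0]
            ivar = cache[f"ivar{i}"]
            dzbn = (ivar / m) * (m * dxhat - dxhat.sum(axis=0)
                                 - xhat * (dxhat * xhat).sum(axis=0))
            grads[f"W{i}"] = cache[f"h{i}"].T @ dzbn
            grads[f"b{i}"] = dzbn.sum(axis=0)
            dh = dzbn @ self.params[f"W{i}"].T
        return grads

    def state_dict(self) -> dict:
        return {"params": copy.deepcopy(self.params),
                "running": copy.deepcopy(self.running)}

    def load_state_dict(self, state: dict) -> None:
        self.params = copy.deepcopy(state["params"])
        self.running = copy.deepcopy(state["running"])


class _Adam:
    def __init__(self, params: dict[str, np.ndarray]):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        b1, b2 = _ADAM_BETAS
        self.t += 1
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)


@dataclass
class TrainResult:
    """A trained model plus its per-epoch history and best-epoch snapshot."""

    model: MLP
    train_accuracy: np.ndarray      # per epoch, evaluation mode
    validation_loss: np.ndarray     # per epoch, evaluation mode
    best_epoch: int
    best_validation_loss: float
    lr_switch_epoch: Optional[int]
    _best_state: dict = field(repr=False, default=None)

    def best_model(self) -> MLP:
        m = copy.copy(self.model)
        m.load_state_dict(self._best_state)
        return m


def _validate_labels(y) -> np.ndarray:
    y = np.asarray(y)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0, 1])) or uniq.size > 2:
        raise ConfigError(f"labels must be binary 0/1, got {uniq}")
    return y.astype(float)


def train_mlp(X_train: np.ndarray, y_train, cfg: ClassifierConfig,
              X_val: np.ndarray, y_val, seed: Optional[int] = None) -> TrainResult:
    """Train the MLP for exactly ``cfg.epochs`` epochs.

    Training accuracy and validation loss are evaluated at every epoch end
    in evaluation mode (batch-norm running statistics); the epoch with the
    lowest validation loss is snapshotted.  The learning rate drops to
    ``cfg.lr_reduced`` permanently after the first epoch whose training
    accuracy reaches ``cfg.lr_switch_train_acc``.
    """
    X_train = np.asarray(X_train, float)
    X_val = np.asarray(X_val, float)
    y_train = _validate_labels(y_train)
    y_val = _validate_labels(y_val)
    if X_train.shape[1] != len(cfg.feature_set):
        raise ConfigError(
            f"expected {len(cfg.feature_set)} features, got {X_train.shape[1]}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    model = MLP(X_train.shape[1], cfg.hidden_sizes, cfg.leaky_slope, rng)
    opt = _Adam(model.params)
    n = X_train.shape[0]
    batch = n if cfg.batch_size is None else min(cfg.batch_size, n)

    lr = cfg.lr_initial
    switch_epoch = None
    accs = np.empty(cfg.epochs)
    vlosses = np.empty(cfg.epochs)
    best_loss, best_epoch, best_state = np.inf, -1, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            if idx.size < 2:
                continue  # batch norm needs >= 2 samples
            _, cache = model._forward(X_train[idx], training=True)
            grads = model._backward(cache, y_train[idx])
            opt.step(model.params, grads, lr)
        accs[epoch] = float(np.mean(model.predict(X_train) == y_train))
        vlosses[epoch] = bce_loss(model.predict_proba(X_val), y_val)
        if vlosses[epoch] < best_loss:
            best_loss = vlosses[epoch]
            best_epoch = epoch
            best_state = model.state_dict()
        if switch_epoch is None and accs[epoch] >= cfg.lr_switch_train_acc:
            switch_epoch = epoch
            lr = cfg.lr_reduced
    return TrainResult(model=model, train_accuracy=accs, validation_loss=vlosses,
                       best_epoch=best_epoch, best_validation_loss=float(best_loss),
                       lr_switch_epoch=switch_epoch, _best_state=best_state)


@dataclass
class FoldResult:
    fold: int
    accuracy: float
    best_validation_loss: float
    val_indices: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    model: MLP
    lr_switch_epoch: Optional[int]


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    fold_val_losses: np.ndarray
    confusion: np.ndarray  # rows true class, cols predicted
    folds: list


def _feature_matrix(table, cfg: ClassifierConfig) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        missing = [c for c in cfg.feature_set if c not in table.columns]
        if missing:
            raise ConfigError(f"feature table lacks columns: {missing}")
        return table.loc[:, list(cfg.feature_set)].to_numpy(dtype=float)
    X = np.asarray(table, float)
    if X.shape[1] != len(cfg.feature_set):
        raise ConfigError(
            f"expected {len(cfg.feature_set)} feature columns, got {X.shape[1]}")
    return X


def cross_validate(table, labels, cfg: ClassifierConfig = ClassifierConfig(),
                   groups: Optional[Sequence] = None) -> CVResult:
    """Stratified k-fold cross-validation of the MLP protocol.

    ``groups`` (e.g. subject ids) switches to stratified *grouped* folds
    that never split one subject's trials across train and validation.
    Normalization follows ``cfg.normalization_scope``: the study default
    fits min-max bounds on the whole dataset before splitting;
    ``per_fold_train`` refits them on each training split only.
    """
    X = _feature_matrix(table, cfg)
    y = _validate_labels(labels).astype(int)
    n = X.shape[0]
    if n < cfg.n_folds:
        raise ConfigError(f"n={n} is smaller than n_folds={cfg.n_folds}")
    class_counts = np.bincount(y, minlength=2)
    if np.any(class_counts < cfg.n_folds):
        raise ConfigError(
            "every class needs at least n_folds members for stratified folds")

    if cfg.normalization_scope == "whole_dataset":
        Xn_full, _ = minmax_normalize(X)
    rs = int(cfg.seed) % (2**31)
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=cfg.n_folds, shuffle=True,
                                        random_state=rs)
        split_iter = splitter.split(X, y, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                                   random_state=rs)
        split_iter = splitter.split(X, y)

    folds: list[FoldResult] = []
    confusion = np.zeros((2, 2), dtype=int)
    for fold, (tr, va) in enumerate(split_iter):
        if cfg.normalization_scope == "whole_dataset":
            X_tr, X_va = Xn_full[tr], Xn_full[va]
        else:
            X_tr, norm = minmax_normalize(X[tr])
            X_va = norm.apply(X[va])
        res = train_mlp(X_tr, y[tr], cfg, X_va, y[va],
                        seed=cfg.seed + 1000 * (fold + 1))
        best = res.best_model()
        pred = best.predict(X_va)
        acc = float(np.mean(pred == y[va]))
        for yi, pi in zip(y[va], pred):
            confusion[yi, pi] += 1
        folds.append(FoldResult(fold=fold, accuracy=acc,
                                best_validation_loss=res.best_validation_loss,
                                val_indices=va, X_val=X_va, y_val=y[va],
                                model=best, lr_switch_epoch=res.lr_switch_epoch))
    accs = np.array([f.accuracy for f in folds])
    losses = np.array([f.best_validation_loss for f in folds])
    return CVResult(fold_accuracies=accs, mean_accuracy=float(accs.mean()),
                    fold_val_losses=losses, confusion=confusion, folds=folds)


@dataclass
class ImportanceResult:
    feature_names: tuple
    importances: np.ndarray        # mean loss increase per feature
    base_loss: float
    ranks: np.ndarray              # permutation of 0..k-1, descending importance

    def ranked_features(self) -> list[str]:
        return [self.feature_names[i] for i in self.ranks]


def column_permuted_loss(model: MLP, X_val: np.ndarray, y_val,
                         feature_idx: int, permutation: np.ndarray) -> float:
    """Validation loss after reordering one feature column by
    ``permutation`` (the identity permutation reproduces the base loss)."""
    Xp = np.array(X_val, dtype=float, copy=True)
    Xp[:, feature_idx] = Xp[permutation, feature_idx]
    return bce_loss(model.predict_proba(Xp), np.asarray(y_val, float))


def permutation_importance(model: MLP, X_val: np.ndarray, y_val,
                           feature_names: Sequence[str], repeats: int = 10,
                           seed: int = 0) -> ImportanceResult:
    """Permutation feature importance on a validation set.

    For each feature, the column is shuffled (``repeats`` independent
    permutations), the model re-evaluated, and the importance reported as
    the mean permuted loss minus the unpermuted loss.
    """
    if repeats < 1:
        raise ConfigError("repeats must be >= 1")
    X_val = np.asarray(X_val, float)
    y_val = _validate_labels(y_val)
    rng = np.random.default_rng(seed)
    base = bce_loss(model.predict_proba(X_val), y_val)
    k = X_val.shape[1]
    imps = np.empty(k)
    for j in range(k):
        losses = [column_permuted_loss(model, X_val, y_val, j,
                                       rng.permutation(X_val.shape[0]))
                  for _ in range(repeats)]
        imps[j] = float(np.mean(losses) - base)
    ranks = np.argsort(-imps, kind="stable")
    return ImportanceResult(feature_names=tuple(feature_names),
                            importances=imps, base_loss=base, ranks=ranks)


def cv_permutation_importance(cv: CVResult, feature_names: Sequence[str],
                              repeats: int = 10, seed: int = 0) -> ImportanceResult:
    """Fold-averaged permutation importance over the CV held-out sets."""
    k = len(feature_names)
    acc = np.zeros(k)
    base = 0.0
    for f in cv.folds:
        res = permutation_importance(f.model, f.X_val, f.y_val, feature_names,
                                     repeats=repeats, seed=seed + f.fold)
        acc += res.importances
        base += res.base_loss
    acc /= len(cv.folds)
    base /= len(cv.folds)
    ranks = np.argsort(-acc, kind="stable")
    return ImportanceResult(feature_names=tuple(feature_names), importances=acc,
                            base_loss=base, ranks=ranks)
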