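"""The decoding engine.

Per time point, the feature vector is the scalp distribution of voltage
over the channels.  Trials of each class are partitioned into k equal
groups; the trials within a (group, class) cell are averaged into a single
scalp vector (trading trial count for signal-to-noise); training uses the
averaged vectors of k-1 groups, testing the held-out group's vectors.  The
classifier is ECOC with a one-vs-rest coding of linear soft-margin SVMs
(C = 1, features standardized per training fold); prediction minimizes the
aggregate hinge loss over the binary learners, ties to the lowest class
code.  The whole procedure is repeated with fresh random partitions
(10 iterations by default), giving n_classes x k x n_iterations = 120
decoding attempts per time point with the defaults.

The fold assignment is drawn once per iteration and shared across all time
points; the per-iteration RNGs are derived from the config seed by a fixed
splitting rule, so a windowed time-course run and a temporal-generalization
run with the same seed use identical partitions (their matrix diagonal and
time course then agree exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _svm
from .core import (AccuracySeries, ConfigError, ConfusionMatrix, DataError,
                   DecodeConfig, EpochSet, PredictionStore)
from .preprocess import smooth_values

__all__ = ["FoldAssignment", "GenMatrix", "partition_balanced",
           "average_by_group", "fit_predict_ecoc", "decode_timecourse",
           "decode_crosstime", "decode_crossdim", "confusion_by_period"]

fit_predict_ecoc = _svm.fit_predict_ecoc


@dataclass(eq=False)
class FoldAssignment:
    """Per class, a partition of that class's trial indices into k groups of
    identical size floor(n_class/k); the n_class mod k leftovers are dropped
    at random (with 160 trials per class and k=3: groups of 53, 1 dropped)."""

    groups: dict  # class code -> (k, m_class) array of trial indices
    dropped: dict  # class code -> array of discarded trial indices
    n_folds: int

    def class_codes(self):
        return sorted(self.groups)


def partition_balanced(class_labels: np.ndarray, k: int,
                       rng: np.random.Generator | int) -> FoldAssignment:
    """Randomly partition each class's trials into k equal-sized groups."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    class_labels = np.asarray(class_labels)
    groups, dropped = {}, {}
    for c in np.unique(class_labels):
        idx = np.flatnonzero(class_labels == c)
        if idx.size < k:
            raise DataError(f"class {c} has {idx.size} trials, fewer than k={k}")
        perm = rng.permutation(idx)
        m = idx.size // k
        groups[int(c)] = perm[: m * k].reshape(k, m)
        dropped[int(c)] = perm[m * k:]
    return FoldAssignment(groups=groups, dropped=dropped, n_folds=k)


def group_class_means(data: np.ndarray, assignment: FoldAssignment) -> np.ndarray:
    """Mean scalp vector per (group, class) at every time point.

    data: (trials, channels, times) -> (k, n_classes, channels, times).
    """
    codes = assignment.class_codes()
    k = assignment.n_folds
    out = np.empty((k, len(codes)) + data.shape[1:], dtype=np.float64)
    for j, c in enumerate(codes):
        for g in range(k):
            out[g, j] = data[assignment.groups[c][g]].mean(axis=0)
    return out


def average_by_group(epochs: EpochSet, assignment: FoldAssignment, t: int) -> np.ndarray:
    """Averaged scalp vectors at time index ``t``: (k, n_classes, channels)."""
    return group_class_means(epochs.data.astype(np.float64), assignment)[..., t]


def _iteration_rngs(seed: int, n_iterations: int):
    """Fixed seed-splitting rule shared by all decoding modes."""
    return [np.random.default_rng(np.random.SeedSequence([int(seed), it]))
            for it in range(n_iterations)]


def _check_balanced(class_labels: np.ndarray, n_classes: int, k: int) -> None:
    present = np.unique(class_labels)
    expected = np.arange(1, n_classes + 1)
    missing = set(expected) - set(present)
    if missing:
        raise DataError(f"classes absent from the labels: {sorted(missing)}")


def decode_timecourse(epochs: EpochSet, class_labels: np.ndarray,
                      config: DecodeConfig, seed: int | None = None):
    """Decode the class label independently at every time point.

    Returns ``(series, store)``: the accuracy series (smoothed with the
    config's 5-point moving window) and the prediction store holding every
    attempt's (predicted, true) pair, from which the raw series and
    permutation nulls can be recomputed without retraining.
    """
    class_labels = np.asarray(class_labels)
    C, k = config.n_classes, config.n_folds
    _check_balanced(class_labels, C, k)
    data = epochs.data.astype(np.float64)
    T = epochs.n_times
    ch = epochs.n_channels
    use_seed = config.rng_seed if seed is None else seed
    n_it = config.n_iterations

    # Every (iteration, fold, time point) training problem has the same shape
    # and the same row-to-class layout, so all of them are solved in one
    # batched call (the batch axis enumerates iteration x fold x time).
    Xtr = np.empty((n_it, k, T, (k - 1) * C, ch))
    Xte = np.empty((n_it, k, T, C, ch))
    codes = None
    for it, rng in enumerate(_iteration_rngs(use_seed, n_it)):
        assignment = partition_balanced(class_labels, k, rng)
        codes = assignment.class_codes()
        means = group_class_means(data, assignment)          # (k, C, ch, T)
        for fold in range(k):
            train = np.delete(means, fold, axis=0)           # (k-1, C, ch, T)
            Xtr[it, fold] = train.reshape((k - 1) * C, ch, T).transpose(2, 0, 1)
            Xte[it, fold] = means[fold].transpose(2, 0, 1)   # (T, C, ch)

    B = n_it * k * T
    Ztr, Zte = _svm.standardize_fold(Xtr.reshape(B, (k - 1) * C, ch),
                                     Xte.reshape(B, C, ch))
    train_codes = np.tile(codes, k - 1)
    Y = np.where(train_codes[None, :] == np.arange(1, C + 1)[:, None], 1.0, -1.0)
    W = _svm.train_ovr_batch(Ztr, Y, C=config.svm_c)
    D = _svm.ecoc_decision(W, Zte)
    pred = _svm.ecoc_predict_from_decision(D)                # (B, C_rows)
    predicted = pred.reshape(n_it, k, T, C).transpose(0, 1, 3, 2)

    true = np.tile(np.asarray(codes, dtype=np.int8), n_it * k)
    store = PredictionStore(
        predicted=predicted.reshape(-1, T),
        true=true,
        n_classes=C,
        times=epochs.times,
        n_iterations=config.n_iterations,
        n_folds=k,
    )
    raw = store.accuracy()
    series = AccuracySeries(
        values=smooth_values(raw, config.smooth_points),
        times=epochs.times,
        n_attempts=store.n_attempts,
    )
    return series, store


@dataclass(eq=False)
class GenMatrix:
    """Temporal-generalization accuracy at (train window, test window)."""

    accuracy: np.ndarray
    window_times: np.ndarray

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        self.window_times = np.asarray(self.window_times, dtype=float)
        n = self.window_times.shape[0]
        if self.accuracy.shape != (n, n):
            raise ConfigError("generalization matrix must be square over the window axis")


def decode_crosstime(epochs: EpochSet, class_labels: np.ndarray,
                     config: DecodeConfig, seed: int | None = None) -> GenMatrix:
    """Train at each time window, test at every window (cross-time decoding).

    ``epochs`` must already be window-averaged (100-ms windows by default,
    giving a 20 x 20 matrix over a [-500, 1500) ms epoch).  The fold
    structure, seeds and classifier match :func:`decode_timecourse`, so the
    matrix diagonal equals the windowed time-course run exactly.  Test
    vectors are standardized with the training window's fold statistics.
    """
    class_labels = np.asarray(class_labels)
    C, k = config.n_classes, config.n_folds
    _check_balanced(class_labels, C, k)
    data = epochs.data.astype(np.float64)
    T = epochs.n_times
    ch = epochs.n_channels
    use_seed = config.rng_seed if seed is None else seed
    n_it = config.n_iterations

    # identical training batch layout to decode_timecourse (same seeds, same
    # partitions, same solver batch) so the diagonal matches it exactly
    Xtr = np.empty((n_it, k, T, (k - 1) * C, ch))
    Xte = np.empty((n_it, k, T, C, ch))
    codes = None
    for it, rng in enumerate(_iteration_rngs(use_seed, n_it)):
        assignment = partition_balanced(class_labels, k, rng)
        codes = assignment.class_codes()
        means = group_class_means(data, assignment)
        for fold in range(k):
            train = np.delete(means, fold, axis=0)
            Xtr[it, fold] = train.reshape((k - 1) * C, ch, T).transpose(2, 0, 1)
            Xte[it, fold] = means[fold].transpose(2, 0, 1)

    B = n_it * k * T
    Xtr = Xtr.reshape(B, (k - 1) * C, ch)
    Xte = Xte.reshape(n_it * k, T, C, ch)
    mu = Xtr.mean(axis=1, keepdims=True)                     # (B, 1, ch)
    sd = Xtr.std(axis=1, keepdims=True, ddof=1)
    sd = np.where(sd > 0.0, sd, 1.0)
    Ztr = np.concatenate([(Xtr - mu) / sd, np.ones(Xtr.shape[:2] + (1,))], axis=-1)
    train_codes = np.tile(codes, k - 1)
    Y = np.where(train_codes[None, :] == np.arange(1, C + 1)[:, None], 1.0, -1.0)
    W = _svm.train_ovr_batch(Ztr, Y, C=config.svm_c)         # (C, B, f)

    # standardize every test window's rows with every train window's fold
    # statistics: expanded batch axis enumerates (iter, fold, train_t, test_t)
    mu = mu.reshape(n_it * k, T, 1, ch)
    sd = sd.reshape(n_it * k, T, 1, ch)
    Zte = (Xte[:, None, :, :, :] - mu[:, :, None, :, :]) / sd[:, :, None, :, :]
    Zte = np.concatenate([Zte, np.ones(Zte.shape[:-1] + (1,))], axis=-1)
    Zte = np.ascontiguousarray(Zte.reshape(n_it * k * T * T, C, ch + 1))
    W_exp = np.ascontiguousarray(
        np.repeat(W.reshape(C, n_it * k, T, 1, ch + 1), T, axis=3).reshape(C, -1, ch + 1))
    D = _svm.ecoc_decision(W_exp, Zte)
    pred = _svm.ecoc_predict_from_decision(D)                # (B*T, C_rows)
    pred = pred.reshape(n_it * k, T, T, C)
    correct = (pred == np.asarray(codes, dtype=np.int8)[None, None, None, :]).sum(axis=(0, 3))
    return GenMatrix(accuracy=correct / (n_it * k * C), window_times=epochs.times)


def decode_crossdim(epochs: EpochSet, target_labels: np.ndarray,
                    control_labels: np.ndarray, config: DecodeConfig):
    """Cross-dimension decoding: train on 3 of the 4 levels of the control
    (task-irrelevant) dimension, test on the held-out level.

    Training rows are within-class averages computed per control level
    (3 rows per class), the test row the held-out level's class average, so
    no stimulus image is shared between training and testing.  The rotation
    over the 4 control levels replaces random subsampling (no iterations);
    accuracy per time point averages 4 rotations x n_classes attempts and is
    then smoothed.
    """
    target_labels = np.asarray(target_labels)
    control_labels = np.asarray(control_labels)
    C = config.n_classes
    _check_balanced(target_labels, C, 1)
    levels = np.arange(1, C + 1)
    data = epochs.data.astype(np.float64)
    T = epochs.n_times

    # cell means: (control level, target class, channels, times)
    cell = np.empty((C, C, epochs.n_channels, T))
    for vi, v in enumerate(levels):
        for ci, c in enumerate(levels):
            rows = np.flatnonzero((control_labels == v) & (target_labels == c))
            if rows.size == 0:
                raise DataError(f"empty cell: target class {c} x control level {v}")
            cell[vi, ci] = data[rows].mean(axis=0)

    predicted = np.empty((C, C, T), dtype=np.int8)  # (rotation, test row, T)
    for vi in range(C):
        train = np.delete(cell, vi, axis=0)                   # (3, C, ch, T)
        Xtr = train.reshape((C - 1) * C, epochs.n_channels, T).transpose(2, 0, 1)
        Xte = cell[vi].transpose(2, 0, 1)
        Ztr, Zte = _svm.standardize_fold(Xtr, Xte)
        train_codes = np.tile(levels, C - 1)
        Y = np.where(train_codes[None, :] == levels[:, None], 1.0, -1.0)
        W = _svm.train_ovr_batch(Ztr, Y, C=config.svm_c)
        D = _svm.ecoc_decision(W, Zte)
        predicted[vi] = _svm.ecoc_predict_from_decision(D).T

    store = PredictionStore(
        predicted=predicted.reshape(-1, T),
        true=np.tile(levels.astype(np.int8), C),
        n_classes=C,
        times=epochs.times,
        n_iterations=1,
        n_folds=C,
    )
    raw = store.accuracy()
    series = AccuracySeries(
        values=smooth_values(raw, config.smooth_points),
        times=epochs.times,
        n_attempts=store.n_attempts,
    )
    return series, store


def confusion_by_period(store: PredictionStore, periods) -> list:
    """Row-normalized confusion matrix per time period (ms intervals,
    half-open), pooling predictions over attempts and time points."""
    out = []
    counts = store.counts()
    for (t0, t1) in periods:
        mask = (store.times >= t0) & (store.times < t1)
        if not mask.any():
            raise DataError(f"period [{t0}, {t1}) ms contains no time points")
        pooled = counts[:, :, mask].sum(axis=-1).astype(float)
        row_tot = pooled.sum(axis=1, keepdims=True)
        matrix = np.divide(pooled, row_tot, out=np.zeros_like(pooled), where=row_tot > 0)
        out.append(ConfusionMatrix(matrix=matrix, period_ms=(float(t0), float(t1)),
                                   n_pooled=int(pooled.sum())))
    return out
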