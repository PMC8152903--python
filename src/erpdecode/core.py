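"""Domain containers and trial bookkeeping for multivariate ERP decoding.

The central object is the :class:`EpochSet`: a participant-level tensor of
epoched EEG voltages (trials x channels x time samples, in microvolts)
together with per-trial labels on two stimulus dimensions -- face identity
and facial expression, four levels each.  Every trial carries both labels
because the task requires participants to encode both dimensions on every
trial; which one is probed is unknown until the test.

Time is expressed in milliseconds relative to stimulus onset.  Sample ``i``
(0-based) corresponds to ``t_start_ms + i * 1000 / fs``; the epoch interval
is half-open in samples, so a [-500, +1500) ms epoch at 250 Hz has exactly
500 samples (the last one at +1496 ms).

Label-reorganization operations live here as well: collapsing the 16-cell
design onto one dimension, removing flagged trials, and relabeling each
trial by the face shown on the *previous* trial (used to probe reactivation
of working-memory content after the next stimulus appears).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DataError",
    "ConfigError",
    "TrialLabels",
    "EpochSet",
    "DecodeConfig",
    "AccuracySeries",
    "PredictionStore",
    "ConfusionMatrix",
    "save_epochs",
    "load_epochs",
    "save_store",
    "load_store",
    "save_labels_tsv",
    "load_labels_tsv",
    "exclude_trials",
    "collapse_dimension",
    "relabel_previous_trial",
    "derive_seed",
]

N_LEVELS = 4  # four identities x four expressions

PAYLOAD_NAME = "epochs_f32.dat"
SIDECAR_NAME = "epochs.json"


class FormatError(ValueError):
    """Raised when a stored epoch container is internally inconsistent."""


class DataError(ValueError):
    """Raised when the data cannot support the requested operation."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


def derive_seed(*keys: int) -> int:
    """Derive a child seed (< 2**31) from a master seed plus context keys.

    One fixed splitting rule is used everywhere so that any stage of the
    pipeline is reproducible bit-for-bit from the master seed alone.
    """
    ss = np.random.SeedSequence(list(keys))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# labels


@dataclass(eq=False)
class TrialLabels:
    """Per-trial categorical labels and bookkeeping flags.

    identity / expression are 1-based codes in {1..4}.  ``trial_index`` is
    the original position within the recording session and is the single
    source of truth for "previous trial".  ``is_post_test`` marks trials
    immediately following a memory test (excluded from analysis because the
    report could contaminate the next epoch); ``is_first`` marks the
    session's first trial (no previous trial exists).
    """

    identity: np.ndarray
    expression: np.ndarray
    trial_index: np.ndarray
    is_post_test: np.ndarray = field(default=None)
    is_first: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.identity = np.asarray(self.identity, dtype=np.int64)
        self.expression = np.asarray(self.expression, dtype=np.int64)
        self.trial_index = np.asarray(self.trial_index, dtype=np.int64)
        n = self.identity.shape[0]
        if self.is_post_test is None:
            self.is_post_test = np.zeros(n, dtype=bool)
        if self.is_first is None:
            self.is_first = np.zeros(n, dtype=bool)
        self.is_post_test = np.asarray(self.is_post_test, dtype=bool)
        self.is_first = np.asarray(self.is_first, dtype=bool)
        for name in ("expression", "trial_index", "is_post_test", "is_first"):
            if getattr(self, name).shape != (n,):
                raise FormatError(f"labels field '{name}' length does not match identity ({n})")
        for name in ("identity", "expression"):
            vals = getattr(self, name)
            if n and not np.isin(vals, np.arange(1, N_LEVELS + 1)).all():
                raise FormatError(f"labels field '{name}' must contain codes in 1..{N_LEVELS}")

    def __len__(self) -> int:
        return self.identity.shape[0]

    def subset(self, idx) -> "TrialLabels":
        return TrialLabels(
            identity=self.identity[idx],
            expression=self.expression[idx],
            trial_index=self.trial_index[idx],
            is_post_test=self.is_post_test[idx],
            is_first=self.is_first[idx],
        )

    def equals(self, other: "TrialLabels") -> bool:
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("identity", "expression", "trial_index", "is_post_test", "is_first")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": self.trial_index,
                "identity": self.identity,
                "expression": self.expression,
                "is_post_test": self.is_post_test.astype(int),
                "is_first": self.is_first.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialLabels":
        required = {"trial_index", "identity", "expression", "is_post_test", "is_first"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"labels table missing columns: {sorted(missing)}")
        return cls(
            identity=df["identity"].to_numpy(),
            expression=df["expression"].to_numpy(),
            trial_index=df["trial_index"].to_numpy(),
            is_post_test=df["is_post_test"].to_numpy().astype(bool),
            is_first=df["is_first"].to_numpy().astype(bool),
        )


# ---------------------------------------------------------------------------
# epochs


@dataclass(eq=False)
class EpochSet:
    """Epoched multichannel EEG voltages with aligned trial labels.

    ``data`` is float32, shape (trials, channels, times), in microvolts.
    """

    data: np.ndarray
    fs: float
    t_start_ms: float
    channel_names: tuple
    participant_id: str
    labels: TrialLabels

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise FormatError("data must be a 3-d (trials, channels, times) array")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) == 0:
            raise FormatError("channel count must be positive")
        if self.data.shape[1] != len(self.channel_names):
            raise FormatError(
                f"channel_names declares {len(self.channel_names)} channels "
                f"but payload has {self.data.shape[1]}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise FormatError(
                f"labels declare {len(self.labels)} trials but payload has {self.data.shape[0]}"
            )
        if self.fs <= 0:
            raise FormatError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time of each sample, ms relative to stimulus onset."""
        return self.t_start_ms + np.arange(self.n_times) * self.dt_ms

    @property
    def t_end_ms(self) -> float:
        """Exclusive end of the epoch (half-open interval in samples)."""
        return self.t_start_ms + self.n_times * self.dt_ms

    def subset(self, idx) -> "EpochSet":
        return replace(self, data=self.data[idx], labels=self.labels.subset(idx))

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), labels=self.labels.subset(slice(None)))


def save_epochs(epochs: EpochSet, path) -> Path:
    """Write an :class:`EpochSet` as raw little-endian float32 + JSON sidecar.

    ``path`` is a directory; it receives ``epochs_f32.dat`` (C-order payload)
    and ``epochs.json``.  Round-trips bit-exactly with :func:`load_epochs`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = np.ascontiguousarray(epochs.data, dtype="<f4")
    (path / PAYLOAD_NAME).write_bytes(payload.tobytes())
    sidecar = {
        "participant_id": epochs.participant_id,
        "fs": epochs.fs,
        "t_start_ms": epochs.t_start_ms,
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_times": epochs.n_times,
        "channel_names": list(epochs.channel_names),
        "labels": epochs.labels.to_frame().to_dict(orient="list"),
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_epochs(path) -> EpochSet:
    """Load an epoch container written by :func:`save_epochs`."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    payload_path = path / PAYLOAD_NAME
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    if not payload_path.exists():
        raise FormatError(f"missing payload {payload_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("participant_id", "fs", "t_start_ms", "n_trials", "n_channels", "n_times",
                "channel_names", "labels"):
        if key not in meta:
            raise FormatError(f"sidecar missing field '{key}'")
    raw = np.frombuffer(payload_path.read_bytes(), dtype="<f4")
    expected = meta["n_trials"] * meta["n_channels"] * meta["n_times"]
    if raw.size != expected:
        raise FormatError(
            f"payload has {raw.size} values but sidecar declares "
            f"n_trials*n_channels*n_times = {expected}"
        )
    data = raw.reshape(meta["n_trials"], meta["n_channels"], meta["n_times"])
    if len(meta["channel_names"]) != meta["n_channels"]:
        raise FormatError("sidecar field 'channel_names' length disagrees with 'n_channels'")
    labels = TrialLabels.from_frame(pd.DataFrame(meta["labels"]))
    return EpochSet(
        data=data,
        fs=float(meta["fs"]),
        t_start_ms=float(meta["t_start_ms"]),
        channel_names=tuple(meta["channel_names"]),
        participant_id=str(meta["participant_id"]),
        labels=labels,
    )


def save_store(store: "PredictionStore", path) -> None:
    """Persist a prediction store (.npz); the substrate for permutation
    nulls and confusion matrices without re-decoding."""
    np.savez(path, predicted=store.predicted, true=store.true,
             times=store.times, n_classes=store.n_classes,
             n_iterations=store.n_iterations, n_folds=store.n_folds)


def load_store(path) -> "PredictionStore":
    with np.load(path) as z:
        return PredictionStore(
            predicted=z["predicted"], true=z["true"], times=z["times"],
            n_classes=int(z["n_classes"]), n_iterations=int(z["n_iterations"]),
            n_folds=int(z["n_folds"]))


def save_labels_tsv(labels: TrialLabels, path) -> None:
    labels.to_frame().to_csv(path, sep="\t", index=False)


def load_labels_tsv(path) -> TrialLabels:
    return TrialLabels.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# decoding configuration and result containers


@dataclass(frozen=True)
class DecodeConfig:
    """Parameters of the decoding pipeline.

    Defaults follow the standard averaged-ERP decoding recipe: 4 classes,
    3-fold cross-validation with within-fold trial averaging, 10 subsampling
    iterations (120 decoding attempts per time point), a 6-Hz low-pass before
    decoding, 5-point smoothing of the accuracy series afterwards (+/-8 ms at
    250 Hz), and 100-ms window averaging for temporal generalization.
    """

    n_classes: int = 4
    n_folds: int = 3
    n_iterations: int = 10
    lowpass_hz: float = 6.0
    smooth_points: int = 5
    svm_c: float = 1.0
    window_ms: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.smooth_points < 1 or self.smooth_points % 2 == 0:
            raise ConfigError("smooth_points must be an odd positive integer")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes

    @property
    def n_attempts(self) -> int:
        """Decoding attempts aggregated per time point."""
        return self.n_classes * self.n_folds * self.n_iterations

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "n_folds": self.n_folds,
            "n_iterations": self.n_iterations,
            "lowpass_hz": self.lowpass_hz,
            "smooth_points": self.smooth_points,
            "svm_c": self.svm_c,
            "window_ms": self.window_ms,
            "rng_seed": self.rng_seed,
        }


@dataclass(eq=False)
class AccuracySeries:
    """Decoding accuracy per time point (proportion correct in [0, 1])."""

    values: np.ndarray
    times: np.ndarray
    n_attempts: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise FormatError("values and times must have the same length")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise FormatError("accuracy values must lie in [0, 1]")


@dataclass(eq=False)
class PredictionStore:
    """Predicted vs true class for every decoding attempt at every time point.

    ``predicted`` has shape (attempts, times) and ``true`` shape (attempts,);
    the attempt axis enumerates (iteration, fold, test row) in order.  The
    store is sufficient to recompute the accuracy series exactly and -- by
    relabeling the true classes -- to build permutation null distributions
    without retraining any classifier.
    """

    predicted: np.ndarray
    true: np.ndarray
    n_classes: int
    times: np.ndarray
    n_iterations: int
    n_folds: int

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=np.int8)
        self.true = np.asarray(self.true, dtype=np.int8)
        self.times = np.asarray(self.times, dtype=float)
        if self.predicted.ndim != 2:
            raise FormatError("predicted must be (attempts, times)")
        if self.true.shape != (self.predicted.shape[0],):
            raise FormatError("true must have one entry per attempt")
        if self.times.shape != (self.predicted.shape[1],):
            raise FormatError("times must have one entry per time point")

    @property
    def n_attempts(self) -> int:
        return self.predicted.shape[0]

    def accuracy(self) -> np.ndarray:
        """Raw (unsmoothed) accuracy per time point."""
        return (self.predicted == self.true[:, None]).mean(axis=0)

    def counts(self) -> np.ndarray:
        """Confusion counts per time point, shape (true, predicted, times)."""
        C = self.n_classes
        out = np.zeros((C, C, self.predicted.shape[1]), dtype=np.int64)
        for ct in range(1, C + 1):
            rows = self.predicted[self.true == ct]
            for cp in range(1, C + 1):
                out[ct - 1, cp - 1] = (rows == cp).sum(axis=0)
        return out

    def accuracy_relabeled(self, relabel: np.ndarray) -> np.ndarray:
        """Accuracy series after applying a class-code permutation to the
        true labels (the same relabeling at every time point)."""
        relabel = np.asarray(relabel)
        new_true = relabel[self.true - 1].astype(np.int8)
        return (self.predicted == new_true[:, None]).mean(axis=0)


@dataclass(eq=False)
class ConfusionMatrix:
    """Row-normalized (true x predicted) classification probabilities pooled
    over a time period."""

    matrix: np.ndarray
    period_ms: tuple
    n_pooled: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise FormatError("confusion matrix must be square")


# ---------------------------------------------------------------------------
# trial bookkeeping operations


def exclude_trials(epochs: EpochSet, drop_post_test: bool = True,
                   drop_first: bool = False) -> EpochSet:
    """Drop flagged trials (post-test and/or the session's first trial).

    Returns a copy; label alignment is preserved.  Idempotent.  A 720-trial
    session with 80 post-test flags reduces to the 640 analysis trials.
    """
    keep = np.ones(epochs.n_trials, dtype=bool)
    if drop_post_test:
        keep &= ~epochs.labels.is_post_test
    if drop_first:
        keep &= ~epochs.labels.is_first
    if not keep.any():
        raise DataError("exclusion removed every trial")
    if keep.all():
        return epochs.copy()
    return epochs.subset(keep)


def collapse_dimension(labels: TrialLabels, target: str) -> np.ndarray:
    """Per-trial class labels for one dimension, collapsed over the other.

    With the balanced 16-cell design this yields total/4 trials per class
    (160 out of 640 with the default session).
    """
    if target == "identity":
        return labels.identity.copy()
    if target == "expression":
        return labels.expression.copy()
    raise ValueError(f"unknown target dimension: {target!r}")


def relabel_previous_trial(labels: TrialLabels, target: str):
    """Relabel each trial by the *previous* trial's class on ``target``.

    Session order is given by ``trial_index``; the first trial in the
    session is necessarily dropped (its previous trial is undefined).
    Returns ``(prev_labels, positions)`` where ``positions`` are row indices
    into ``labels`` (in session order, first trial excluded) and
    ``prev_labels[i]`` is the target-dimension class of the trial preceding
    ``positions[i]``.

    The task design guarantees consecutive trials never repeat either
    dimension, so the new label never equals the trial's own current label.
    """
    if target not in ("identity", "expression"):
        raise ValueError(f"unknown target dimension: {target!r}")
    n = len(labels)
    if n < 2:
        raise DataError("previous-trial relabeling requires at least 2 trials")
    order = np.argsort(labels.trial_index, kind="stable")
    dim = collapse_dimension(labels, target)
    positions = order[1:]
    prev_labels = dim[order[:-1]]
    return prev_labels, positions
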