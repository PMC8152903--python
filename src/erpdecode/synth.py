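"""Synthetic multichannel ERP epochs with known ground truth.

The generator emulates the statistical structure the decoding analysis
assumes, so every downstream stage can be tested against parameters it
should recover:

* class-specific scalp topographies per stimulus dimension (identity and
  expression), optionally changing across piecewise time segments so the
  neural code evolves dynamically (diagonal-dominant temporal
  generalization);
* dissociable temporal envelopes -- by default identity coding is transient
  (fast rise, gone by the middle of the delay) while expression coding is
  sustained (slow rise to a plateau held through the delay), with the
  generative signal difference crossing at ~500 ms (end of the perception
  period);
* optional reactivation: the *previous* trial's identity topography
  re-emerges after the current stimulus appears (gain rho; 0 disables),
  modeling recovery of activity-silent working-memory content;
* temporally autocorrelated noise: AR(1) in time (one autocorrelation knob,
  phi, which is what the cluster-permutation correctness claim is about),
  independent across channels, plus an alpha-band (8-12 Hz) sinusoid with
  random frequency and phase per trial;
* a balanced 16-cell design in which consecutive trials never repeat either
  dimension (so previous-trial decoding cannot be driven by stimulus
  repetition).

Default scale mirrors the emulated study: 22 participants, 640 analysis
trials (40 per identity x expression cell), 59 channels, 250 Hz, epochs
[-500, +1500) ms = 500 samples.  Gains are in microvolts of spatial-pattern
norm; the defaults put single-trial signal well below the noise floor, as
in real EEG, so decodability emerges only through trial averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .core import ConfigError, EpochSet, TrialLabels, derive_seed

__all__ = ["EnvelopeParams", "NoiseParams", "SynthConfig", "TopographySet",
           "make_topographies", "envelope", "simulate_participant",
           "simulate_study", "simulate_behavior", "default_channel_names"]

N_CLASSES = 4
N_CELLS = 16


def default_channel_names(n: int):
    return tuple(f"CH{i + 1:02d}" for i in range(n))


@dataclass(frozen=True)
class EnvelopeParams:
    """Raised-cosine rise (onset -> peak to 1), raised-cosine fall
    (peak -> peak+fall to the plateau), exactly constant afterwards."""

    onset_ms: float
    peak_ms: float
    fall_ms: float
    plateau: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.plateau <= 1.0):
            raise ConfigError("plateau must lie in [0, 1]")
        if self.peak_ms <= self.onset_ms:
            raise ConfigError("peak must come after onset")
        if self.fall_ms <= 0:
            raise ConfigError("fall duration must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """sd_uv is the stationary standard deviation of the AR(1) process;
    ar_phi its lag-1 coefficient; alpha_amp_uv the amplitude of the
    alpha-band sinusoid added to every channel."""

    sd_uv: float = 6.0
    ar_phi: float = 0.5
    alpha_amp_uv: float = 4.0

    def __post_init__(self) -> None:
        if self.sd_uv < 0 or self.alpha_amp_uv < 0:
            raise ConfigError("noise amplitudes must be >= 0")
        if not (0.0 <= self.ar_phi < 1.0):
            raise ConfigError("AR(1) coefficient must lie in [0, 1)")


@dataclass(frozen=True)
class SynthConfig:
    n_participants: int = 22
    n_trials: int = 640
    n_channels: int = 59
    fs: float = 250.0
    epoch_ms: tuple = (-500.0, 1500.0)
    identity_gain: float = 1.0
    expression_gain: float = 0.45
    reactivation_gain: float = 0.0
    identity_envelope: EnvelopeParams = EnvelopeParams(60.0, 160.0, 600.0, 0.0)
    expression_envelope: EnvelopeParams = EnvelopeParams(150.0, 700.0, 500.0, 0.8)
    reactivation_envelope: EnvelopeParams = EnvelopeParams(60.0, 250.0, 350.0, 0.0)
    n_pattern_segments: int = 3
    segment_edges_ms: tuple = (0.0, 200.0, 500.0)
    noise: NoiseParams = NoiseParams()
    include_post_test: bool = False
    n_post_test: int = 80
    behavior_mean: float = 0.71
    behavior_sd: float = 0.08
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.identity_gain, self.expression_gain, self.reactivation_gain) < 0:
            raise ConfigError("gains must be >= 0")
        if self.n_trials % N_CELLS:
            raise ConfigError(f"n_trials must be divisible by {N_CELLS} (balanced cells)")
        if self.n_channels < 2:
            raise ConfigError("n_channels must be >= 2")
        if self.n_pattern_segments < 1:
            raise ConfigError("n_pattern_segments must be >= 1")
        if len(self.segment_edges_ms) != self.n_pattern_segments:
            raise ConfigError("segment_edges_ms must list one start per pattern segment")
        if self.include_post_test and self.n_post_test % N_CELLS:
            raise ConfigError(f"n_post_test must be divisible by {N_CELLS}")

    @property
    def n_times(self) -> int:
        return int(round((self.epoch_ms[1] - self.epoch_ms[0]) * self.fs / 1000.0))

    def envelope_params(self, dimension: str) -> EnvelopeParams:
        try:
            return {
                "identity": self.identity_envelope,
                "expression": self.expression_envelope,
                "reactivation": self.reactivation_envelope,
            }[dimension]
        except KeyError:
            raise ValueError(f"unknown envelope dimension: {dimension!r}") from None


@dataclass(eq=False)
class TopographySet:
    """Unit-norm spatial pattern per (class, pattern segment), one array per
    dimension; shape (n_classes, n_segments, n_channels)."""

    identity: np.ndarray
    expression: np.ndarray

    def __post_init__(self) -> None:
        for name in ("identity", "expression"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.ndim != 3:
                raise ConfigError(f"{name} topographies must be (classes, segments, channels)")
            norms = np.linalg.norm(arr, axis=-1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ConfigError(f"{name} topographies must be unit norm")


def make_topographies(config: SynthConfig, seed: int) -> TopographySet:
    """Draw unit-norm class topographies; across consecutive segments the
    patterns rotate with cosine similarity 0.6 exactly (dynamic coding),
    or stay identical when a single segment is configured."""
    rng = np.random.default_rng(seed)
    cos_step = 0.6

    def one_dimension() -> np.ndarray:
        out = np.empty((N_CLASSES, config.n_pattern_segments, config.n_channels))
        for c in range(N_CLASSES):
            v = rng.standard_normal(config.n_channels)
            v /= np.linalg.norm(v)
            out[c, 0] = v
            for s in range(1, config.n_pattern_segments):
                eps = rng.standard_normal(config.n_channels)
                eps -= eps @ v * v
                eps /= np.linalg.norm(eps)
                v = cos_step * v + np.sqrt(1.0 - cos_step**2) * eps
                v /= np.linalg.norm(v)  # exact renorm against round-off
                out[c, s] = v
        return out

    return TopographySet(identity=one_dimension(), expression=one_dimension())


def envelope(dimension: str, t, config: SynthConfig) -> np.ndarray:
    """Gain multiplier in [0, 1] at time(s) ``t`` ms for one signal
    dimension.  Zero before onset; 1 at the peak; equal to the plateau from
    peak+fall onwards."""
    p = config.envelope_params(dimension)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rise = (t >= p.onset_ms) & (t < p.peak_ms)
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - p.onset_ms) / (p.peak_ms - p.onset_ms)))
    fall = (t >= p.peak_ms) & (t < p.peak_ms + p.fall_ms)
    out[fall] = p.plateau + (1.0 - p.plateau) * 0.5 * (
        1.0 + np.cos(np.pi * (t[fall] - p.peak_ms) / p.fall_ms)
    )
    out[t >= p.peak_ms + p.fall_ms] = p.plateau
    return np.clip(out, 0.0, 1.0)


def segment_index(t, config: SynthConfig) -> np.ndarray:
    """Pattern segment active at time(s) t; times before the first edge map
    to segment 0 (irrelevant in practice: envelopes are zero there)."""
    edges = np.asarray(config.segment_edges_ms[1:], dtype=float)
    return np.searchsorted(edges, np.asarray(t, dtype=float), side="right")


# ---------------------------------------------------------------------------
# label sequences


def _draw_balanced_sequence(rng: np.random.Generator, n_trials: int,
                            max_restarts: int = 200) -> np.ndarray:
    """Balanced random cell sequence where consecutive trials never share
    identity or expression.  Greedy draw proportional to remaining cell
    counts, restarting on dead ends (rare for balanced designs)."""
    cells = np.array([(i, e) for i in range(1, 5) for e in range(1, 5)], dtype=np.int64)
    per_cell = n_trials // N_CELLS
    for _ in range(max_restarts):
        counts = np.full(N_CELLS, per_cell, dtype=np.int64)
        seq = np.empty((n_trials, 2), dtype=np.int64)
        prev = None
        ok = True
        for step in range(n_trials):
            w = counts.astype(float)
            if prev is not None:
                w = w * ((cells[:, 0] != prev[0]) & (cells[:, 1] != prev[1]))
            total = w.sum()
            if total == 0:
                ok = False
                break
            choice = rng.choice(N_CELLS, p=w / total)
            counts[choice] -= 1
            seq[step] = cells[choice]
            prev = cells[choice]
        if ok:
            return seq
    raise ConfigError("could not draw a balanced no-repeat trial sequence")


def draw_session_labels(rng: np.random.Generator, config: SynthConfig) -> TrialLabels:
    """Draw a session's label table.  With ``include_post_test`` the session
    has n_trials + n_post_test trials, the extra ones flagged (balanced per
    cell) so that excluding them restores the balanced analysis set."""
    n_total = config.n_trials + (config.n_post_test if config.include_post_test else 0)
    seq = _draw_balanced_sequence(rng, n_total)
    n = seq.shape[0]
    is_post = np.zeros(n, dtype=bool)
    if config.include_post_test:
        per_cell_flag = config.n_post_test // N_CELLS
        for ident in range(1, 5):
            for expr in range(1, 5):
                rows = np.flatnonzero((seq[:, 0] == ident) & (seq[:, 1] == expr))
                is_post[rng.choice(rows, size=per_cell_flag, replace=False)] = True
    is_first = np.zeros(n, dtype=bool)
    is_first[0] = True
    return TrialLabels(
        identity=seq[:, 0],
        expression=seq[:, 1],
        trial_index=np.arange(n),
        is_post_test=is_post,
        is_first=is_first,
    )


# ---------------------------------------------------------------------------
# voltage synthesis


def _ar1_noise(rng: np.random.Generator, shape, noise: NoiseParams,
               burn: int = 32) -> np.ndarray:
    """Stationary AR(1) noise along the last axis."""
    n_t = shape[-1]
    innov_sd = noise.sd_uv * np.sqrt(1.0 - noise.ar_phi**2)
    white = rng.standard_normal(shape[:-1] + (n_t + burn,)) * innov_sd
    colored = _sig.lfilter([1.0], [1.0, -noise.ar_phi], white, axis=-1)
    return colored[..., burn:]


def simulate_participant(config: SynthConfig, topo: TopographySet, seed: int,
                         participant_id: str = "sim") -> EpochSet:
    """Simulate one participant's epochs; deterministic given (config,
    topographies, seed).

    Trial voltage = identity_gain * env_id(t) * T_id(class, segment(t))
                  + expression_gain * env_ex(t) * T_ex(class, segment(t))
                  + rho * env_react(t) * T_id(previous class, segment(t))
                  + AR(1) noise + alpha sinusoid.
    """
    rng = np.random.default_rng(seed)
    labels = draw_session_labels(rng, config)
    n = len(labels)
    times = config.epoch_ms[0] + np.arange(config.n_times) * 1000.0 / config.fs
    seg = segment_index(times, config)
    seg = np.clip(seg, 0, config.n_pattern_segments - 1)

    # (class, channels, times) signal fields for each dimension
    env_id = envelope("identity", times, config)
    env_ex = envelope("expression", times, config)
    env_re = envelope("reactivation", times, config)
    topo_id_t = topo.identity[:, seg, :].transpose(0, 2, 1)      # (C, ch, T)
    topo_ex_t = topo.expression[:, seg, :].transpose(0, 2, 1)
    field_id = config.identity_gain * env_id[None, None, :] * topo_id_t
    field_ex = config.expression_gain * env_ex[None, None, :] * topo_ex_t
    field_re = config.reactivation_gain * env_re[None, None, :] * topo_id_t

    data = np.zeros((n, config.n_channels, config.n_times))
    for c in range(1, N_CLASSES + 1):
        data[labels.identity == c] += field_id[c - 1]
        data[labels.expression == c] += field_ex[c - 1]
    if config.reactivation_gain > 0:
        order = np.argsort(labels.trial_index, kind="stable")
        prev_identity = np.zeros(n, dtype=np.int64)
        prev_identity[order[1:]] = labels.identity[order[:-1]]
        for c in range(1, N_CLASSES + 1):
            data[prev_identity == c] += field_re[c - 1]

    data += _ar1_noise(rng, (n, config.n_channels, config.n_times), config.noise)
    if config.noise.alpha_amp_uv > 0:
        freq = rng.uniform(8.0, 12.0, size=n)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=n)
        alpha = config.noise.alpha_amp_uv * np.sin(
            2.0 * np.pi * freq[:, None] * (times / 1000.0)[None, :] + phase[:, None]
        )
        data += alpha[:, None, :]

    return EpochSet(
        data=data.astype(np.float32),
        fs=config.fs,
        t_start_ms=config.epoch_ms[0],
        channel_names=default_channel_names(config.n_channels),
        participant_id=participant_id,
        labels=labels,
    )


def simulate_study(config: SynthConfig, seed: int | None = None):
    """Yield (participant_id, EpochSet) for every simulated participant.

    Topographies are drawn once per participant (individual anatomy), each
    from a seed derived deterministically from the master seed.
    """
    master = config.rng_seed if seed is None else seed
    for p in range(config.n_participants):
        pid = f"sub-{p + 1:02d}"
        topo = make_topographies(config, derive_seed(master, p, 0))
        yield pid, simulate_participant(config, topo, derive_seed(master, p, 1), pid)


def simulate_behavior(config: SynthConfig, seed: int | None = None) -> np.ndarray:
    """Per-participant behavioral accuracies for the two report types,
    shape (n_participants, 2) = (identity test, expression test).

    Emulates approximately equal performance on the two dimensions (the
    generator encodes no true behavioral difference)."""
    master = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(derive_seed(master, 999))
    acc = rng.normal(config.behavior_mean, config.behavior_sd,
                     size=(config.n_participants, 2))
    return np.clip(acc, 0.0, 1.0)
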