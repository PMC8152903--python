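"""Signal conditioning before decoding and smoothing after.

Order of operations in the pipeline: the raw epochs are low-pass filtered
(6 Hz by default, which removes alpha-band 8-12 Hz activity -- a major
source of trial-to-trial variability that is not phase-locked to the
stimulus) and baseline-corrected; decoding then runs per time point; the
resulting accuracy series is smoothed with a 5-point centered moving
average (+/-8 ms at 250 Hz).  Smoothing is never applied to the raw EEG.

The low-pass is a zero-phase (forward-backward) Hamming-windowed-sinc FIR.
The analysis depends on phase-locked low-frequency content, not on any
specific filter kernel, so any zero-phase FIR with unit DC gain and
adequate stop-band attenuation is equivalent for this purpose.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import signal

from .core import AccuracySeries, ConfigError, EpochSet

__all__ = ["lowpass_filter", "baseline_correct", "smooth_series",
           "smooth_values", "window_average", "decimate"]


def _design_lowpass(cutoff_hz: float, fs: float, n_times: int) -> np.ndarray:
    """Hamming-windowed sinc taps; order ~ 3*fs/cutoff rounded to even,
    capped so filtfilt's default padding fits the epoch length."""
    order = int(round(3.0 * fs / cutoff_hz))
    if order % 2:
        order += 1
    # filtfilt pads with 3*(order+1) samples by default; keep that inside the epoch
    max_order = max(2, (n_times - 1) // 3 - 1)
    if max_order % 2:
        max_order -= 1
    order = min(order, max_order)
    return signal.firwin(order + 1, cutoff_hz, fs=fs, window="hamming")


def lowpass_filter(epochs: EpochSet, cutoff_hz: float) -> EpochSet:
    """Zero-phase FIR low-pass applied per epoch along the time axis."""
    if cutoff_hz >= epochs.fs / 2:
        raise ConfigError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({epochs.fs / 2} Hz)")
    if cutoff_hz <= 0:
        raise ConfigError("cutoff must be positive")
    taps = _design_lowpass(cutoff_hz, epochs.fs, epochs.n_times)
    filtered = signal.filtfilt(taps, [1.0], epochs.data.astype(np.float64), axis=-1)
    return replace(epochs, data=filtered.astype(np.float32))


def baseline_correct(epochs: EpochSet, window_ms=(-500.0, 0.0)) -> EpochSet:
    """Subtract, per trial and channel, the mean voltage over ``window_ms``
    (half-open interval [start, end))."""
    t0, t1 = float(window_ms[0]), float(window_ms[1])
    times = epochs.times
    mask = (times >= t0) & (times < t1)
    if not mask.any():
        raise ConfigError(f"baseline window [{t0}, {t1}) ms contains no samples")
    data = epochs.data.astype(np.float64)
    data -= data[:, :, mask].mean(axis=-1, keepdims=True)
    return replace(epochs, data=data.astype(np.float32))


def smooth_values(values: np.ndarray, n_points: int = 5) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the
    edges so it never extends past the series (no zero padding, which would
    bias edge values toward 0 and create spurious clusters)."""
    if n_points < 1 or n_points % 2 == 0:
        raise ConfigError("smoothing window must be an odd positive integer")
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    half = n_points // 2
    out = np.empty_like(values)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[..., i] = values[..., i - h:i + h + 1].mean(axis=-1)
    return out


def smoothing_matrix(n: int, n_points: int = 5) -> np.ndarray:
    """Linear operator S with smooth(x) = x @ S.T; used to smooth many
    permutation-null accuracy series in one matrix product."""
    if n_points < 1 or n_points % 2 == 0:
        raise ConfigError("smoothing window must be an odd positive integer")
    S = np.zeros((n, n))
    half = n_points // 2
    for i in range(n):
        h = min(half, i, n - 1 - i)
        S[i, i - h:i + h + 1] = 1.0 / (2 * h + 1)
    return S


def smooth_series(series: AccuracySeries, n_points: int = 5) -> AccuracySeries:
    """5-point (by default) moving-average smoothing of an accuracy series."""
    return AccuracySeries(
        values=smooth_values(series.values, n_points),
        times=series.times.copy(),
        n_attempts=series.n_attempts,
    )


def window_average(epochs: EpochSet, width_ms: float = 100.0) -> EpochSet:
    """Average consecutive non-overlapping windows of ``width_ms``.

    Window i covers [t_start + i*width, t_start + (i+1)*width); its time
    stamp is the window start.  A [-500, 1500) ms epoch at 100 ms width
    yields 20 time points.
    """
    w = int(round(width_ms / epochs.dt_ms))
    if w < 1:
        raise ConfigError("window width must cover at least one sample")
    if abs(width_ms - w * epochs.dt_ms) > 1e-9:
        raise ConfigError("window width must be an integer number of samples")
    n_win = epochs.n_times // w
    if n_win * w != epochs.n_times:
        raise ConfigError(
            f"epoch length ({epochs.n_times} samples) is not divisible by the "
            f"window width ({w} samples)"
        )
    data = epochs.data.astype(np.float64)
    data = data[:, :, : n_win * w].reshape(epochs.n_trials, epochs.n_channels, n_win, w)
    averaged = data.mean(axis=-1).astype(np.float32)
    return replace(epochs, data=averaged, fs=epochs.fs / w)


def decimate(epochs: EpochSet, factor: int) -> EpochSet:
    """Integer-factor decimation (sample picking) for building small
    fixtures; apply a low-pass first if aliasing matters."""
    if factor < 1:
        raise ConfigError("decimation factor must be >= 1")
    return replace(epochs, data=epochs.data[:, :, ::factor], fs=epochs.fs / factor)
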