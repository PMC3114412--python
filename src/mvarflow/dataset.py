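"""Epoched multichannel time-series container and standard preprocessing.

The universal input object is :class:`EpochedTimeSeries`: a
``channels × samples × trials`` real array together with its sampling rate and
an event-relative time axis in seconds (the time-locking event sits at 0 s).
Preprocessing covers detrending, temporal / ensemble normalization,
anti-aliased downsampling, and sliding-window segmentation for
locally-stationary modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .exceptions import DegenerateDataError, InvalidArgumentError

__all__ = [
    "EpochedTimeSeries",
    "WindowSpec",
    "detrend",
    "normalize_ensemble",
    "downsample",
    "segment_windows",
]

_TIME_TOL = 1e-9  # tolerance on uniformity of the time axis, seconds


@dataclass
class EpochedTimeSeries:
    """Epoched multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples, n_trials)
        Signal values; units arbitrary but consistent across trials.
    srate : float
        Sampling rate in Hz, > 0.
    times : ndarray, shape (n_samples,)
        Latency of each sample in seconds relative to the time-locking
        event, strictly increasing with constant step ``1/srate``.
    channel_labels : list of str
        Unique channel names, one per channel.
    condition : str or None
        Optional condition label (e.g. for between-condition tests).
    """

    data: np.ndarray
    srate: float
    times: np.ndarray
    channel_labels: list[str]
    condition: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError(
                f"data must be (n_channels, n_samples, n_trials); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("data contains non-finite values")
        if not (self.srate > 0):
            raise InvalidArgumentError(f"srate must be > 0, got {self.srate}")
        m, n, t = self.data.shape
        if m < 1 or t < 1:
            raise InvalidArgumentError("need n_channels >= 1 and n_trials >= 1")
        if self.times.shape != (n,):
            raise InvalidArgumentError(
                f"times has length {self.times.shape}, expected ({n},)"
            )
        if n > 1:
            steps = np.diff(self.times)
            if np.any(np.abs(steps - 1.0 / self.srate) > _TIME_TOL):
                raise InvalidArgumentError(
                    "times must be uniformly spaced at 1/srate"
                )
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != m:
            raise InvalidArgumentError(
                f"{len(self.channel_labels)} labels for {m} channels"
            )
        if len(set(self.channel_labels)) != m:
            raise InvalidArgumentError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Epoch duration in seconds (n_samples / srate)."""
        return self.n_samples / self.srate

    def copy(self) -> "EpochedTimeSeries":
        return replace(self, data=self.data.copy(), times=self.times.copy(),
                       channel_labels=list(self.channel_labels))

    def with_data(self, data: np.ndarray) -> "EpochedTimeSeries":
        """Return a copy carrying ``data`` (same shape) and unchanged metadata."""
        return replace(self, data=np.asarray(data, dtype=float),
                       times=self.times.copy(),
                       channel_labels=list(self.channel_labels))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window specification: window length and hop, both in seconds."""

    win_len: float
    step: float

    def __post_init__(self) -> None:
        if not (self.win_len > 0):
            raise InvalidArgumentError(f"win_len must be > 0, got {self.win_len}")
        if not (self.step > 0):
            raise InvalidArgumentError(f"step must be > 0, got {self.step}")

    def n_window_samples(self, srate: float) -> int:
        return int(round(self.win_len * srate))

    def n_step_samples(self, srate: float) -> int:
        return max(1, int(round(self.step * srate)))


def detrend(ts: EpochedTimeSeries, mode: str = "linear") -> EpochedTimeSeries:
    """Remove the least-squares constant or linear trend per channel and trial.

    Parameters
    ----------
    ts : EpochedTimeSeries
    mode : {'constant', 'linear'}
        'constant' subtracts the per-series mean; 'linear' subtracts the
        best-fit line over samples.
    """
    if mode not in ("constant", "linear"):
        raise InvalidArgumentError(f"unknown detrend mode {mode!r}")
    out = scipy.signal.detrend(ts.data, axis=1, type=mode)
    return ts.with_data(out)


def normalize_ensemble(ts: EpochedTimeSeries, mode: str = "temporal") -> EpochedTimeSeries:
    """Z-score the data over samples ('temporal') or over trials ('ensemble').

    Temporal mode standardizes each (channel, trial) series across samples.
    Ensemble mode standardizes each (channel, sample) point across trials,
    removing the trial-mean (evoked) component.  Both use the unbiased (n-1)
    standard deviation.

    Raises
    ------
    DegenerateDataError
        If any standard deviation used for division is zero; the message
        names the offending channel and trial/sample.
    """
    if mode == "temporal":
        if ts.n_samples < 2:
            raise InvalidArgumentError("temporal normalization needs n_samples >= 2")
        mu = ts.data.mean(axis=1, keepdims=True)
        sd = ts.data.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            ch, _, tr = np.argwhere(sd == 0)[0]
            raise DegenerateDataError(
                f"zero temporal standard deviation at channel "
                f"{ts.channel_labels[ch]!r}, trial {tr}"
            )
        return ts.with_data((ts.data - mu) / sd)
    if mode == "ensemble":
        if ts.n_trials < 2:
            raise InvalidArgumentError("ensemble normalization needs n_trials >= 2")
        mu = ts.data.mean(axis=2, keepdims=True)
        sd = ts.data.std(axis=2, ddof=1, keepdims=True)
        if np.any(sd == 0):
            ch, s, _ = np.argwhere(sd == 0)[0]
            raise DegenerateDataError(
                f"zero ensemble standard deviation at channel "
                f"{ts.channel_labels[ch]!r}, sample {s}"
            )
        return ts.with_data((ts.data - mu) / sd)
    raise InvalidArgumentError(f"unknown normalization mode {mode!r}")


def downsample(ts: EpochedTimeSeries, factor: int) -> EpochedTimeSeries:
    """Anti-alias filter and decimate by an integer factor.

    Uses a zero-phase (forward-backward) order-8 Chebyshev-I lowpass with
    cutoff at 0.8 × the new Nyquist frequency, then keeps every ``factor``-th
    sample.  ``factor=1`` is the bit-exact identity.
    """
    if not isinstance(factor, (int, np.integer)) or isinstance(factor, bool):
        raise InvalidArgumentError(f"factor must be an integer, got {factor!r}")
    if factor < 1:
        raise InvalidArgumentError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return ts.copy()
    out = scipy.signal.decimate(ts.data, int(factor), axis=1,
                                ftype="iir", zero_phase=True)
    return EpochedTimeSeries(
        data=out,
        srate=ts.srate / factor,
        times=ts.times[::factor].copy(),
        channel_labels=list(ts.channel_labels),
        condition=ts.condition,
    )


def segment_windows(
    ts: EpochedTimeSeries, spec: WindowSpec
) -> list[tuple[float, EpochedTimeSeries]]:
    """Cut the epoch into onset-anchored sliding windows.

    Windows start at ``times[0]`` and advance by ``spec.step`` while the full
    window fits inside the epoch; a trailing partial window is dropped, never
    zero-padded.  Each entry is ``(window_center_seconds, window)`` where the
    center is event-relative.
    """
    win = spec.n_window_samples(ts.srate)
    if win < 2:
        raise InvalidArgumentError("window must cover at least 2 samples")
    if win > ts.n_samples:
        raise InvalidArgumentError(
            f"win_len {spec.win_len} s exceeds epoch duration {ts.duration} s"
        )
    hop = spec.n_step_samples(ts.srate)
    out: list[tuple[float, EpochedTimeSeries]] = []
    for onset in range(0, ts.n_samples - win + 1, hop):
        sl = slice(onset, onset + win)
        center = ts.times[onset] + (win - 1) / (2.0 * ts.srate)
        wts = EpochedTimeSeries(
            data=ts.data[:, sl, :].copy(),
            srate=ts.srate,
            times=ts.times[sl].copy(),
            channel_labels=list(ts.channel_labels),
            condition=ts.condition,
        )
        out.append((float(center), wts))
    return out
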