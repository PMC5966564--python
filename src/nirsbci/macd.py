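"""Causal band-pass filtering of hemoglobin time series by an EMA difference (MACD).

The filter is the difference of a short-window and a long-window exponential
moving average applied sample by sample:

    EMA_N:  y[n] = 2/(N+1) * x[n] + (N-1)/(N+1) * y[n-1]
    MACD:   m[n] = EMA_Nshort(x)[n] - EMA_Nlong(x)[n]

Each EMA has unit DC gain, so their difference rejects DC and slow drift
exactly while passing the hemodynamic band; with the default 6 s / 13 s
windows the filter approximates a 0.02-0.33 Hz band-pass.  It is strictly
causal and O(1) per sample, which is what makes it usable online.

Window lengths are specified in seconds and converted to sample counts as
``N = round(window_s * fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .hemodynamics import HemoStream

__all__ = [
    "EmaState",
    "MacdConfig",
    "ema_update",
    "macd_update",
    "MacdFilter",
    "filter_stream",
    "frequency_response",
]


@dataclass(frozen=True)
class EmaState:
    """State of one exponential moving average: window length and last output."""

    n_window: int
    last_output: float = 0.0
    initialized: bool = False

    def __post_init__(self) -> None:
        if self.n_window < 1:
            raise ValueError(f"EMA window must be >= 1 sample, got {self.n_window}")

    @property
    def alpha(self) -> float:
        """Smoothing weight 2/(N+1), in (0, 1]."""
        return 2.0 / (self.n_window + 1)


@dataclass(frozen=True)
class MacdConfig:
    """Filter windows in seconds plus the sampling rate that fixes N."""

    short_window_s: float = 6.0
    long_window_s: float = 13.0
    sampling_rate: float = 2.0
    init_to_first_sample: bool = True

    def __post_init__(self) -> None:
        if self.short_window_s <= 0 or self.long_window_s <= 0:
            raise ValueError("windows must be positive")
        if self.short_window_s >= self.long_window_s:
            raise ValueError("short window must be shorter than the long window")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_short(self) -> int:
        return max(1, round(self.short_window_s * self.sampling_rate))

    @property
    def n_long(self) -> int:
        return max(1, round(self.long_window_s * self.sampling_rate))


def ema_update(state: EmaState, x: float, init_to_first_sample: bool = True) -> tuple[EmaState, float]:
    """One EMA step; returns the new state and the filtered value.

    On the first sample the running output is seeded with the sample itself
    (default), which removes the startup transient and makes a constant
    stream a fixed point from sample one.  With
    ``init_to_first_sample=False`` the recurrence starts from y = 0 instead.
    """
    alpha = state.alpha
    if not state.initialized:
        prev = x if init_to_first_sample else 0.0
    else:
        prev = state.last_output
    # algebraically alpha*x + (1-alpha)*prev, written so a constant input is
    # an exact floating-point fixed point
    y = prev + alpha * (x - prev)
    return replace(state, last_output=y, initialized=True), y


def macd_update(
    short: EmaState, long: EmaState, x: float, init_to_first_sample: bool = True
) -> tuple[EmaState, EmaState, float]:
    """One MACD step: feed both EMAs the same sample, return their difference."""
    if short.initialized != long.initialized:
        raise ValueError("short and long EMA states are out of sync")
    short, ys = ema_update(short, x, init_to_first_sample)
    long, yl = ema_update(long, x, init_to_first_sample)
    return short, long, ys - yl


class MacdFilter:
    """Streaming MACD filter over a bank of channels.

    Holds one (short, long) EMA state pair per channel and updates all of
    them from a vector of simultaneous samples.  Used by the online session
    runner; the batch path (:func:`filter_stream`) produces identical output.
    """

    def __init__(self, config: MacdConfig, n_channels: int):
        self.config = config
        self.n_channels = n_channels
        self._short = [EmaState(config.n_short) for _ in range(n_channels)]
        self._long = [EmaState(config.n_long) for _ in range(n_channels)]

    def update(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_channels,):
            raise ValueError(f"expected {self.n_channels} channel samples")
        out = np.empty(self.n_channels)
        for c in range(self.n_channels):
            self._short[c], self._long[c], out[c] = macd_update(
                self._short[c], self._long[c], x[c], self.config.init_to_first_sample
            )
        return out


def _ema_batch(x: np.ndarray, n_window: int, init_to_first_sample: bool) -> np.ndarray:
    """Vectorized EMA along axis 0 via a first-order IIR filter."""
    alpha = 2.0 / (n_window + 1)
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    if init_to_first_sample:
        # zi chosen so the first output is alpha*x0 + (1-alpha)*x0 = x0
        zi = (1.0 - alpha) * x[:1]
        y, _ = lfilter(b, a, x, axis=0, zi=zi)
    else:
        y = lfilter(b, a, x, axis=0)
    return y


def filter_stream(stream: HemoStream, config: MacdConfig, rtol: float = 1e-6) -> HemoStream:
    """Apply the MACD filter independently per (optode, chromophore) channel.

    Requires uniform sampling at the configured rate; output has the same
    length and timestamps as the input and uses no future samples.
    """
    if stream.time.size >= 2:
        dt = np.diff(stream.time)
        expected = 1.0 / config.sampling_rate
        if np.any(np.abs(dt - expected) > rtol * expected + 1e-9):
            raise ValueError(
                "stream is not uniformly sampled at the configured rate"
            )
    hbo = _ema_batch(stream.hbo, config.n_short, config.init_to_first_sample) - _ema_batch(
        stream.hbo, config.n_long, config.init_to_first_sample
    )
    hhb = _ema_batch(stream.hhb, config.n_short, config.init_to_first_sample) - _ema_batch(
        stream.hhb, config.n_long, config.init_to_first_sample
    )
    return HemoStream(time=stream.time, hbo=hbo, hhb=hhb)


def _ema_transfer(n_window: int, f: np.ndarray, fs: float) -> np.ndarray:
    alpha = 2.0 / (n_window + 1)
    z = np.exp(-2j * np.pi * f / fs)
    return alpha / (1.0 - (1.0 - alpha) * z)


def frequency_response(config: MacdConfig, f: float | np.ndarray) -> np.ndarray | float:
    """Closed-form gain magnitude |H(f)| of the MACD filter.

    Each EMA is the first-order IIR ``alpha / (1 - (1-alpha) z^{-1})``; the
    MACD response is the difference of the two.  |H(0)| = 0 exactly because
    both EMAs have unit DC gain.  Valid for 0 <= f <= fs/2.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0) or np.any(f_arr > config.sampling_rate / 2 + 1e-12):
        raise ValueError("frequency outside [0, Nyquist]")
    h = _ema_transfer(config.n_short, f_arr, config.sampling_rate) - _ema_transfer(
        config.n_long, f_arr, config.sampling_rate
    )
    mag = np.abs(h)
    return float(mag) if np.isscalar(f) else mag
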