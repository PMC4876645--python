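"""Spike-density estimation and EMG conditioning.

Spike trains are converted to continuous firing-rate estimates by
convolving spike times with a causal asymmetric double-exponential kernel
(default 1 ms rise, 20 ms fall time constants).  Raw EMG is band-pass
filtered (10-150 Hz, zero-phase third-order Butterworth) and full-wave
rectified.

All times are in milliseconds relative to perturbation onset (t = 0); all
rates are in spikes per second.  The kernel is normalized to unit area over
time measured in *seconds*, so that a single spike contributes exactly one
spike of integrated rate and convolution output reads directly in sp/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class Kernel:
    """Causal asymmetric double-exponential smoothing kernel.

    ``k(t) ∝ (1 - exp(-t / rise_tau)) * exp(-t / fall_tau)`` for
    ``0 <= t <= support_ms``, zero elsewhere; normalized after truncation so
    that its area over seconds is one.
    """

    rise_tau: float
    fall_tau: float
    dt: float
    support_ms: float
    values: np.ndarray = field(repr=False)
    _norm: float = field(repr=False)

    @property
    def grid(self) -> np.ndarray:
        """Time grid (ms) the discretized kernel lives on."""
        return np.arange(self.values.size) * self.dt

    @property
    def area(self) -> float:
        """Integral of the kernel over time in seconds (should be 1)."""
        return float(np.sum(self.values) * self.dt / 1000.0)

    @property
    def peak_time(self) -> float:
        """Location of the discretized kernel's maximum, in ms."""
        return float(self.grid[int(np.argmax(self.values))])

    def evaluate(self, tau_ms: np.ndarray) -> np.ndarray:
        """Kernel value (sp/s per spike) at arbitrary lags, in ms."""
        tau = np.asarray(tau_ms, dtype=float)
        out = np.zeros_like(tau)
        mask = (tau >= 0.0) & (tau <= self.support_ms)
        t = tau[mask]
        out[mask] = (1.0 - np.exp(-t / self.rise_tau)) * np.exp(-t / self.fall_tau)
        out /= self._norm
        return out


def make_kernel(
    rise_tau: float = 1.0,
    fall_tau: float = 20.0,
    dt: float = 1.0,
    support_multiplier: float = 8.0,
) -> Kernel:
    """Build the discretized causal double-exponential kernel.

    Parameters
    ----------
    rise_tau, fall_tau : float
        Rise and fall time constants in ms; must satisfy
        ``0 < rise_tau < fall_tau``.
    dt : float
        Grid step in ms; must not exceed ``rise_tau`` so the rising edge is
        resolved.
    support_multiplier : float
        The kernel is truncated at ``support_multiplier * fall_tau`` ms and
        renormalized to unit area (over seconds) after truncation.
    """
    if rise_tau <= 0 or fall_tau <= 0:
        raise ValueError("time constants must be positive")
    if rise_tau >= fall_tau:
        raise ValueError("rise_tau must be smaller than fall_tau")
    if dt <= 0 or dt > rise_tau:
        raise ValueError("dt must be in (0, rise_tau]")
    support = support_multiplier * fall_tau
    grid = np.arange(0.0, support + dt / 2, dt)
    raw = (1.0 - np.exp(-grid / rise_tau)) * np.exp(-grid / fall_tau)
    norm = float(np.sum(raw) * dt / 1000.0)  # Riemann area in seconds
    values = raw / norm
    return Kernel(
        rise_tau=rise_tau,
        fall_tau=fall_tau,
        dt=dt,
        support_ms=float(grid[-1]),
        values=values,
        _norm=norm,
    )


@dataclass
class RateSeries:
    """A firing-rate trace on a uniform time grid (ms, sp/s)."""

    time_ms: np.ndarray
    rate: np.ndarray
    n_trials_averaged: int = 1
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.time_ms.shape != self.rate.shape:
            raise ValueError("time and rate grids differ in length")

    @property
    def dt(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


def spike_density(
    spike_times_ms,
    window: tuple[float, float],
    kernel: Kernel,
) -> RateSeries:
    """Spike-density function: sum of kernels translated to each spike.

    ``rate(t) = sum_s k(t - t_s)`` evaluated on the grid
    ``window[0] ... window[1]`` with the kernel's ``dt``.  Spikes *before*
    the window still contribute if the window lies within their kernel
    support (no artificial onset transient at the window edge); spikes after
    the window cannot contribute (the kernel is causal).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    grid = np.arange(t0, t1 + kernel.dt / 2, kernel.dt)
    spikes = np.asarray(spike_times_ms, dtype=float)
    spikes = spikes[(spikes >= t0 - kernel.support_ms) & (spikes <= t1)]
    if spikes.size == 0:
        return RateSeries(grid, np.zeros_like(grid))
    # evaluate in spike blocks to bound the (n_grid x n_spikes) broadcast
    rate = np.zeros_like(grid)
    block = max(1, int(8_000_000 // max(grid.size, 1)))
    for i in range(0, spikes.size, block):
        lags = grid[:, None] - spikes[None, i:i + block]
        rate += kernel.evaluate(lags).sum(axis=1)
    return RateSeries(grid, rate)


def trial_average(series_list: list[RateSeries]) -> RateSeries:
    """Pointwise mean and standard error across trials.

    All input series must share the same time grid; SEM uses the n-1 sample
    standard deviation divided by sqrt(n_trials).
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 series to average")
    grid = series_list[0].time_ms
    for s in series_list[1:]:
        if s.time_ms.shape != grid.shape or not np.allclose(s.time_ms, grid):
            raise ValueError("all series must share the same time grid")
    stack = np.vstack([s.rate for s in series_list])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return RateSeries(grid, mean, n_trials_averaged=stack.shape[0], sem=sem)


@dataclass
class EMGSeries:
    """Rectified, band-passed EMG envelope on a uniform grid (ms, a.u.)."""

    time_ms: np.ndarray
    envelope: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.envelope = np.asarray(self.envelope, dtype=float)


def preprocess_emg(
    raw: np.ndarray,
    sampling_rate_hz: float,
    time_ms: np.ndarray | None = None,
    band_hz: tuple[float, float] = (10.0, 150.0),
    order: int = 3,
) -> EMGSeries:
    """Band-pass filter (zero-phase) and full-wave rectify a raw EMG trace.

    The filter is a third-order Butterworth applied forward and backward
    ("two-pass"), giving zero phase shift so evoked-onset timing is
    preserved; rectification is the absolute value.
    """
    low, high = band_hz
    if sampling_rate_hz <= 2 * high:
        raise ValueError(
            f"sampling rate {sampling_rate_hz} Hz too low for a {high} Hz band edge"
        )
    raw = np.asarray(raw, dtype=float)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, raw)
    if time_ms is None:
        time_ms = np.arange(raw.size) * 1000.0 / sampling_rate_hz
    return EMGSeries(time_ms, np.abs(filtered))
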