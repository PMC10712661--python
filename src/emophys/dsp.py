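"""Shared signal-processing primitives.

All filters are zero-phase (forward-backward Butterworth), so filtered
traces keep their timing; downsampling is plain index selection and assumes
the caller has already applied an anti-aliasing filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps


@dataclass
class SignalTrace:
    """Uniformly sampled signal, one or more channels.

    ``data`` has shape ``(n_samples,)`` for a single channel or
    ``(n_channels, n_samples)`` for multichannel traces. Missing samples
    are NaN.
    """

    data: np.ndarray
    rate: float
    units: str = ""
    channel_labels: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.data.ndim not in (1, 2):
            raise ValueError("data must be 1-D or 2-D (channels x samples)")
        if self.channel_labels and len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match data")

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 1 else self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None
        return np.atleast_2d(self.data)[i]

    def slice(self, t_start: float, t_end: float) -> "SignalTrace":
        """Samples with time in [t_start, t_end)."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.rate - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil((t_end - self.t0) * self.rate - 1e-9)))
        return replace(self, data=self.data[..., i0:i1], t0=self.t0 + i0 / self.rate)


@dataclass
class Spectrum:
    """One-sided power spectral density on a frequency grid."""

    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def _filtfilt(trace: SignalTrace, b: np.ndarray, a: np.ndarray) -> SignalTrace:
    padlen = min(3 * max(len(a), len(b)), trace.n_samples - 1)
    if padlen < 1:
        raise ValueError("trace too short for zero-phase filtering")
    out = sps.filtfilt(b, a, trace.data, axis=-1, padlen=padlen)
    return replace(trace, data=out)


def zero_phase_lowpass(trace: SignalTrace, order: int, cutoff: float) -> SignalTrace:
    """Forward-backward Butterworth low-pass (no phase distortion)."""
    nyq = trace.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be in (0, {nyq}) Hz")
    b, a = sps.butter(order, cutoff / nyq, btype="low")
    return _filtfilt(trace, b, a)


def bandpass(trace: SignalTrace, order: int, low: float, high: float) -> SignalTrace:
    """Forward-backward Butterworth band-pass."""
    nyq = trace.rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band [{low}, {high}] Hz must satisfy 0 < low < high < {nyq}")
    b, a = sps.butter(order, [low / nyq, high / nyq], btype="band")
    return _filtfilt(trace, b, a)


def downsample(trace: SignalTrace, target_rate: float) -> SignalTrace:
    """Decimate by index selection to target_rate.

    Anti-aliasing is the caller's responsibility (matching the two-step
    filter-then-decimate processing order of each signal chain).
    """
    if target_rate > trace.rate:
        raise ValueError(f"target rate {target_rate} exceeds trace rate {trace.rate}")
    if target_rate == trace.rate:
        return replace(trace)
    n_out = int(np.floor(trace.n_samples * target_rate / trace.rate))
    idx = np.round(np.arange(n_out) * trace.rate / target_rate).astype(int)
    idx = np.minimum(idx, trace.n_samples - 1)
    return replace(trace, data=trace.data[..., idx], rate=float(target_rate))


def welch_psd(
    trace: SignalTrace,
    segment_len: int,
    overlap_fraction: float = 0.5,
    window: str = "hamming",
    detrend: bool = True,
) -> Spectrum:
    """One-sided Welch PSD (density scaling, Parseval-consistent)."""
    if segment_len > trace.n_samples:
        raise ValueError(
            f"segment_len {segment_len} exceeds trace length {trace.n_samples}"
        )
    noverlap = int(segment_len * overlap_fraction)
    freqs, psd = sps.welch(
        trace.data,
        fs=trace.rate,
        window=window,
        nperseg=segment_len,
        noverlap=noverlap,
        detrend="constant" if detrend else False,
        axis=-1,
        scaling="density",
    )
    return Spectrum(frequencies=freqs, density=psd)


def band_power(spectrum: Spectrum, low: float, high: float) -> float | np.ndarray:
    """Trapezoidal integral of the density over [low, high).

    Band edges are interpolated onto the grid so disjoint bands sum exactly
    to the integral over their union.
    """
    f = spectrum.frequencies
    if low < f[0] - 1e-12 or high > f[-1] + 1e-12:
        raise ValueError(f"band [{low}, {high}) outside spectrum range [{f[0]}, {f[-1]}]")
    low = max(low, f[0])
    high = min(high, f[-1])
    if high <= low:
        return np.zeros(spectrum.density.shape[:-1]) if spectrum.density.ndim > 1 else 0.0
    inner = f[(f > low) & (f < high)]
    grid = np.concatenate(([low], inner, [high]))
    dens = np.atleast_2d(spectrum.density)
    out = np.empty(dens.shape[0])
    for i, row in enumerate(dens):
        vals = np.interp(grid, f, row)
        out[i] = np.trapezoid(vals, grid)
    return out if spectrum.density.ndim > 1 else float(out[0])
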