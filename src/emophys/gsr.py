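"""Skin-conductance processing: phasic extraction, SCR peaks, features.

The chain is: zero-phase 2 Hz low-pass (order 4) at the native rate,
decimation to 5 Hz, then tonic/phasic split by a running median over a
+/-4 s window. SCR peaks are located between threshold crossings of the
phasic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dsp import SignalTrace, bandpass, downsample, zero_phase_lowpass

ONSET_THRESHOLD_US = 0.01  # microsiemens; SCR onset amplitude criterion


@dataclass
class PhasicDecomposition:
    filtered: SignalTrace
    tonic: SignalTrace
    phasic: SignalTrace


@dataclass
class SCRPeak:
    onset_t: float
    peak_t: float
    offset_t: float
    amplitude: float

    @property
    def rise_time(self) -> float:
        return self.peak_t - self.onset_t

    @property
    def recovery_time(self) -> float:
        return self.offset_t - self.peak_t


@dataclass
class GSRFeatures:
    n_peaks: int
    amp_peaks_mean: float
    rise_time_mean: float
    recovery_time_mean: float
    avg: float
    sd: float
    max_signed_amp: float
    deriv_avg: float
    deriv_sd: float
    deriv_max: float
    env_avg: float

    def as_dict(self) -> dict[str, float]:
        return {
            "GSR_n_peaks": float(self.n_peaks),
            "GSR_amp_peaks": self.amp_peaks_mean,
            "AVGSR_rise_time": self.rise_time_mean,
            "AVGSR_recovery_time": self.recovery_time_mean,
            "AVGSR": self.avg,
            "SDGSR": self.sd,
            "MAXGSR_sign_amp": self.max_signed_amp,
            "AVGSR_der": self.deriv_avg,
            "SDGSR_der": self.deriv_sd,
            "MAXGSR_der": self.deriv_max,
            "AVenv": self.env_avg,
        }


def preprocess_gsr(raw: SignalTrace, cutoff: float = 2.0, order: int = 4,
                   target_rate: float = 5.0) -> SignalTrace:
    """Low-pass at 2 Hz (order-4 zero-phase) then decimate to 5 Hz."""
    if raw.rate < target_rate:
        raise ValueError("raw rate below target rate")
    filtered = zero_phase_lowpass(raw, order=order, cutoff=cutoff)
    return downsample(filtered, target_rate)


def extract_phasic(filtered: SignalTrace, half_window_s: float = 4.0
                   ) -> PhasicDecomposition:
    """Tonic = running median over +/-half_window_s (truncated at edges);
    phasic = filtered - tonic, so the identity holds samplewise."""
    if filtered.duration < 2 * half_window_s:
        raise ValueError("trace shorter than the median window")
    half = int(round(half_window_s * filtered.rate))
    tonic_vals = (
        pd.Series(filtered.data)
        .rolling(window=2 * half + 1, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    tonic = SignalTrace(tonic_vals, filtered.rate, filtered.units, t0=filtered.t0)
    phasic = SignalTrace(filtered.data - tonic_vals, filtered.rate,
                         filtered.units, t0=filtered.t0)
    return PhasicDecomposition(filtered=filtered, tonic=tonic, phasic=phasic)


def detect_scr_peaks(decomp: PhasicDecomposition,
                     threshold: float = ONSET_THRESHOLD_US) -> list[SCRPeak]:
    """SCR peaks between phasic onset (> threshold) and offset (<= 0) crossings.

    The peak is the maximum of the *filtered* signal inside the
    onset..offset span; its amplitude is the phasic value there. When the
    phasic signal never returns to zero, the offset clamps to the end of
    the trace.
    """
    phasic = decomp.phasic.data
    filt = decomp.filtered.data
    rate = decomp.phasic.rate
    t0 = decomp.phasic.t0
    n = len(phasic)
    peaks: list[SCRPeak] = []
    i = 1
    while i < n:
        if phasic[i] > threshold and phasic[i - 1] <= threshold:
            onset = i
            j = onset + 1
            while j < n and phasic[j] > 0:
                j += 1
            offset = min(j, n - 1)
            if offset <= onset + 1:
                i = offset + 1
                continue
            seg = slice(onset + 1, offset + 1)
            peak = onset + 1 + int(np.argmax(filt[seg]))
            if peak >= offset:
                offset = min(peak + 1, n - 1)
            if onset < peak < offset:
                peaks.append(SCRPeak(
                    onset_t=t0 + onset / rate,
                    peak_t=t0 + peak / rate,
                    offset_t=t0 + offset / rate,
                    amplitude=float(phasic[peak]),
                ))
            i = offset + 1
        else:
            i += 1
    return peaks


def gsr_features(decomp: PhasicDecomposition, peaks: list[SCRPeak],
                 window: tuple[float, float]) -> GSRFeatures:
    """The 11 per-window conductance features.

    Peak-dependent features are NaN (not zero) when no peak falls in the
    window. Derivative features use the first difference of the filtered
    signal scaled by the rate; AVenv is the time-average of the running
    trapezoidal integral of the phasic component over the window.
    """
    t_lo, t_hi = window
    filt_w = decomp.filtered.slice(t_lo, t_hi)
    phasic_w = decomp.phasic.slice(t_lo, t_hi)
    if filt_w.n_samples == 0:
        raise ValueError("window outside trace span")
    x = filt_w.data
    rate = filt_w.rate

    in_win = [p for p in peaks if t_lo <= p.peak_t < t_hi]
    n_peaks = len(in_win)
    if n_peaks:
        amp_mean = float(np.mean([p.amplitude for p in in_win]))
        rise_mean = float(np.mean([p.rise_time for p in in_win]))
        rec_mean = float(np.mean([p.recovery_time for p in in_win]))
    else:
        amp_mean = rise_mean = rec_mean = float("nan")

    deriv = np.diff(x) * rate
    if deriv.size == 0:
        deriv = np.array([np.nan])

    # peak-to-trough swing of the 0.5-1 Hz band-passed signal
    bp = bandpass(decomp.filtered, order=2, low=0.5, high=1.0).slice(t_lo, t_hi).data
    max_signed = _max_swing_between_maxima(bp)

    cum = np.concatenate(([0.0], np.cumsum((phasic_w.data[1:] + phasic_w.data[:-1]) / 2)
                          / rate))
    return GSRFeatures(
        n_peaks=n_peaks,
        amp_peaks_mean=amp_mean,
        rise_time_mean=rise_mean,
        recovery_time_mean=rec_mean,
        avg=float(np.mean(x)),
        sd=float(np.std(x)),
        max_signed_amp=max_signed,
        deriv_avg=float(np.mean(deriv)),
        deriv_sd=float(np.std(deriv)),
        deriv_max=float(np.max(deriv)),
        env_avg=float(np.mean(cum)),
    )


def _max_swing_between_maxima(x: np.ndarray) -> float:
    from scipy.signal import argrelextrema

    maxima = argrelextrema(x, np.greater)[0]
    if len(maxima) < 2:
        return float("nan")
    best = -np.inf
    for a, b in zip(maxima[:-1], maxima[1:]):
        best = max(best, x[a] - np.min(x[a:b + 1]))
    return float(best)
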