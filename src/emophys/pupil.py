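"""Two-eye pupil diameter cleaning and time/frequency features.

Samples outside the physiological 2-8 mm range are blinks: when one eye
is valid it substitutes the other; when both are missing the gap is
linearly interpolated. The cleaned eyes are low-passed at 5 Hz,
decimated to 10 Hz and averaged into a single diameter trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dsp import SignalTrace, band_power, downsample, welch_psd, zero_phase_lowpass

PHYSIO_RANGE_MM = (2.0, 8.0)
DLF_BAND = (0.05, 0.15)
DHF_BAND = (0.15, 0.45)
DVHF_BAND = (0.45, 1.5)


@dataclass
class PupilFeatures:
    avd: float
    sdd: float
    dlf: float
    dhf: float
    dvhf: float
    dlf_dhf: float
    dlfn: float
    dhfn: float

    def as_dict(self) -> dict[str, float]:
        return {"AVD": self.avd, "SDD": self.sdd, "DLF": self.dlf,
                "DHF": self.dhf, "DVHF": self.dvhf, "DLF_DHF": self.dlf_dhf,
                "DLFn": self.dlfn, "DHFn": self.dhfn}


def _interpolate_gaps(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN runs; nearest-valid fill at the edges."""
    valid = ~np.isnan(x)
    if not valid.any():
        raise ValueError("no valid pupil samples in trace")
    if not valid.all():
        idx = np.arange(x.size)
        if not (valid[0] and valid[-1]):
            warnings.warn("pupil trace edge has no valid sample; "
                          "extrapolating nearest valid value")
        x = np.interp(idx, idx[valid], x[valid])
    return x


def clean_pupil(
    left: SignalTrace,
    right: SignalTrace,
    cutoff: float = 5.0,
    order: int = 4,
    target_rate: float = 10.0,
) -> SignalTrace:
    """Blink handling, filtering and averaging into one diameter trace."""
    if left.n_samples != right.n_samples or left.rate != right.rate:
        raise ValueError("left/right traces must share span and rate")
    lo, hi = PHYSIO_RANGE_MM
    l = np.where((left.data >= lo) & (left.data <= hi), left.data, np.nan)
    r = np.where((right.data >= lo) & (right.data <= hi), right.data, np.nan)
    # one-eye blink: borrow the other eye's sample
    l_only = np.isnan(l) & ~np.isnan(r)
    r_only = np.isnan(r) & ~np.isnan(l)
    l[l_only] = r[l_only]
    r[r_only] = l[r_only]
    l = _interpolate_gaps(l)
    r = _interpolate_gaps(r)

    cleaned = []
    for eye in (l, r):
        tr = SignalTrace(eye, left.rate, units="mm", t0=left.t0)
        tr = zero_phase_lowpass(tr, order=order, cutoff=cutoff)
        cleaned.append(downsample(tr, target_rate))
    diameter = (cleaned[0].data + cleaned[1].data) / 2.0
    return SignalTrace(diameter, target_rate, units="mm", t0=left.t0)


def pupil_features(
    diameter: SignalTrace,
    window: tuple[float, float],
    segment_len: int = 300,
    overlap_fraction: float = 0.5,
) -> PupilFeatures:
    """AVD/SDD plus Welch band powers of the detrended diameter.

    Spectral features need at least one 300-sample segment (30 s at
    10 Hz); shorter windows return them as NaN.
    """
    win = diameter.slice(*window)
    if win.n_samples == 0:
        raise ValueError("window outside trace span")
    avd = float(np.mean(win.data))
    sdd = float(np.std(win.data))
    if win.n_samples < segment_len:
        nan = float("nan")
        return PupilFeatures(avd=avd, sdd=sdd, dlf=nan, dhf=nan, dvhf=nan,
                             dlf_dhf=nan, dlfn=nan, dhfn=nan)
    spec = welch_psd(win, segment_len=segment_len,
                     overlap_fraction=overlap_fraction, window="hamming",
                     detrend=True)
    dlf = float(band_power(spec, *DLF_BAND))
    dhf = float(band_power(spec, *DHF_BAND))
    dvhf = float(band_power(spec, *DVHF_BAND))
    dlf_dhf = dlf / dhf if dhf > 0 else float("nan")
    tot = dlf + dhf
    dlfn = dlf / tot if tot > 0 else float("nan")
    dhfn = dhf / tot if tot > 0 else float("nan")
    return PupilFeatures(avd=avd, sdd=sdd, dlf=dlf, dhf=dhf, dvhf=dvhf,
                         dlf_dhf=dlf_dhf, dlfn=dlfn, dhfn=dhfn)
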