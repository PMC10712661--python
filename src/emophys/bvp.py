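"""Blood-volume-pulse fiducials and the VP / PAT features.

Fiducials are anchored to the ECG R-peaks: in each R-R interval the BVP
maximum is the systole, the minimum the diastole, and the pulse onset is
the steepest point of the rising limb before the systolic peak. Pulse
arrival time (PAT) is onset minus R-time; volume pulse (VP) is systolic
minus diastolic amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dsp import SignalTrace, downsample, zero_phase_lowpass
from .hrv import RRSeries


@dataclass
class BeatFiducials:
    r_time: float
    systole_t: float
    systole_amp: float
    diastole_t: float
    diastole_amp: float
    onset_t: float


@dataclass
class BVPFeatures:
    vp: float
    pat: float

    def as_dict(self) -> dict[str, float]:
        return {"VP": self.vp, "PAT": self.pat}


def preprocess_bvp(raw: SignalTrace, cutoff: float = 25.0, order: int = 4,
                   target_rate: float = 250.0) -> SignalTrace:
    """Anti-aliasing low-pass at 25 Hz then decimation to 250 Hz."""
    filtered = zero_phase_lowpass(raw, order=order, cutoff=cutoff)
    return downsample(filtered, target_rate)


def locate_fiducials(bvp: SignalTrace, rr: RRSeries) -> list[BeatFiducials]:
    """Per-beat systole/diastole/onset between consecutive R-peaks.

    Beats with flat segments, no rising-limb inflection, or a PAT outside
    (0, RR) are skipped with a warning count.
    """
    if len(rr) < 2:
        raise ValueError("need at least two R-peaks")
    x = bvp.data
    rate = bvp.rate
    t0 = bvp.t0
    out: list[BeatFiducials] = []
    skipped = 0
    for r_a, r_b in zip(rr.r_times[:-1], rr.r_times[1:]):
        i0 = int(np.ceil((r_a - t0) * rate))
        i1 = int(np.floor((r_b - t0) * rate))
        if i1 - i0 < 4 or i0 < 0 or i1 > len(x):
            skipped += 1
            continue
        seg = x[i0:i1]
        if np.ptp(seg) < 1e-12:
            skipped += 1
            continue
        sys_i = int(np.argmax(seg))
        dia_i = int(np.argmin(seg))
        # onset: steepest rise on the limb climbing to the systolic peak
        limb_start = dia_i if dia_i < sys_i else 0
        if sys_i - limb_start < 2:
            skipped += 1
            continue
        limb = seg[limb_start:sys_i + 1]
        dseg = np.gradient(limb) * rate  # central differences: no half-sample bias
        onset_i = limb_start + int(np.argmax(dseg))
        onset_t = t0 + (i0 + onset_i) / rate
        pat = onset_t - r_a
        if pat <= 0 or pat >= (r_b - r_a):
            skipped += 1
            continue
        out.append(BeatFiducials(
            r_time=float(r_a),
            systole_t=t0 + (i0 + sys_i) / rate,
            systole_amp=float(seg[sys_i]),
            diastole_t=t0 + (i0 + dia_i) / rate,
            diastole_amp=float(seg[dia_i]),
            onset_t=float(onset_t),
        ))
    if skipped:
        warnings.warn(f"{skipped} beat(s) skipped during fiducial detection")
    return out


def bvp_features(fiducials: list[BeatFiducials],
                 window: tuple[float, float]) -> BVPFeatures:
    """Window means of VP and PAT over beats whose R-time is in-window."""
    t_lo, t_hi = window
    sel = [f for f in fiducials if t_lo <= f.r_time < t_hi]
    if not sel:
        return BVPFeatures(vp=float("nan"), pat=float("nan"))
    vp = float(np.mean([f.systole_amp - f.diastole_amp for f in sel]))
    pat = float(np.mean([f.onset_t - f.r_time for f in sel]))
    return BVPFeatures(vp=vp, pat=pat)


def fiducials_to_frame(fiducials: list[BeatFiducials]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in fiducials])
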