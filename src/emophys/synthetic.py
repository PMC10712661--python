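"""Synthetic multimodal recordings with known ground truth.

Every generator here is the inverse of one analysis chain: RR intervals
from the history-dependent inverse-Gaussian model, conductance as tonic
level plus bi-exponential SCR kernels, a pulse waveform delayed from
each R spike by a controllable arrival time, EEG as band-limited noise
with set per-region band powers, and pupil diameter with oscillations
and blinks. All randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import protocol as proto
from .dsp import SignalTrace, bandpass
from .eeg import BANDS, Montage
from .hrv import RRSeries


# --------------------------------------------------------------------------
# Ground-truth records

@dataclass
class RRGroundTruth:
    theta0: float = 0.8
    ar_coeffs: tuple[float, ...] = ()
    shape: float = 1500.0  # inverse-Gaussian shape (seconds)
    mean_modulation: list[tuple[float, float]] = field(default_factory=list)
    realized_mu: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        _check_ar_stable(np.asarray(self.ar_coeffs, dtype=float))


def _check_ar_stable(coeffs: np.ndarray) -> None:
    if coeffs.size == 0:
        return
    roots = np.roots(np.concatenate(([1.0], -coeffs)))
    if np.any(np.abs(roots) >= 1.0):
        raise ValueError("AR coefficients are not stable")


@dataclass
class SCRGroundTruth:
    event_times: np.ndarray = field(default_factory=lambda: np.array([]))
    amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))
    # fast enough that the +/-4 s running median sees mostly baseline,
    # keeping the phasic amplitude recoverable within 10%
    rise_tau: float = 0.3
    decay_tau: float = 1.0
    tonic_level: float = 2.0

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need decay_tau > rise_tau > 0")
        if np.any(self.amplitudes <= 0):
            raise ValueError("SCR amplitudes must be positive")


@dataclass
class BVPGroundTruth:
    pat: float = 0.25
    vp_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.pat <= 0:
            raise ValueError("pat must be positive")


@dataclass
class EEGGroundTruth:
    """Target integrated band power per (region, band)."""

    powers: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def uniform(cls, power: float) -> "EEGGroundTruth":
        return cls({(region, band): power
                    for region in ("frontal", "parietal") for band in BANDS})

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.powers.values()):
            raise ValueError("band powers must be non-negative")


@dataclass
class PupilGroundTruth:
    baseline: float = 5.0
    oscillations: list[tuple[float, float]] = field(default_factory=list)
    blink_intervals_left: list[tuple[float, float]] = field(default_factory=list)
    blink_intervals_right: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 2.0 <= self.baseline <= 8.0:
            raise ValueError("baseline must lie in the physiological [2, 8] mm range")


@dataclass
class MultimodalRecording:
    schedule: proto.ProtocolSchedule
    gsr: SignalTrace | None = None
    ecg: SignalTrace | None = None
    bvp: SignalTrace | None = None
    eeg: SignalTrace | None = None
    pupil_left: SignalTrace | None = None
    pupil_right: SignalTrace | None = None
    rr_true: RRSeries | None = None
    truth: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# RR intervals

def simulate_rr_ig(
    duration: float,
    truth: RRGroundTruth,
    seed: int,
    theta0_scale_fn=None,
) -> tuple[RRSeries, RRGroundTruth]:
    """Draw R-event times from the history-dependent inverse-Gaussian model.

    Each interval is Wald-distributed with shape ``truth.shape`` and mean
    theta_0(t) + sum_i theta_i RR_{k-i}; ``mean_modulation`` entries
    (frequency, relative amplitude) modulate theta_0 multiplicatively,
    as does the optional per-time ``theta0_scale_fn``.
    """
    rng = np.random.default_rng(seed)
    ar = np.asarray(truth.ar_coeffs, dtype=float)
    p = ar.size
    stationary = truth.theta0 / max(1.0 - ar.sum(), 1e-6)
    history = [stationary] * p
    t = 0.0
    times = [0.0]
    mus = []
    while t < duration:
        theta0_t = truth.theta0
        for f_hz, rel_amp in truth.mean_modulation:
            theta0_t *= 1.0 + rel_amp * np.sin(2 * np.pi * f_hz * t)
        if theta0_scale_fn is not None:
            theta0_t *= theta0_scale_fn(t)
        mu = theta0_t + (ar @ history[:p] if p else 0.0)
        mu = max(mu, 0.05)
        w = float(rng.wald(mu, truth.shape))
        w = min(max(w, 1e-3), 5.0)
        t += w
        if t >= duration:
            break
        times.append(t)
        mus.append(mu)
        if p:
            history = [w] + history[:-1]
    realized = replace(truth, realized_mu=np.asarray(mus))
    return RRSeries(np.asarray(times)), realized


# --------------------------------------------------------------------------
# GSR

def scr_kernel(u: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Bi-exponential SCR shape normalised to unit peak."""
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    out = np.where(u >= 0, np.exp(-u / decay_tau) - np.exp(-u / rise_tau), 0.0)
    return out / peak


def simulate_gsr(
    truth: SCRGroundTruth,
    duration: float,
    rate: float = 256.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SignalTrace:
    """Tonic level plus SCR kernels at the event times, plus Gaussian noise."""
    if rate < 10:
        raise ValueError("rate must be at least 10 Hz")
    if truth.event_times.size and (np.any(truth.event_times < 0)
                                   or np.any(truth.event_times >= duration)):
        raise ValueError("SCR events must fall inside the trace duration")
    n = int(round(duration * rate))
    x = np.full(n, truth.tonic_level, dtype=float)
    support = int(round(min(12 * truth.decay_tau, duration) * rate))
    for t_ev, amp in zip(truth.event_times, truth.amplitudes):
        i0 = int(np.ceil(t_ev * rate))
        i1 = min(n, i0 + support)
        u = np.arange(i0, i1) / rate - t_ev
        x[i0:i1] += amp * scr_kernel(u, truth.rise_tau, truth.decay_tau)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return SignalTrace(x, rate, units="uS")


# --------------------------------------------------------------------------
# ECG + BVP

def _add_gaussian(x: np.ndarray, rate: float, center: float, amp: float,
                  width: float) -> None:
    i0 = max(0, int((center - 5 * width) * rate))
    i1 = min(len(x), int((center + 5 * width) * rate) + 1)
    if i1 <= i0:
        return
    tt = np.arange(i0, i1) / rate
    x[i0:i1] += amp * np.exp(-0.5 * ((tt - center) / width) ** 2)


# (offset s, amplitude, width s) relative to the R peak
_PQRST = [(-0.20, 0.15, 0.025), (-0.035, -0.10, 0.010), (0.0, 1.0, 0.009),
          (0.035, -0.15, 0.010), (0.25, 0.30, 0.040)]


def _pulse_kernel(u: np.ndarray, rise_w: float, decay_tau: float) -> np.ndarray:
    """Unit-peak pulse: half-cosine upstroke of width ``rise_w`` whose
    steepest point sits exactly at u = 0 (the pulse onset), followed by
    exponential decay. An interior derivative maximum survives zero-phase
    anti-aliasing filtering, so arrival time stays recoverable to a sample."""
    out = np.zeros_like(u)
    rising = (u >= -rise_w / 2) & (u <= rise_w / 2)
    out[rising] = 0.5 * (1.0 + np.sin(np.pi * u[rising] / rise_w))
    falling = u > rise_w / 2
    out[falling] = np.exp(-(u[falling] - rise_w / 2) / decay_tau)
    return out


def simulate_ecg_bvp(
    rr: RRSeries,
    truth: BVPGroundTruth,
    rate: float = 2048.0,
    duration: float | None = None,
    template: str = "spike",
    rise_w: float = 0.12,
    decay_tau: float = 0.12,
) -> tuple[SignalTrace, SignalTrace]:
    """Stylised ECG (one dominant R spike per event) and a coupled pulse
    waveform whose onset (steepest upstroke point) trails each R peak by
    ``truth.pat`` and whose systolic-diastolic swing is
    ``truth.vp_amplitude``."""
    if len(rr) > 1 and truth.pat >= np.min(rr.intervals):
        raise ValueError("pat must be smaller than the minimum RR interval")
    if duration is None:
        duration = (rr.r_times[-1] + 1.5) if len(rr) else 1.0
    n = int(round(duration * rate))
    ecg = np.zeros(n)
    bvp = np.zeros(n)
    for r in rr.r_times:
        if template == "pqrst":
            for off, amp, width in _PQRST:
                _add_gaussian(ecg, rate, r + off, amp, width)
        else:
            _add_gaussian(ecg, rate, r, 1.0, 0.008)
        onset = r + truth.pat
        i0 = max(0, int(np.ceil((onset - rise_w / 2) * rate)))
        i1 = min(n, i0 + int((rise_w + 12 * decay_tau) * rate))
        if i1 <= i0:
            continue
        u = np.arange(i0, i1) / rate - onset
        bvp[i0:i1] += truth.vp_amplitude * _pulse_kernel(u, rise_w, decay_tau)
    return (SignalTrace(ecg, rate, units="mV"),
            SignalTrace(bvp, rate, units="a.u."))


# --------------------------------------------------------------------------
# EEG

def _region_of(label: str, montage: Montage) -> str:
    if label in montage.frontal:
        return "frontal"
    if label in montage.parietal:
        return "parietal"
    return "other"


def simulate_eeg(
    truth: EEGGroundTruth,
    duration: float,
    rate: float = 300.0,
    montage: Montage | None = None,
    seed: int = 0,
    band_scale_fn=None,
) -> SignalTrace:
    """Each channel is a sum of band-pass-filtered white noise components
    scaled so the integrated power of each band matches the channel
    region's target (non-frontal/parietal channels get the mean target).
    ``band_scale_fn(band, times)`` may return a power-scale envelope."""
    montage = montage or Montage()
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    data = np.zeros((len(montage.labels), n))
    times = np.arange(n) / rate
    for ci, label in enumerate(montage.labels):
        region = _region_of(label, montage)
        for band, (lo, hi) in BANDS.items():
            if region == "other":
                p_f = truth.powers.get(("frontal", band), 0.0)
                p_p = truth.powers.get(("parietal", band), 0.0)
                target = 0.5 * (p_f + p_p)
            else:
                target = truth.powers.get((region, band), 0.0)
            if target <= 0:
                continue
            white = SignalTrace(rng.normal(0.0, 1.0, n), rate)
            comp = bandpass(white, order=4, low=lo, high=hi).data
            var = np.var(comp)
            if var <= 0:
                continue
            comp *= np.sqrt(target / var)
            if band_scale_fn is not None:
                comp = comp * np.sqrt(band_scale_fn(band, times))
            data[ci] += comp
    return SignalTrace(data, rate, units="uV", channel_labels=list(montage.labels))


# --------------------------------------------------------------------------
# Pupil

def simulate_pupil(
    truth: PupilGroundTruth,
    duration: float,
    rate: float = 60.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    baseline_fn=None,
) -> tuple[SignalTrace, SignalTrace]:
    """Baseline plus sinusoidal oscillations per eye; blink samples are
    forced outside the [2, 8] mm physiological range (to 0 mm)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    base = baseline_fn(t) if baseline_fn is not None else truth.baseline
    common = np.broadcast_to(np.asarray(base, dtype=float), (n,)).copy()
    for f_hz, amp in truth.oscillations:
        common += amp * np.sin(2 * np.pi * f_hz * t)
    eyes = []
    for blinks in (truth.blink_intervals_left, truth.blink_intervals_right):
        x = common.copy()
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, n)
        for b0, b1 in blinks:
            x[(t >= b0) & (t < b1)] = 0.0
        eyes.append(SignalTrace(x, rate, units="mm"))
    return eyes[0], eyes[1]


# --------------------------------------------------------------------------
# Full experiment

@dataclass
class SessionEffect:
    """Per-session generator settings; the effect map varies these."""

    scr_rate_hz: float = 0.06
    scr_amp_us: float = 0.5
    theta0_scale: float = 1.0
    eeg_beta_scale: float = 1.0
    pupil_baseline_mm: float = 5.0


@dataclass
class EffectMap:
    base: SessionEffect = field(default_factory=SessionEffect)
    overrides: dict[tuple[str, str], SessionEffect] = field(default_factory=dict)

    def resolve(self, phase: str, kind: str) -> SessionEffect:
        return self.overrides.get((phase, kind), self.base)


def null_effect_map() -> EffectMap:
    return EffectMap()


def simulate_experiment(
    schedule: proto.ProtocolSchedule,
    effect_map: EffectMap,
    seed: int,
    signals: tuple[str, ...] = ("gsr", "ecg", "bvp", "eeg", "pupil"),
    rates: dict[str, float] | None = None,
) -> MultimodalRecording:
    """Simulate a full protocol run with per-session ground-truth deltas.

    The per-session effects (SCR rate/amplitude, mean RR scaling, EEG
    beta power scaling, pupil baseline) are resolved from the effect map
    and recorded in ``truth`` for end-to-end recovery tests.
    """
    rates = {"gsr": 256.0, "ecg": 2048.0, "bvp": 2048.0,
             "eeg": 300.0, "pupil": 60.0, **(rates or {})}
    duration = schedule.t_end + 1.0
    rng = np.random.default_rng(seed)
    rec = MultimodalRecording(schedule=schedule)
    windows = schedule.all_windows()
    session_effects = {
        (w.phase, w.kind, w.arousal_level, w.t_start): effect_map.resolve(w.phase, w.kind)
        for w in windows
    }
    rec.truth["session_effects"] = session_effects

    if "gsr" in signals:
        ev_times, ev_amps, per_session = [], [], {}
        for w in windows:
            eff = effect_map.resolve(w.phase, w.kind)
            lam = eff.scr_rate_hz * (w.duration - 4.0)
            n_ev = rng.poisson(lam) if lam > 0 else 0
            tt = np.sort(rng.uniform(w.t_start + 1.0, w.t_end - 3.0, n_ev))
            aa = eff.scr_amp_us * rng.uniform(0.8, 1.2, n_ev)
            ev_times.append(tt)
            ev_amps.append(aa)
            per_session[(w.phase, w.kind, w.arousal_level, w.t_start)] = (tt, aa)
        scr_truth = SCRGroundTruth(
            event_times=np.concatenate(ev_times) if ev_times else np.array([]),
            amplitudes=np.concatenate(ev_amps) if ev_amps else np.array([]),
        )
        rec.gsr = simulate_gsr(scr_truth, duration, rates["gsr"],
                               seed=int(rng.integers(2 ** 31)), noise_sd=0.002)
        rec.truth["scr"] = scr_truth
        rec.truth["scr_per_session"] = per_session

    if "ecg" in signals or "bvp" in signals:
        def theta0_scale(t: float) -> float:
            for w in windows:
                if w.t_start <= t < w.t_end:
                    return effect_map.resolve(w.phase, w.kind).theta0_scale
            return 1.0

        rr_truth = RRGroundTruth(theta0=0.8, shape=1500.0,
                                 mean_modulation=[(0.1, 0.03), (0.25, 0.03)])
        rr, realized = simulate_rr_ig(duration, rr_truth,
                                      seed=int(rng.integers(2 ** 31)),
                                      theta0_scale_fn=theta0_scale)
        bvp_truth = BVPGroundTruth(pat=0.25, vp_amplitude=1.0)
        ecg, bvp = simulate_ecg_bvp(rr, bvp_truth, rate=rates["ecg"],
                                    duration=duration)
        rec.ecg, rec.bvp, rec.rr_true = ecg, bvp, rr
        rec.truth["rr"] = realized
        rec.truth["bvp"] = bvp_truth

    if "eeg" in signals:
        eeg_truth = EEGGroundTruth.uniform(1.0)

        def beta_scale(band: str, times: np.ndarray) -> np.ndarray:
            scale = np.ones_like(times)
            if band != "beta":
                return scale
            for w in windows:
                s = effect_map.resolve(w.phase, w.kind).eeg_beta_scale
                if s != 1.0:
                    scale[(times >= w.t_start) & (times < w.t_end)] = s
            return scale

        rec.eeg = simulate_eeg(eeg_truth, duration, rates["eeg"],
                               seed=int(rng.integers(2 ** 31)),
                               band_scale_fn=beta_scale)
        rec.truth["eeg"] = eeg_truth

    if "pupil" in signals:
        n_blinks = rng.poisson(0.05 * duration)
        starts = np.sort(rng.uniform(0, duration - 0.5, n_blinks))
        blinks = [(s, s + 0.3) for s in starts]
        pupil_truth = PupilGroundTruth(
            baseline=5.0, oscillations=[(0.1, 0.15), (0.3, 0.05)],
            blink_intervals_left=blinks, blink_intervals_right=blinks,
        )

        def baseline_fn(t: np.ndarray) -> np.ndarray:
            base = np.full_like(t, pupil_truth.baseline)
            for w in windows:
                b = effect_map.resolve(w.phase, w.kind).pupil_baseline_mm
                if b != pupil_truth.baseline:
                    base[(t >= w.t_start) & (t < w.t_end)] = b
            return base

        left, right = simulate_pupil(pupil_truth, duration, rates["pupil"],
                                     seed=int(rng.integers(2 ** 31)),
                                     noise_sd=0.02, baseline_fn=baseline_fn)
        rec.pupil_left, rec.pupil_right = left, right
        rec.truth["pupil"] = pupil_truth

    return rec
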