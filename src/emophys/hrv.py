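"""Point-process heartbeat model with time-varying AR spectral indices.

R events are detected with a Pan-Tompkins style chain. The inter-beat
intervals are modeled with a history-dependent inverse-Gaussian density
whose mean is an AR combination of the previous ``p`` intervals,

    mu_k = theta_0 + sum_i theta_i * RR_{k-i},

and whose shape parameter ``lambda`` gives the interval variance
``mu^3 / lambda``. Parameters are re-estimated on a time grid by locally
weighted maximum likelihood (exponential forgetting inside a sliding
window), and the AR coefficients yield an instantaneous parametric
spectrum integrated over the VLF/LF/HF bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import signal as sps
from scipy import stats as spstats

from .dsp import SignalTrace, Spectrum, bandpass, downsample, zero_phase_lowpass

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.5)

RR_MIN_S = 0.25  # physiologic guard for accepted beats
RR_MAX_S = 3.0


@dataclass
class RRSeries:
    """Ordered R-event times (seconds) with derived inter-beat intervals."""

    r_times: np.ndarray

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.size and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.r_times)

    def __len__(self) -> int:
        return self.r_times.size

    def physiologic_mask(self) -> np.ndarray:
        """True for intervals inside the (0.25 s, 3 s) guard."""
        rr = self.intervals
        return (rr > RR_MIN_S) & (rr < RR_MAX_S)


@dataclass
class IGParams:
    theta0: float
    ar_coeffs: np.ndarray
    shape: float
    order: int

    def __post_init__(self) -> None:
        self.ar_coeffs = np.asarray(self.ar_coeffs, dtype=float)
        if self.shape <= 0:
            raise ValueError("shape parameter must be positive")
        if self.ar_coeffs.size != self.order:
            raise ValueError("ar_coeffs length must equal order")


@dataclass
class InstantaneousEstimate:
    t: float
    mu_rr: float
    sigma2: float
    vlf: float
    lf: float
    hf: float
    tot: float
    lf_hf: float
    lfn: float
    hfn: float

    FIELDS = ("mu_rr", "sigma2", "vlf", "lf", "hf", "tot", "lf_hf", "lfn", "hfn")


@dataclass
class HRVFeatures:
    mu_rr: float
    sigma2: float
    vlf: float
    lf: float
    hf: float
    tot: float
    lf_hf: float
    lfn: float
    hfn: float

    def as_dict(self) -> dict[str, float]:
        return {
            "RR_mu": self.mu_rr, "RR_sigma2": self.sigma2,
            "RR_VLF": self.vlf, "RR_LF": self.lf, "RR_HF": self.hf,
            "RR_TOT": self.tot, "RR_LF_HF": self.lf_hf,
            "RR_LFn": self.lfn, "RR_HFn": self.hfn,
        }


# --------------------------------------------------------------------------
# ECG preprocessing and R-peak detection

def preprocess_ecg(raw: SignalTrace, cutoff: float = 125.0, order: int = 4,
                   target_rate: float = 250.0) -> SignalTrace:
    """Anti-aliasing low-pass at 125 Hz then decimation to 250 Hz."""
    filtered = zero_phase_lowpass(raw, order=order, cutoff=cutoff)
    return downsample(filtered, target_rate)


def detect_rpeaks(ecg: SignalTrace, refractory_s: float = 0.2) -> RRSeries:
    """Pan-Tompkins style R-peak detection.

    Band-pass 5-15 Hz, differentiate, square, 150 ms moving-window
    integration, then adaptive signal/noise thresholding with a 200 ms
    refractory period. Detected locations are refined to the local
    maximum of the band-passed ECG.
    """
    if ecg.duration < 5.0:
        raise ValueError("need at least 5 s of ECG")
    rate = ecg.rate
    bp = bandpass(ecg, order=2, low=5.0, high=15.0).data
    deriv = np.gradient(bp) * rate
    squared = deriv ** 2
    win = max(1, int(round(0.150 * rate)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    if np.max(mwi) <= 0:
        warnings.warn("no beats found in ECG trace")
        return RRSeries(np.array([]))

    cand, _ = sps.find_peaks(mwi, distance=max(1, int(refractory_s * rate)))
    if cand.size == 0:
        warnings.warn("no beats found in ECG trace")
        return RRSeries(np.array([]))

    # adaptive signal/noise levels (initialised on the first 2 s)
    head = mwi[: int(2 * rate)]
    spki = 0.25 * np.max(head) if head.size else np.max(mwi) * 0.25
    npki = 0.5 * np.mean(head) if head.size else 0.0
    accepted = []
    for idx in cand:
        thresh = npki + 0.25 * (spki - npki)
        if mwi[idx] > thresh:
            accepted.append(idx)
            spki = 0.125 * mwi[idx] + 0.875 * spki
        else:
            npki = 0.125 * mwi[idx] + 0.875 * npki
    if not accepted:
        warnings.warn("no beats found in ECG trace")
        return RRSeries(np.array([]))

    # refine on the band-passed signal
    half = int(round(0.1 * rate))
    r_idx = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(len(bp), idx + half + 1)
        r_idx.append(lo + int(np.argmax(bp[lo:hi])))
    r_idx = np.unique(r_idx)
    # enforce refractory after refinement
    keep = [r_idx[0]]
    for idx in r_idx[1:]:
        if (idx - keep[-1]) / rate >= refractory_s:
            keep.append(idx)
    return RRSeries(ecg.t0 + np.asarray(keep) / rate)


# --------------------------------------------------------------------------
# Inverse-Gaussian primitives

def ig_density(w: float | np.ndarray, mu: float, shape: float) -> float | np.ndarray:
    """Inverse-Gaussian density with mean ``mu`` and shape ``shape``.

    f(w) = sqrt(shape / (2 pi w^3)) * exp(-shape (w - mu)^2 / (2 mu^2 w))
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("w must be positive")
    if mu <= 0 or shape <= 0:
        raise ValueError("mu and shape must be positive")
    out = np.sqrt(shape / (2 * np.pi * w ** 3)) * np.exp(
        -shape * (w - mu) ** 2 / (2 * mu ** 2 * w)
    )
    return out if out.ndim else float(out)


def ig_variance(mu: float, shape: float) -> float:
    """Closed-form inverse-Gaussian variance mu^3 / shape."""
    return mu ** 3 / shape


def mu_rr(params: IGParams, history: np.ndarray) -> float:
    """AR mean of the next interval given the last ``p`` intervals
    (history[0] is the most recent)."""
    history = np.asarray(history, dtype=float)
    if history.size != params.order:
        raise ValueError(
            f"history length {history.size} != model order {params.order}"
        )
    return float(params.theta0 + params.ar_coeffs @ history)


# --------------------------------------------------------------------------
# Local maximum-likelihood fitting

def _design(intervals: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Regression targets y_k = RR_k and lagged histories X[k] =
    (RR_{k-1} ... RR_{k-p}) for k >= p."""
    y = intervals[p:]
    if p == 0:
        return np.empty((y.size, 0)), y
    X = np.column_stack([intervals[p - i:len(intervals) - i] for i in range(1, p + 1)])
    return X, y


def _profile_objective(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                       w: np.ndarray) -> float:
    """Weighted mean of (y-mu)^2/(mu^2 y); minimising this maximises the
    lambda-profiled inverse-Gaussian log-likelihood."""
    mu = theta[0] + X @ theta[1:]
    if np.any(mu <= 1e-4):
        return 1e12
    d = (y - mu) ** 2 / (mu ** 2 * y)
    return float(np.sum(w * d) / np.sum(w))


def _profile_gradient(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                      w: np.ndarray) -> np.ndarray:
    """d/dtheta of the profiled objective; dd/dmu = -2 (y - mu) / mu^3."""
    mu = theta[0] + X @ theta[1:]
    if np.any(mu <= 1e-4):
        return np.zeros_like(theta)
    dd = -2.0 * (y - mu) / mu ** 3
    coef = w * dd / np.sum(w)
    return np.concatenate(([coef.sum()], coef @ X))


def _weighted_ls_init(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(y.size), X])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    return coef


def local_ml_fit(
    rr: RRSeries,
    t: float,
    order: int = 8,
    window_s: float = 90.0,
    forgetting: float = 0.98,
    theta_init: np.ndarray | None = None,
) -> IGParams | None:
    """Locally weighted ML fit of the inverse-Gaussian AR model at time t.

    Beats with R-time in (t - window_s, t] enter the likelihood with
    weight forgetting**(t - R_k). Returns None when fewer than order + 2
    usable beats are available.
    """
    if not 0 < forgetting <= 1:
        raise ValueError("forgetting must be in (0, 1]")
    intervals = rr.intervals
    ends = rr.r_times[1:]  # time at which each interval completes
    X_all, y_all = _design(intervals, order)
    end_all = ends[order:]
    mask = (end_all > t - window_s) & (end_all <= t)
    X, y, te = X_all[mask], y_all[mask], end_all[mask]
    if y.size < order + 2:
        return None
    w = forgetting ** (t - te)

    x0 = theta_init if theta_init is not None else _weighted_ls_init(X, y, w)
    res = optimize.minimize(
        _profile_objective, x0, args=(X, y, w), jac=_profile_gradient,
        method="BFGS", options={"gtol": 1e-10, "maxiter": 200},
    )
    theta = res.x if np.isfinite(res.fun) and res.fun < 1e11 else x0
    obj = _profile_objective(theta, X, y, w)
    if not np.isfinite(obj) or obj >= 1e11:
        warnings.warn("local ML fit failed to produce a valid mean; "
                      "falling back to least squares")
        theta = _weighted_ls_init(X, y, w)
        obj = _profile_objective(theta, X, y, w)
        if not np.isfinite(obj) or obj >= 1e11:
            return None
    shape = 1.0 / max(obj, 1e-12)
    return IGParams(theta0=float(theta[0]), ar_coeffs=theta[1:], shape=float(shape),
                    order=order)


def log_likelihood(params: IGParams, rr: RRSeries) -> float:
    """Unweighted inverse-Gaussian AR log-likelihood over all usable beats."""
    X, y = _design(rr.intervals, params.order)
    mu = params.theta0 + X @ params.ar_coeffs
    if np.any(mu <= 0):
        return -np.inf
    lam = params.shape
    return float(np.sum(0.5 * (np.log(lam) - np.log(2 * np.pi * y ** 3))
                        - lam * (y - mu) ** 2 / (2 * mu ** 2 * y)))


# --------------------------------------------------------------------------
# Spectral indices

def instantaneous_spectrum(params: IGParams, mu: float, n_freq: int = 256,
                           f_max: float = 0.5) -> tuple[Spectrum, dict[str, float]]:
    """Parametric AR spectrum of the interval series and its band indices.

    S(f) = sigma2 * dt / |1 - sum_i theta_i exp(-2j pi f i dt)|^2 with
    dt = mu (the local mean interval). Bands: VLF [0, 0.04), LF
    [0.04, 0.15), HF [0.15, 0.5) Hz.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    sigma2 = ig_variance(mu, params.shape)
    freqs = np.linspace(0.0, f_max, n_freq)
    dt = mu
    k = np.arange(1, params.order + 1)
    denom = np.abs(1.0 - np.exp(-2j * np.pi * freqs[:, None] * k * dt)
                   @ params.ar_coeffs) ** 2 if params.order else np.ones(n_freq)
    dens = sigma2 * dt / np.maximum(denom, 1e-12)
    spec = Spectrum(frequencies=freqs, density=dens)
    from .dsp import band_power

    vlf = band_power(spec, *VLF_BAND)
    lf = band_power(spec, *LF_BAND)
    hf = band_power(spec, *HF_BAND)
    tot = band_power(spec, 0.0, f_max)
    lf_hf = lf / hf if hf > 0 else float("nan")
    denom_n = lf + hf
    lfn = lf / denom_n if denom_n > 0 else float("nan")
    hfn = hf / denom_n if denom_n > 0 else float("nan")
    return spec, {"vlf": vlf, "lf": lf, "hf": hf, "tot": tot,
                  "lf_hf": lf_hf, "lfn": lfn, "hfn": hfn}


def track(
    rr: RRSeries,
    grid_step: float = 0.25,
    order: int = 8,
    window_s: float = 90.0,
    forgetting: float = 0.98,
) -> list[InstantaneousEstimate]:
    """Instantaneous estimates on a regular time grid.

    Each grid point re-fits the local model warm-started from the
    previous one; non-converged points carry the previous parameters.
    """
    if len(rr) < order + 3:
        return []
    estimates: list[InstantaneousEstimate] = []
    t_first = rr.r_times[order + 2]
    t_last = rr.r_times[-1]
    grid = np.arange(t_first, t_last + 1e-9, grid_step)
    theta_prev: np.ndarray | None = None
    params_prev: IGParams | None = None
    intervals = rr.intervals
    for t in grid:
        params = local_ml_fit(rr, t, order=order, window_s=window_s,
                              forgetting=forgetting, theta_init=theta_prev)
        if params is None:
            params = params_prev
            if params is None:
                continue
        theta_prev = np.concatenate(([params.theta0], params.ar_coeffs))
        params_prev = params
        # most recent p intervals completed before t (history[0] newest)
        k = np.searchsorted(rr.r_times, t, side="right") - 1
        if k < params.order:
            continue
        hist = intervals[k - params.order:k][::-1]
        mu = mu_rr(params, hist)
        if mu <= 0:
            continue
        _, bands = instantaneous_spectrum(params, mu)
        estimates.append(InstantaneousEstimate(
            t=float(t), mu_rr=mu, sigma2=ig_variance(mu, params.shape), **bands))
    return estimates


def hrv_features(tracked: list[InstantaneousEstimate],
                 window: tuple[float, float]) -> HRVFeatures:
    """Arithmetic means of every instantaneous index over the window."""
    t_lo, t_hi = window
    sel = [e for e in tracked if t_lo <= e.t < t_hi]
    if not sel:
        return HRVFeatures(*([float("nan")] * 9))
    vals = {name: float(np.nanmean([getattr(e, name) for e in sel]))
            for name in InstantaneousEstimate.FIELDS}
    return HRVFeatures(**vals)


# --------------------------------------------------------------------------
# Goodness of fit

def time_rescaling_uniforms(params: IGParams, rr: RRSeries) -> np.ndarray:
    """Map each interval through its fitted conditional CDF; values are
    approximately uniform when the model is well specified."""
    X, y = _design(rr.intervals, params.order)
    mu = params.theta0 + X @ params.ar_coeffs
    valid = mu > 0
    lam = params.shape
    return spstats.invgauss.cdf(y[valid], mu[valid] / lam, scale=lam)


def time_rescaling_ks(params: IGParams, rr: RRSeries) -> tuple[float, float]:
    u = time_rescaling_uniforms(params, rr)
    res = spstats.kstest(u, "uniform")
    return float(res.statistic), float(res.pvalue)
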