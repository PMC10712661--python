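"""EEG channel repair, common-average referencing and band features.

Channels follow the 21-electrode 10-20 montage. Band powers are Welch
integrals in delta (1-3 Hz), theta (4-7 Hz), alpha (8-12 Hz) and beta
(16-38 Hz); gamma is deliberately excluded. The beta/theta ratio per
region is the attention index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dsp import SignalTrace, band_power, bandpass, welch_psd

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (16.0, 38.0),
}

MONTAGE_1020_LABELS = [
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T7/T3", "T8/T4",
    "Pz", "P3", "P4", "P7/T5", "P8/T6",
    "O1", "O2", "A1", "A2",
]

LABEL_ALIASES = {
    "T3": "T7/T3", "T7": "T7/T3",
    "T4": "T8/T4", "T8": "T8/T4",
    "T5": "P7/T5", "P7": "P7/T5",
    "T6": "P8/T6", "P8": "P8/T6",
}

_NEIGHBORS = {
    "Fp1": ["Fp2", "F3", "F7", "Fz"],
    "Fp2": ["Fp1", "F4", "F8", "Fz"],
    "Fz": ["Fp1", "Fp2", "F3", "F4", "Cz"],
    "F3": ["Fp1", "Fz", "F7", "C3"],
    "F4": ["Fp2", "Fz", "F8", "C4"],
    "F7": ["Fp1", "F3", "T7/T3"],
    "F8": ["Fp2", "F4", "T8/T4"],
    "Cz": ["Fz", "C3", "C4", "Pz"],
    "C3": ["F3", "Cz", "T7/T3", "P3"],
    "C4": ["F4", "Cz", "T8/T4", "P4"],
    "T7/T3": ["F7", "C3", "P7/T5"],
    "T8/T4": ["F8", "C4", "P8/T6"],
    "Pz": ["P3", "P4", "Cz"],
    "P3": ["C3", "Pz", "P7/T5", "O1"],
    "P4": ["C4", "Pz", "P8/T6", "O2"],
    "P7/T5": ["T7/T3", "P3", "O1"],
    "P8/T6": ["T8/T4", "P4", "O2"],
    "O1": ["P3", "P7/T5", "O2"],
    "O2": ["P4", "P8/T6", "O1"],
    "A1": ["T7/T3"],
    "A2": ["T8/T4"],
}

FRONTAL = ["Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8"]
PARIETAL = ["Pz", "P3", "P4", "P7/T5", "P8/T6"]
MASTOIDS = ["A1", "A2"]


@dataclass
class Montage:
    labels: list[str] = field(default_factory=lambda: list(MONTAGE_1020_LABELS))
    neighbors: dict[str, list[str]] = field(default_factory=lambda: dict(_NEIGHBORS))
    frontal: list[str] = field(default_factory=lambda: list(FRONTAL))
    parietal: list[str] = field(default_factory=lambda: list(PARIETAL))
    reference_excluded: list[str] = field(default_factory=lambda: list(MASTOIDS))

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")

    def canonical(self, label: str) -> str:
        label = LABEL_ALIASES.get(label, label)
        if label not in self.labels:
            raise KeyError(f"unknown electrode label {label!r}")
        return label

    def scalp_labels(self) -> list[str]:
        return [l for l in self.labels if l not in self.reference_excluded]


def interpolate_channel(trace: SignalTrace, bad: str,
                        montage: Montage | None = None) -> SignalTrace:
    """Replace a corrupted channel by the mean of its montage neighbours."""
    montage = montage or Montage()
    bad = montage.canonical(bad)
    neigh = montage.neighbors.get(bad)
    if not neigh:
        raise KeyError(f"no neighbour set for {bad!r}")
    labels = trace.channel_labels
    data = trace.data.copy()
    idx = labels.index(bad)
    neigh_idx = [labels.index(n) for n in neigh]
    data[idx] = data[neigh_idx].mean(axis=0)
    return replace(trace, data=data)


def car_reference(trace: SignalTrace, montage: Montage | None = None) -> SignalTrace:
    """Common-average re-referencing over the scalp channels.

    The instantaneous mean of the non-mastoid channels is subtracted from
    every channel (including the mastoids), so the operation is
    idempotent and removes any common-mode component.
    """
    montage = montage or Montage()
    labels = trace.channel_labels
    scalp_idx = [labels.index(l) for l in montage.scalp_labels() if l in labels]
    if not scalp_idx:
        raise ValueError("no scalp channels found in trace")
    common = trace.data[scalp_idx].mean(axis=0)
    return replace(trace, data=trace.data - common)


def band_filter(trace: SignalTrace, band: str) -> SignalTrace:
    """Zero-phase band-pass in one of the canonical EEG bands."""
    if band not in BANDS:
        raise KeyError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    low, high = BANDS[band]
    return bandpass(trace, order=4, low=low, high=high)


@dataclass
class EEGFeatures:
    band_powers: dict[str, float]  # keys like "delta_F", "beta_P"
    attention_frontal: float
    attention_parietal: float

    def as_dict(self) -> dict[str, float]:
        out = {f"EEG_{k}": v for k, v in self.band_powers.items()}
        out["EEG_beta_theta_F"] = self.attention_frontal
        out["EEG_beta_theta_P"] = self.attention_parietal
        return out


def eeg_features(
    trace: SignalTrace,
    window: tuple[float, float],
    montage: Montage | None = None,
    segment_s: float = 2.0,
    overlap_fraction: float = 0.5,
) -> EEGFeatures:
    """Region-averaged Welch band powers and beta/theta attention indices.

    Per channel, the Welch PSD of the in-window samples is integrated
    over each band; region power is the mean over member channels.
    """
    montage = montage or Montage()
    win = trace.slice(*window)
    seg_len = min(int(round(segment_s * trace.rate)), win.n_samples)
    spec = welch_psd(win, segment_len=seg_len, overlap_fraction=overlap_fraction,
                     window="hamming")
    labels = trace.channel_labels
    powers: dict[str, float] = {}
    for region_name, members in (("F", montage.frontal), ("P", montage.parietal)):
        idx = [labels.index(l) for l in members if l in labels]
        if not idx:
            raise ValueError(f"no channels found for region {region_name}")
        for band in BANDS:
            per_ch = np.atleast_1d(band_power(spec, *BANDS[band]))
            powers[f"{band}_{region_name}"] = float(np.mean(per_ch[idx]))
    att_f = (powers["beta_F"] / powers["theta_F"]
             if powers["theta_F"] > 0 else float("nan"))
    att_p = (powers["beta_P"] / powers["theta_P"]
             if powers["theta_P"] > 0 else float("nan"))
    return EEGFeatures(band_powers=powers, attention_frontal=att_f,
                       attention_parietal=att_p)
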