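"""Three-phase experimental timeline with labeled stimulus windows.

The default schedule has three randomized phases (image-only, sound-only,
combined). Each phase opens with a 5-minute rest, then four arousal
sessions at strictly increasing level alternate with 90 s neutral
sessions (A N A N A N A N). Each arousal session delivers six 15 s
stimuli, the first half low valence and the second half high valence.
Phases are separated by 2-minute rests, represented as gaps between
phase blocks. All intervals are half-open ``[t_start, t_end)`` in
seconds from experiment start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASES = ("IAPS", "IADS", "IAPS+IADS")
PHASE_MODALITY = {"IAPS": "image", "IADS": "sound", "IAPS+IADS": "image+sound"}
KINDS = ("rest", "neutral", "arousal")
VALENCE_CLASSES = ("low", "high", "neutral")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class StimulusEvent:
    modality: str
    valence_class: str
    arousal_level: int
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("stimulus duration must be positive")
        if (self.valence_class == "neutral") != (self.arousal_level == 0):
            raise ConfigurationError(
                "valence_class is neutral iff arousal_level is 0"
            )


@dataclass
class SessionWindow:
    phase: str
    kind: str
    arousal_level: int
    t_start: float
    t_end: float
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ConfigurationError("session must have positive duration")
        for ev in self.events:
            if ev.onset < self.t_start or ev.onset + ev.duration > self.t_end + 1e-9:
                raise ConfigurationError("event not contained in session window")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ProtocolSchedule:
    phases: list[list[SessionWindow]]
    phase_order: list[str]
    phase_order_seed: int

    @property
    def t_end(self) -> float:
        if not self.phases:
            return 0.0
        return self.phases[-1][-1].t_end

    def phase_block(self, phase: str) -> list[SessionWindow]:
        if phase not in self.phase_order:
            raise KeyError(f"unknown phase {phase!r}")
        return self.phases[self.phase_order.index(phase)]

    def all_windows(self) -> list[SessionWindow]:
        return [w for block in self.phases for w in block]


@dataclass
class ProtocolConfig:
    initial_rest_s: float = 300.0
    neutral_s: float = 90.0
    stimulus_s: float = 15.0
    interphase_rest_s: float = 120.0
    n_phases: int = 3
    n_arousal_sessions: int = 4
    n_stimuli: int = 6
    phase_order_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("initial_rest_s", "neutral_s", "stimulus_s", "interphase_rest_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("n_phases", "n_arousal_sessions", "n_stimuli"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_phases > len(PHASES):
            raise ConfigurationError(f"at most {len(PHASES)} phases supported")


def build_schedule(config: ProtocolConfig | None = None) -> ProtocolSchedule:
    """Build the protocol timeline from element durations and counts."""
    cfg = config or ProtocolConfig()
    rng = np.random.default_rng(cfg.phase_order_seed)
    order = [PHASES[i] for i in rng.permutation(len(PHASES))][: cfg.n_phases]

    blocks: list[list[SessionWindow]] = []
    t = 0.0
    arousal_span = cfg.n_stimuli * cfg.stimulus_s
    for phase in order:
        block: list[SessionWindow] = []
        block.append(
            SessionWindow(phase=phase, kind="rest", arousal_level=0,
                          t_start=t, t_end=t + cfg.initial_rest_s)
        )
        t += cfg.initial_rest_s
        for level in range(1, cfg.n_arousal_sessions + 1):
            events = _stimulus_train(phase, level, t, cfg.n_stimuli, cfg.stimulus_s)
            block.append(
                SessionWindow(phase=phase, kind="arousal", arousal_level=level,
                              t_start=t, t_end=t + arousal_span, events=events)
            )
            t += arousal_span
            n_neutral = int(cfg.neutral_s // cfg.stimulus_s)
            neutral_events = [
                StimulusEvent(modality=PHASE_MODALITY[phase], valence_class="neutral",
                              arousal_level=0, onset=t + i * cfg.stimulus_s,
                              duration=cfg.stimulus_s)
                for i in range(n_neutral)
            ]
            block.append(
                SessionWindow(phase=phase, kind="neutral", arousal_level=0,
                              t_start=t, t_end=t + cfg.neutral_s, events=neutral_events)
            )
            t += cfg.neutral_s
        blocks.append(block)
        t += cfg.interphase_rest_s  # gap before the next phase block
    return ProtocolSchedule(phases=blocks, phase_order=order,
                            phase_order_seed=cfg.phase_order_seed)


def _stimulus_train(phase: str, level: int, t0: float, n: int, dur: float
                    ) -> list[StimulusEvent]:
    events = []
    for i in range(n):
        valence = "low" if i < n // 2 else "high"
        events.append(
            StimulusEvent(modality=PHASE_MODALITY[phase], valence_class=valence,
                          arousal_level=level, onset=t0 + i * dur, duration=dur)
        )
    return events


def select_windows(
    schedule: ProtocolSchedule,
    phase: str,
    kind: str,
    arousal_level: int | None = None,
    valence_class: str = "any",
) -> list[tuple[float, float]]:
    """Time intervals for feature extraction.

    For arousal sessions, ``valence_class='low'`` returns the span of the
    first-half stimuli and ``'high'`` the second-half span; ``'any'``
    returns the whole session.
    """
    if kind not in KINDS:
        raise KeyError(f"unknown kind {kind!r}")
    block = schedule.phase_block(phase)
    matches = [w for w in block if w.kind == kind
               and (arousal_level is None or w.arousal_level == arousal_level)]
    if not matches:
        raise KeyError(
            f"no session with kind={kind!r}, arousal_level={arousal_level} in {phase!r}"
        )
    out: list[tuple[float, float]] = []
    for w in matches:
        if valence_class == "any":
            out.append((w.t_start, w.t_end))
            continue
        if valence_class not in ("low", "high"):
            raise KeyError(f"unknown valence_class {valence_class!r}")
        evs = [e for e in w.events if e.valence_class == valence_class]
        if not evs:
            raise KeyError(f"no {valence_class}-valence events in session")
        out.append((evs[0].onset, evs[-1].onset + evs[-1].duration))
    return out


def to_markers(schedule: ProtocolSchedule) -> pd.DataFrame:
    """Flatten the schedule to a tidy marker table (one row per window/event)."""
    rows = []
    for w in schedule.all_windows():
        rows.append(dict(onset_s=w.t_start, duration_s=w.duration, phase=w.phase,
                         kind=w.kind, arousal_level=w.arousal_level,
                         valence_class="", modality=""))
        for ev in w.events:
            rows.append(dict(onset_s=ev.onset, duration_s=ev.duration, phase=w.phase,
                             kind="stimulus", arousal_level=ev.arousal_level,
                             valence_class=ev.valence_class, modality=ev.modality))
    return pd.DataFrame(rows)


def write_markers(schedule: ProtocolSchedule, path) -> None:
    to_markers(schedule).to_csv(path, sep="\t", index=False)


def read_markers(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
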