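"""Core containers for pulse-timing data.

A pulse-type weakly electric fish emits stereotyped ~1 ms electric organ
discharges (EODs); everything downstream works on the *times* of those
events.  :class:`PulseTrain` is the single container used for fish EODs,
delivered stimulus pulses and detector output alike.  One closed-loop
experiment (a spontaneous control session plus a stimulation session at a
fixed delay) is a :class:`SessionPair`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PulseTrain", "SessionPair", "compute_ipis"]

#: allowed provenance tags for a train
SOURCES = ("fish", "stimulus", "detected")


@dataclass(frozen=True)
class PulseTrain:
    """A strictly increasing sequence of event times from one source.

    Parameters
    ----------
    times_ms
        Event times in milliseconds from session start; strictly increasing,
        all within ``[0, duration_ms]``.
    duration_ms
        Length of the recording session in ms.
    source
        One of ``"fish"``, ``"stimulus"`` or ``"detected"``.
    """

    times_ms: np.ndarray
    duration_ms: float
    source: str = "fish"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        object.__setattr__(self, "times_ms", t)
        if t.ndim != 1:
            raise ValueError("times_ms must be one-dimensional")
        if not np.all(np.isfinite(t)):
            raise ValueError("times_ms must be finite")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("times_ms must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration_ms):
            raise ValueError("times_ms must lie in [0, duration_ms]")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")

    def __len__(self) -> int:
        return int(self.times_ms.size)

    @property
    def n(self) -> int:
        return len(self)

    def ipis_ms(self) -> np.ndarray:
        """First differences of the event times (see :func:`compute_ipis`)."""
        return compute_ipis(self)

    def with_source(self, source: str) -> "PulseTrain":
        return replace(self, source=source)


def compute_ipis(train: PulseTrain | np.ndarray) -> np.ndarray:
    """Inter-pulse intervals (IPIs): first differences of a pulse train.

    Raises
    ------
    ValueError
        If the train holds fewer than two events (an unusable session).
    """
    t = train.times_ms if isinstance(train, PulseTrain) else np.asarray(train, float)
    if t.size < 2:
        raise ValueError("need at least 2 events to form an IPI")
    return np.diff(t)


@dataclass(frozen=True)
class SessionPair:
    """One closed-loop experiment: control + stimulation session + stimulus log.

    ``stim_fish`` holds the fish's own pulses during the stimulation session
    (stimulus pulses excluded); ``stimulus_log`` is the exact delivery times
    of the stimulus pulses.  ``excluded`` flags an experiment that an analyst
    removed on non-statistical grounds (it is reported, never silently
    dropped).
    """

    fish_id: str
    delay_ms: float
    control: PulseTrain
    stim_fish: PulseTrain
    stimulus_log: PulseTrain
    excluded: bool = False
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.control.source != "fish" or self.stim_fish.source != "fish":
            raise ValueError("control and stim_fish must have source='fish'")
        if self.stimulus_log.source != "stimulus":
            raise ValueError("stimulus_log must have source='stimulus'")
        if self.delay_ms < 0:
            raise ValueError("delay_ms must be nonnegative")
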