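"""Data model for traces, stimulus events and session protocols.

A session is one bee in the chamber: an 8-stimulus differential training
phase (4 CS+ paired with shock, 4 CS-) followed, after a recall gap, by a
4-stimulus unreinforced test phase.  The trace is the 5 Hz position record;
events carry odor identity, CS role, injection side and the shock schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .chamber import ChamberConfig, DEFAULT_CHAMBER

__all__ = [
    "Trace",
    "ShockSchedule",
    "StimulusEvent",
    "SessionProtocol",
    "SessionRecord",
    "TRAINING_ORDERS",
    "TEST_ORDERS",
    "ODORS",
]

ODORS = ("linalool", "nonanol")
TRAINING_ORDERS = ("ABBABAAB", "BAABABBA")
TEST_ORDERS = ("ABBA", "BAAB")

_T_TOL = 1e-3  # s; tolerance on the 5 Hz sample grid


@dataclass
class Trace:
    """Sampled 1-D positions of one bee, on the sensor grid.

    ``t`` is seconds from session start, strictly increasing at the chamber
    sampling interval; ``x`` is the chamber coordinate in cm.
    """

    bee_id: str
    t: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.shape != self.x.shape or self.t.ndim != 1:
            raise ValueError("t and x must be 1-D arrays of equal length")

    def validate(self, chamber: ChamberConfig = DEFAULT_CHAMBER) -> None:
        if self.t.size == 0:
            raise ValueError(f"trace for bee {self.bee_id!r} is empty")
        if self.t[0] < -_T_TOL:
            raise ValueError("trace starts before session start")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(f"non-monotone timestamps at sample {i + 1}")
        if np.any(np.abs(dt - chamber.sample_dt) > _T_TOL):
            i = int(np.argmax(np.abs(dt - chamber.sample_dt) > _T_TOL))
            raise ValueError(
                f"sample interval at index {i + 1} deviates from "
                f"1/{chamber.sampling_rate} s by more than {_T_TOL} s"
            )
        if not chamber.contains(self.x):
            bad = int(np.argmax((self.x < chamber.position_min) | (self.x > chamber.position_max)))
            raise ValueError(
                f"position {self.x[bad]:.4f} cm at sample {bad} outside "
                f"[{chamber.position_min}, {chamber.position_max}]"
            )

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def __len__(self) -> int:
        return int(self.t.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            self.bee_id == other.bee_id
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
        )


@dataclass(frozen=True)
class ShockSchedule:
    """Pulsed electric shock attached to a training CS+.

    The shock starts ``onset_offset`` s after odor onset (2 s on the bee's
    first CS+, 1 s on later ones) and delivers short pulses for
    ``total_duration`` s.
    """

    onset_offset: float = 1.0  # s after odor onset
    total_duration: float = 3.0  # s
    pulse_rate: float = 1.2  # pulses/s
    pulse_width: float = 0.2  # s
    voltage: float = 10.0  # V, metadata only

    def __post_init__(self) -> None:
        if self.onset_offset < 0:
            raise ValueError("shock onset offset must be >= 0")
        if self.pulse_width >= 1.0 / self.pulse_rate:
            raise ValueError("pulse width must be shorter than the pulse period")

    def pulse_times(self, t_odor_onset: float) -> np.ndarray:
        """Absolute onset times of the individual pulses."""
        start = t_odor_onset + self.onset_offset
        n = int(np.floor(self.total_duration * self.pulse_rate + 1e-9))
        return start + np.arange(n) / self.pulse_rate


@dataclass(frozen=True)
class StimulusEvent:
    """One 4-s odor presentation."""

    index: int
    phase: str  # "training" | "test"
    t_stim: float  # s, odor onset
    duration: float  # s
    odor: str
    role: str  # "CS+" | "CS-"
    side_index: int  # -1 odor injected at the left (negative) end, +1 right
    shock: Optional[ShockSchedule] = None

    def __post_init__(self) -> None:
        if self.phase not in ("training", "test"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.role not in ("CS+", "CS-"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.side_index not in (-1, 1):
            raise ValueError(f"side index must be -1 or +1, got {self.side_index}")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.shock is not None and not (self.role == "CS+" and self.phase == "training"):
            raise ValueError("shock may only be attached to a training CS+")

    @property
    def t_end(self) -> float:
        return self.t_stim + self.duration


@dataclass(frozen=True)
class SessionProtocol:
    """Stimulus schedule of one session.

    ``training_order``/``test_order`` are strings over {A, B} where A is the
    CS+ odor; training uses one of the two pseudorandomized 8-stimulus
    orders, the test one of the two 4-stimulus orders.  ``iti`` is the
    interval between stimulus offset and the next onset; ``test_gap`` the
    recall delay between the last training offset and the first test onset.
    """

    training_order: str = "ABBABAAB"
    test_order: str = "ABBA"
    csplus_odor: str = "linalool"
    iti: float = 34.0  # s
    stimulus_duration: float = 4.0  # s
    test_gap: float = 300.0  # s
    t_first: float = 10.0  # s, first training onset (acclimation)
    side_assignments: tuple[int, ...] = ()  # SI per training stimulus

    def __post_init__(self) -> None:
        if self.training_order not in TRAINING_ORDERS:
            raise ValueError(f"training order must be one of {TRAINING_ORDERS}")
        if self.test_order not in TEST_ORDERS:
            raise ValueError(f"test order must be one of {TEST_ORDERS}")
        if self.csplus_odor not in ODORS:
            raise ValueError(f"unknown odor {self.csplus_odor!r}")
        if self.iti <= self.stimulus_duration:
            raise ValueError("ITI must exceed the stimulus duration")
        if self.side_assignments and len(self.side_assignments) != len(self.training_order):
            raise ValueError("need one side assignment per training stimulus")
        if any(s not in (-1, 1) for s in self.side_assignments):
            raise ValueError("side assignments must be -1 or +1")

    @property
    def csminus_odor(self) -> str:
        return ODORS[1] if self.csplus_odor == ODORS[0] else ODORS[0]

    def odor_of(self, letter: str) -> str:
        return self.csplus_odor if letter == "A" else self.csminus_odor

    def training_onsets(self) -> np.ndarray:
        step = self.stimulus_duration + self.iti
        return self.t_first + np.arange(len(self.training_order)) * step

    def test_onsets(self) -> np.ndarray:
        last_training_end = self.training_onsets()[-1] + self.stimulus_duration
        step = self.stimulus_duration + self.iti
        return last_training_end + self.test_gap + np.arange(len(self.test_order)) * step

    @property
    def session_end(self) -> float:
        return float(self.test_onsets()[-1] + self.stimulus_duration + self.iti / 2.0)


@dataclass
class SessionRecord:
    """One bee's complete session: chamber, protocol, trace and events."""

    chamber: ChamberConfig
    protocol: SessionProtocol
    trace: Trace
    events: list[StimulusEvent]
    provenance: str = "measured"

    def validate(self) -> None:
        self.trace.validate(self.chamber)
        for ev in self.events:
            if ev.t_stim < self.trace.t[0] - _T_TOL or ev.t_end > self.trace.t[-1] + _T_TOL:
                raise ValueError(
                    f"event {ev.index} window [{ev.t_stim}, {ev.t_end}] outside "
                    f"the trace span [{self.trace.t[0]}, {self.trace.t[-1]}]"
                )

    def test_events(self) -> list[StimulusEvent]:
        return [ev for ev in self.events if ev.phase == "test"]

    def training_events(self) -> list[StimulusEvent]:
        return [ev for ev in self.events if ev.phase == "training"]

    @property
    def bee_id(self) -> str:
        return self.trace.bee_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionRecord):
            return NotImplemented
        return (
            self.chamber == other.chamber
            and self.protocol == other.protocol
            and self.trace == other.trace
            and self.events == other.events
            and self.provenance == other.provenance
        )
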