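"""Behavioral repertoire of the simulated bee.

The simulator is a four-mode state machine (explore / attracted / escaping /
startled) walking a point bee along the chamber axis.  Its parameters are
calibrated so that a default test-phase cohort reproduces the recall-phase
statistics of the reference dataset: escape rates of 54.0% (first test CS+)
and 17.8% (first test CS-), population mean signed velocities of -1.5 and
-0.2 cm/s, an escape-subset CS+ velocity of -2.5 cm/s, and the associated
attractance-index means and rank correlations.

Signed velocities are odor-relative: negative means movement away from the
odor-injected end.  Escape and non-escape velocity parameters are the means
of the *measured* per-stimulus velocities (displacement over the first 2 s
of the window, halved), not hidden run speeds; the simulator converts them
to run speeds internally so that the scoring module's estimator recovers
them without bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["BehaviorParams", "BeeState", "SCENARIOS"]


@dataclass(frozen=True)
class BehaviorParams:
    """Tunable constants of the behavior model.

    Probabilities apply per test stimulus; velocities are cm/s in the
    odor-relative sign convention.  The non-escape drift means are moment
    matches: with escape probability p and escape velocity v_esc, the
    non-escape drift v_non solves p*v_esc + (1-p)*v_non = population mean
    (-1.5 cm/s for CS+, -0.2 cm/s for CS-).
    """

    # escape initiation probabilities (per test stimulus, both trials)
    p_escape_csplus: float = 0.540
    p_escape_csminus: float = 0.178
    # measured-velocity means of escape runs, cm/s
    v_escape_csplus: float = -2.5
    v_escape_csminus: float = -1.8
    # drift of non-escaping bees during the first 2 s of a stimulus, cm/s
    v_nonescape_csplus: float = -0.33
    v_nonescape_csminus: float = 0.15
    # between-stimulus SD of all drawn velocities, cm/s; calibrated so the
    # velocity-escape rank correlation of a default cohort lands at -0.73
    sd_velocity: float = 1.2
    # free-running walk speed between stimuli, cm/s
    explore_speed: float = 2.0
    # fraction of the post-approach dwell time a non-escaping CS- bee spends
    # in the odor-side third of the chamber
    attraction_dwell: float = 0.8
    # displacement of the startle jump at a shock pulse, cm
    startle_jump: float = 1.5
    # probability weight of walking leftward after a spontaneous turn
    left_bias: float = 0.5
    # escape-run latency bounds after odor onset, s
    latency_min: float = 0.2
    latency_max: float = 1.0
    # spontaneous turn rate during exploration, 1/s
    turn_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("p_escape_csplus", "p_escape_csminus", "left_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sd_velocity < 0:
            raise ValueError("sd_velocity must be >= 0")
        if self.explore_speed < 0:
            raise ValueError("explore_speed must be >= 0")
        if not 0.0 < self.attraction_dwell <= 1.0:
            raise ValueError("attraction_dwell must be in (0, 1]")
        if not 0.0 <= self.latency_min <= self.latency_max:
            raise ValueError("latency bounds must satisfy 0 <= min <= max")

    def p_escape(self, role: str) -> float:
        return self.p_escape_csplus if role == "CS+" else self.p_escape_csminus

    def v_escape(self, role: str) -> float:
        return self.v_escape_csplus if role == "CS+" else self.v_escape_csminus

    def v_nonescape(self, role: str) -> float:
        return self.v_nonescape_csplus if role == "CS+" else self.v_nonescape_csminus


@dataclass
class BeeState:
    """Instantaneous state of the simulated bee (internal bookkeeping)."""

    mode: str  # explore | attracted | escaping | startled
    x: float  # cm
    v: float  # cm/s
    mode_entry_time: float  # s


#: Named parameter presets selectable from the CLI.
SCENARIOS: dict[str, BehaviorParams] = {
    # the calibrated recall-phase conditions (defaults)
    "paper-recall": BehaviorParams(),
    # untrained control: CS+ and CS- behave identically at the CS- level
    "naive": BehaviorParams(
        p_escape_csplus=0.178,
        v_escape_csplus=-1.8,
        v_nonescape_csplus=0.15,
    ),
    # exchangeable groups for null calibration of the statistics layer
    "null": BehaviorParams(
        p_escape_csplus=0.3,
        p_escape_csminus=0.3,
        v_escape_csplus=-2.0,
        v_escape_csminus=-2.0,
        v_nonescape_csplus=0.0,
        v_nonescape_csminus=0.0,
    ),
}
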