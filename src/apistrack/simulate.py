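"""Agent-based session simulator.

Builds a continuous piecewise-linear path for one bee through a full
session (8-stimulus training, recall gap, 4-stimulus test), evaluates it on
a 50 Hz internal grid and exports only the 5 Hz sensor-quantized trace, so
the scoring module never sees the hidden path.

Test-phase behavior implements the delivery rule of the physical chamber:
the odor is injected on the side where the bee is located at onset, giving
it the opportunity to withdraw.  Escape runs are constructed so that the
scoring module's velocity estimator recovers the drawn velocity without
bias: the bee drifts so that its displacement two seconds after onset is
exactly twice the drawn (odor-relative) velocity, then commits to a dash
that carries it across the midline to a rest position on the far side well
before the window closes.  Velocity draws are taken from a symmetrically
truncated normal so wall constraints do not bias the configured means.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .behavior import BeeState, BehaviorParams
from .chamber import ChamberConfig, DEFAULT_CHAMBER
from .records import (
    ODORS,
    SessionProtocol,
    SessionRecord,
    ShockSchedule,
    StimulusEvent,
    TEST_ORDERS,
    TRAINING_ORDERS,
    Trace,
)

__all__ = ["build_protocol", "simulate_session", "simulate_cohort", "sensor_sample"]

_INTERNAL_HZ = 50.0
_SIDE_MARGIN = 0.3  # cm; how far onto a side a controlled move must reach
_CROSS_MARGIN = 0.25  # cm; required overshoot past the midline for escapes
_REST_DEPTH_MIN = 2.5  # cm; escape runs settle between these depths beyond the midline
_REST_DEPTH_MAX = 7.4  # cm
_DRIFT_GAIN = 4.0  # s; maps the drawn drift velocity to the dwell set-point
_SETTLE_TIME = 1.2  # s; time scale for an escape run to reach its rest depth


def build_protocol(
    seed: int,
    csplus_odor: str = "linalool",
    balance: bool = True,
    *,
    iti: float = 34.0,
    test_gap: float = 300.0,
    t_first: float = 10.0,
    stimulus_duration: float = 4.0,
    training_order: Optional[str] = None,
    test_order: Optional[str] = None,
) -> SessionProtocol:
    """Draw a session protocol for one bee.

    With ``balance`` the training order (ABBABAAB vs BAABABBA), test order
    (ABBA vs BAAB) and the left/right injection sides of the 8 training
    stimuli (4 left, 4 right, shuffled) are chosen from the seed, emulating
    the balanced pseudorandomized presentation of the assay.
    """
    if csplus_odor not in ODORS:
        raise ValueError(f"unknown odor {csplus_odor!r}; expected one of {ODORS}")
    rng = np.random.default_rng(seed)
    if training_order is None:
        training_order = TRAINING_ORDERS[rng.integers(2)] if balance else TRAINING_ORDERS[0]
    if test_order is None:
        test_order = TEST_ORDERS[rng.integers(2)] if balance else TEST_ORDERS[0]
    sides = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
    if balance:
        sides = rng.permutation(sides)
    return SessionProtocol(
        training_order=training_order,
        test_order=test_order,
        csplus_odor=csplus_odor,
        iti=iti,
        stimulus_duration=stimulus_duration,
        test_gap=test_gap,
        t_first=t_first,
        side_assignments=tuple(int(s) for s in sides),
    )


def sensor_sample(continuous_path, chamber: ChamberConfig, bee_id: str = "bee") -> Trace:
    """Pass a continuous path through the 5 Hz photo-sensor array.

    ``continuous_path`` is a ``(t, x)`` pair of arrays covering the session
    span.  Samples are taken at t = k / sampling_rate and quantized to the
    nearest sensor-field center (then rounded to the 4-decimal log
    precision), so the quantization error is bounded by half the sensor
    pitch.
    """
    t, x = (np.asarray(a, dtype=float) for a in continuous_path)
    if t.size < 2:
        raise ValueError("continuous path needs at least two points")
    dt = 1.0 / chamber.sampling_rate
    n = int(math.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    ts = t[0] + np.arange(n) * dt
    xs = np.interp(ts, t, x)
    xs = np.clip(xs, chamber.position_min, chamber.position_max)
    # round to the log precision so traces are canonical: writing and
    # re-reading a simulated session reproduces it exactly
    return Trace(bee_id=bee_id, t=np.round(ts, 3), x=np.round(chamber.quantize(xs), 4))


class _Path:
    """Breakpoint accumulator for a piecewise-linear path."""

    def __init__(self, t0: float, x0: float):
        self.ts = [t0]
        self.xs = [x0]

    @property
    def t(self) -> float:
        return self.ts[-1]

    @property
    def x(self) -> float:
        return self.xs[-1]

    def to(self, t: float, x: float) -> None:
        if t < self.ts[-1] - 1e-12:
            raise ValueError("path breakpoints must be non-decreasing in time")
        if t > self.ts[-1] + 1e-12:
            self.ts.append(t)
            self.xs.append(x)
        else:
            self.xs[-1] = x

    def hold(self, t: float) -> None:
        self.to(t, self.x)


def _reflect_walk(
    path: _Path,
    until: float,
    lo: float,
    hi: float,
    speed: float,
    direction: int,
    rng: Optional[np.random.Generator] = None,
    turn_rate: float = 0.0,
    left_bias: float = 0.5,
) -> int:
    """Walk at constant speed with reflecting bounds, optional random turns.

    Appends breakpoints up to ``until`` and returns the final direction.
    """
    if until <= path.t + 1e-12:
        return direction
    if speed <= 0.0:
        path.hold(until)
        return direction
    t, x = path.t, path.x
    # nudge a bee resting on a bound back inward
    if x >= hi - 1e-9 and direction > 0:
        direction = -1
    elif x <= lo + 1e-9 and direction < 0:
        direction = 1
    while t < until - 1e-12:
        t_turn = math.inf
        if rng is not None and turn_rate > 0.0:
            t_turn = t + rng.exponential(1.0 / turn_rate)
        bound = hi if direction > 0 else lo
        t_bound = t + (bound - x) / (direction * speed)
        t_next = min(t_turn, t_bound, until)
        x_next = x + direction * speed * (t_next - t)
        path.to(t_next, x_next)
        if t_next == t_bound and t_next < until:
            direction = -direction
        elif t_next == t_turn and t_next < until:
            direction = -1 if rng.random() < left_bias else 1
        t, x = t_next, x_next
    return direction


def _draw_truncated(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    """Symmetrically truncated normal draw.

    The feasible interval [lo, hi] is shrunk to [mean - c, mean + c] with
    c = min(mean - lo, hi - mean) before truncation, so the draw stays
    unbiased for the configured mean; only when the mean itself is
    infeasible does the draw clamp to the nearest feasible bound.
    """
    c = min(mean - lo, hi - mean)
    if c <= 0.0 or sd <= 0.0:
        return min(max(mean, lo), hi)
    a = _norm_cdf(-c / sd)
    u = rng.uniform(a, 1.0 - a)
    return mean + sd * _norm_ppf(u)


def _norm_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def _norm_ppf(q: float) -> float:
    from scipy.special import ndtri

    return float(ndtri(q))


def _test_stimulus(
    path: _Path,
    rng: np.random.Generator,
    params: BehaviorParams,
    chamber: ChamberConfig,
    t0: float,
    role: str,
    direction: int,
    modes: list[BeeState],
) -> tuple[int, int]:
    """Simulate one 4-s test window; returns (side_index, new direction)."""
    wall = chamber.position_max
    x_on = path.x
    if x_on > 0:
        si = 1
    elif x_on < 0:
        si = -1
    else:  # exactly on the midline: the side it came from
        si = -direction if direction != 0 else 1
    a0 = x_on * si  # odor-relative start, >= 0

    if rng.random() < params.p_escape(role):
        # escaping mode: latency, drift covering exactly 2w cm by t0 + 2 s,
        # then a dash that guarantees the midline crossing within the window
        lat = rng.uniform(params.latency_min, params.latency_max)
        w = _draw_truncated(
            rng, params.v_escape(role), params.sd_velocity,
            -(a0 + wall - 1e-3) / 2.0, (wall - 1e-3 - a0) / 2.0,
        )
        a2 = a0 + 2.0 * w
        u_a = 2.0 * abs(w) / (2.0 - lat)  # cm/s during the velocity window
        modes.append(BeeState("escaping", x_on, w * si, t0))
        path.hold(t0 + lat)
        path.to(t0 + 2.0, a2 * si)
        t, a = t0 + 2.0, a2
        # run to a rest position on the far side, arriving by t0 + 3.8 s at
        # the latest; faster drifts settle sooner
        rest = -min(wall, rng.uniform(_REST_DEPTH_MIN, _REST_DEPTH_MAX))
        if a > rest:
            u_c = max(u_a, (a - rest) / _SETTLE_TIME, 1.0)
            t_rest = t + (a - rest) / u_c
            if t_rest < t0 + 4.0:
                path.to(t_rest, rest * si)
                path.hold(t0 + 4.0)
            else:
                path.to(t0 + 4.0, (a - u_c * (t0 + 4.0 - t)) * si)
        else:
            path.hold(t0 + 4.0)
        new_dir = si if abs(path.x + wall * si) < 1e-6 else -si
        return si, new_dir

    # non-escape: drift for the velocity window, then a confined walk
    w = _draw_truncated(
        rng,
        params.v_nonescape(role),
        params.sd_velocity,
        (-(wall - _SIDE_MARGIN) - a0) / 2.0,
        (wall - 1e-3 - a0) / 2.0,
    )
    modes.append(BeeState("attracted" if role == "CS-" else "explore", x_on, w * si, t0))
    a2 = a0 + 2.0 * w
    path.to(t0 + 2.0, a2 * si)

    if role == "CS-":
        # attracted: bounce within a band near the odor wall whose width is
        # set by the attraction_dwell target (fraction of dwell time spent
        # in the odor-side third of the chamber)
        third_edge = wall - chamber.length / 3.0
        b = wall - (wall - third_edge) / params.attraction_dwell
        region_lo = max(_SIDE_MARGIN, b)
    else:
        region_lo = 0.8
    # settle toward a set-point that carries the drift forward: bees that
    # approached the odor keep close to it, bees that backed off settle low
    center = 0.5 * (region_lo + wall)
    target = min(max(center + _DRIFT_GAIN * w, region_lo), wall)
    v_move = max(0.5 * params.explore_speed, abs(target - a2) / 1.5, 0.5)
    t_arr = t0 + 2.0 + abs(target - a2) / v_move
    if t_arr < t0 + 4.0:
        path.to(t_arr, target * si)
        path.hold(t0 + 4.0)
    else:
        a_end = a2 + math.copysign(v_move * 2.0, target - a2)
        path.to(t0 + 4.0, a_end * si)
    last_dir = 1 if target >= a2 else -1
    return si, last_dir * si


def _training_csplus(
    path: _Path,
    rng: np.random.Generator,
    params: BehaviorParams,
    chamber: ChamberConfig,
    event: StimulusEvent,
    direction: int,
    until_cap: float,
    modes: list[BeeState],
) -> int:
    """Startle jump at shock onset, then agitated walking until it wears off."""
    wall = chamber.position_max
    shock = event.shock if event.shock is not None else ShockSchedule()
    t_shock = event.t_stim + shock.onset_offset
    direction = _reflect_walk(
        path, min(t_shock, until_cap), -wall, wall, params.explore_speed, direction,
        rng, params.turn_rate, params.left_bias,
    )
    if t_shock >= until_cap:
        return direction
    away = -event.side_index
    x_jump = min(max(path.x + away * params.startle_jump, -wall), wall)
    modes.append(BeeState("startled", path.x, 0.0, t_shock))
    path.to(min(t_shock + 0.1, until_cap), x_jump)
    t_end = min(t_shock + shock.total_duration + 5.0, until_cap)
    direction = away
    direction = _reflect_walk(
        path, t_end, -wall, wall, 2.0 * params.explore_speed, direction,
        rng, params.turn_rate, params.left_bias,
    )
    modes.append(BeeState("explore", path.x, 0.0, t_end))
    return direction


def simulate_session(
    protocol: SessionProtocol,
    params: Optional[BehaviorParams] = None,
    chamber: Optional[ChamberConfig] = None,
    seed: int = 0,
    bee_id: str = "bee0000",
) -> SessionRecord:
    """Simulate one bee through a full session.

    The result is fully determined by ``(protocol, params, chamber, seed)``.
    """
    params = params if params is not None else BehaviorParams()
    chamber = chamber if chamber is not None else DEFAULT_CHAMBER
    rng = np.random.default_rng(seed)
    wall = chamber.position_max

    sides = protocol.side_assignments
    if not sides:
        sides = tuple(
            int(s) for s in rng.permutation([-1] * 4 + [1] * 4)[: len(protocol.training_order)]
        )

    training: list[StimulusEvent] = []
    first_csplus = True
    for k, letter in enumerate(protocol.training_order):
        role = "CS+" if letter == "A" else "CS-"
        shock = None
        if role == "CS+":
            shock = ShockSchedule(onset_offset=2.0 if first_csplus else 1.0)
            first_csplus = False
        training.append(
            StimulusEvent(
                index=k,
                phase="training",
                t_stim=float(protocol.training_onsets()[k]),
                duration=protocol.stimulus_duration,
                odor=protocol.odor_of(letter),
                role=role,
                side_index=sides[k],
                shock=shock,
            )
        )

    x0 = float(rng.uniform(-wall + 0.1, wall - 0.1))
    direction = -1 if rng.random() < params.left_bias else 1
    path = _Path(0.0, x0)
    modes = [BeeState("explore", x0, direction * params.explore_speed, 0.0)]

    test_onsets = protocol.test_onsets()
    upcoming = [(ev.t_stim, "training", ev) for ev in training]
    upcoming += [
        (float(test_onsets[j]), "test", j) for j in range(len(protocol.test_order))
    ]
    upcoming.sort(key=lambda item: item[0])

    test_events: list[StimulusEvent] = []
    for pos, (t_on, kind, payload) in enumerate(upcoming):
        next_on = upcoming[pos + 1][0] if pos + 1 < len(upcoming) else protocol.session_end
        direction = _reflect_walk(
            path, t_on, -wall, wall, params.explore_speed, direction,
            rng, params.turn_rate, params.left_bias,
        )
        if kind == "training":
            ev = payload
            if ev.role == "CS+":
                direction = _training_csplus(
                    path, rng, params, chamber, ev, direction, next_on, modes
                )
            # a training CS- does not interrupt exploration
        else:
            j = payload
            letter = protocol.test_order[j]
            role = "CS+" if letter == "A" else "CS-"
            si, direction = _test_stimulus(
                path, rng, params, chamber, t_on, role, direction, modes
            )
            test_events.append(
                StimulusEvent(
                    index=len(protocol.training_order) + j,
                    phase="test",
                    t_stim=t_on,
                    duration=protocol.stimulus_duration,
                    odor=protocol.odor_of(letter),
                    role=role,
                    side_index=si,
                )
            )
        modes.append(BeeState("explore", path.x, direction * params.explore_speed, path.t))
    _reflect_walk(
        path, protocol.session_end, -wall, wall, params.explore_speed, direction,
        rng, params.turn_rate, params.left_bias,
    )

    # evaluate the hidden path on the internal 50 Hz grid, then sensor-sample
    n50 = int(math.floor(protocol.session_end * _INTERNAL_HZ + 1e-9)) + 1
    t50 = np.arange(n50) / _INTERNAL_HZ
    x50 = np.clip(np.interp(t50, path.ts, path.xs), -wall, wall)
    trace = sensor_sample((t50, x50), chamber, bee_id=bee_id)

    record = SessionRecord(
        chamber=chamber,
        protocol=protocol,
        trace=trace,
        events=training + test_events,
        provenance=f"seed={seed};generator=apistrack-{__version__}",
    )
    record.validate()
    return record


def simulate_cohort(
    n: int,
    seed: int = 0,
    params: Optional[BehaviorParams] = None,
    chamber: Optional[ChamberConfig] = None,
    csplus_odors: Optional[Sequence[str]] = None,
    protocol_kwargs: Optional[dict] = None,
) -> list[SessionRecord]:
    """Simulate ``n`` independent sessions with balanced odor assignment.

    Per-bee seeds are derived from ``seed`` through a seed sequence, so the
    cohort is reproducible bit-for-bit and bees are mutually independent.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ss = np.random.SeedSequence(seed)
    bee_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]
    kw = protocol_kwargs or {}
    records = []
    for i in range(n):
        odor = csplus_odors[i] if csplus_odors is not None else ODORS[i % 2]
        protocol = build_protocol(bee_seeds[i], csplus_odor=odor, **kw)
        records.append(
            simulate_session(
                protocol,
                params=params,
                chamber=chamber,
                seed=bee_seeds[i],
                bee_id=f"bee{i:04d}",
            )
        )
    return records
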