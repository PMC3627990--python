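"""Per-stimulus quantification of 1-D traces.

Four readouts per 4-s odor stimulus:

escape call
    the bee is on the odor side at onset and crosses the chamber midline
    without returning for the remainder of the stimulation window;

signed velocity
    mean rate of position change over the first 2 s of the window, in cm/s,
    negative away from the odor injection.  Operationally the mean of the
    derivative of a cubic spline through the dwell-midpoint knots of the
    trace, which collapses to the endpoint form
    ``SI * (s(t_stim + 2) - s(t_stim)) / 2``;

raw attractance integral
    ``SI * integral of P(t) dt`` over the 4-s window (trapezoid rule), in
    cm*s, positive for presence on the odor side;

Attractance Index (AI)
    the raw integral normalized over the minimum and maximum observed
    integral of the whole scored population, dimensionless in [-1, 1].

All side-dependent quantities are multiplied by the side index SI of the
stimulus, so they are mirror-invariant: reflecting every position and every
injection side leaves all scores unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .chamber import ChamberConfig, DEFAULT_CHAMBER
from .records import SessionRecord, StimulusEvent, Trace

__all__ = [
    "EscapeCall",
    "StimulusScore",
    "CohortTable",
    "detect_escape",
    "estimate_velocity",
    "dwell_spline",
    "raw_attractance_integral",
    "normalize_ai",
    "classify_response",
    "score_cohort",
]

logger = logging.getLogger(__name__)

_TOL = 1e-6


@dataclass(frozen=True)
class EscapeCall:
    escaped: bool
    crossing_time: Optional[float] = None  # s after odor onset
    start_side_ok: bool = True

    def __post_init__(self) -> None:
        if self.escaped != (self.crossing_time is not None):
            raise ValueError("crossing_time must be present iff escaped")


@dataclass
class StimulusScore:
    """All per-stimulus readouts for one bee and one odor presentation."""

    bee_id: str
    stim_index: int
    phase: str
    odor: str
    role: str
    side_index: int
    escape: EscapeCall
    velocity: float  # cm/s, odor-relative sign
    raw_integral: float  # cm*s, odor-relative sign
    ai: Optional[float] = None  # filled by normalize_ai


@dataclass
class CohortTable:
    """Scores of a population plus the AI normalization constants."""

    scores: list[StimulusScore] = field(default_factory=list)
    min_raw: Optional[float] = None
    max_raw: Optional[float] = None
    ai_norm: Optional[str] = None
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "bee_id": s.bee_id,
                "stim_index": s.stim_index,
                "phase": s.phase,
                "odor": s.odor,
                "role": s.role,
                "side_index": s.side_index,
                "escaped": s.escape.escaped,
                "crossing_time_s": np.nan if s.escape.crossing_time is None else s.escape.crossing_time,
                "velocity_cm_s": s.velocity,
                "raw_integral_cm_s": s.raw_integral,
                "ai": np.nan if s.ai is None else s.ai,
            }
            for s in self.scores
        ]
        cols = [
            "bee_id", "stim_index", "phase", "odor", "role", "side_index",
            "escaped", "crossing_time_s", "velocity_cm_s", "raw_integral_cm_s", "ai",
        ]
        return pd.DataFrame(rows, columns=cols)


def _window_slice(trace: Trace, t0: float, t1: float) -> tuple[int, int]:
    """Indices [i0, i1) of samples with t0 <= t <= t1 (within tolerance)."""
    i0 = int(np.searchsorted(trace.t, t0 - _TOL, side="left"))
    i1 = int(np.searchsorted(trace.t, t1 + _TOL, side="right"))
    return i0, i1


def _check_window(trace: Trace, t0: float, t1: float) -> None:
    if t0 < trace.t[0] - _TOL or t1 > trace.t[-1] + _TOL:
        raise ValueError(
            f"stimulus window [{t0}, {t1}] extends past the trace span "
            f"[{trace.t[0]}, {trace.t[-1]}]"
        )


def _sides(x: np.ndarray, lead: float) -> np.ndarray:
    """Side of each sample: sign(x), with zeros inheriting the previous side.

    ``lead`` is the position of the sample preceding the window (or the
    first window sample itself at the start of a trace).
    """
    s = np.sign(x).astype(int)
    prev = int(np.sign(lead))
    for i in range(s.size):
        if s[i] == 0:
            s[i] = prev
        else:
            prev = s[i]
    return s


def detect_escape(
    trace: Trace, event: StimulusEvent, chamber: ChamberConfig = DEFAULT_CHAMBER
) -> EscapeCall:
    """Call an escape for one stimulus window.

    Escape requires (a) the bee on the odor side (sample side equals the
    stimulus side index) at the first sample at or after onset and (b) some
    sample from which every remaining in-window sample lies on the opposite
    side.  The crossing time is the first sample time of that terminal
    run, relative to onset.  A bee on the wrong side at onset is flagged
    (``start_side_ok=False``) and never scored as escaped.
    """
    t0, t1 = event.t_stim, event.t_stim + event.duration
    _check_window(trace, t0, t1)
    i0, i1 = _window_slice(trace, t0, t1)
    if i1 - i0 < 2:
        raise ValueError("stimulus window covers fewer than two samples")
    x = trace.x[i0:i1]
    lead = trace.x[i0 - 1] if i0 > 0 else x[0]
    sides = _sides(x, lead)
    si = event.side_index
    if sides[0] != si:
        return EscapeCall(escaped=False, start_side_ok=False)
    away = sides == -si
    if not away[-1]:
        return EscapeCall(escaped=False)
    # first index of the terminal all-away run
    not_away = np.nonzero(~away)[0]
    start = int(not_away[-1]) + 1 if not_away.size else 0
    if start == 0:
        # whole window away contradicts the start-side check above
        return EscapeCall(escaped=False)
    return EscapeCall(escaped=True, crossing_time=float(trace.t[i0 + start] - t0))


def _boundary_position(trace: Trace, t: float) -> float:
    """Trace position at an arbitrary time by linear interpolation.

    Between samples the flanking samples are interpolated; at or beyond the
    trace ends the nearest sample is extended.
    """
    return float(np.interp(t, trace.t, trace.x))


def _dwell_knots(trace: Trace, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    """Knots for the spline fit: one per dwell, at the dwell's time midpoint.

    Runs of consecutive equal positions (the bee resting on one sensor)
    collapse to a single (midpoint time, position) pair; the window
    boundary positions are added as anchoring knots.
    """
    i0, i1 = _window_slice(trace, t0, t1)
    kt: list[float] = [t0]
    kx: list[float] = [_boundary_position(trace, t0)]
    j = i0
    while j < i1:
        k = j
        while k + 1 < i1 and trace.x[k + 1] == trace.x[j]:
            k += 1
        tm = 0.5 * (trace.t[j] + trace.t[k])
        if tm > kt[-1] + _TOL and tm < t1 - _TOL:
            kt.append(float(tm))
            kx.append(float(trace.x[j]))
        j = k + 1
    kt.append(t1)
    kx.append(_boundary_position(trace, t1))
    return np.array(kt), np.array(kx)


def dwell_spline(
    trace: Trace,
    event: StimulusEvent,
    chamber: ChamberConfig = DEFAULT_CHAMBER,
    window: float = 2.0,
) -> CubicSpline:
    """Natural cubic spline through the dwell-midpoint knots of a window."""
    t0, t1 = event.t_stim, event.t_stim + window
    _check_window(trace, t0, t1)
    kt, kx = _dwell_knots(trace, t0, t1)
    return CubicSpline(kt, kx, bc_type="natural")


def estimate_velocity(
    trace: Trace,
    event: StimulusEvent,
    chamber: ChamberConfig = DEFAULT_CHAMBER,
    window: float = 2.0,
) -> float:
    """Signed velocity over the first 2 s of a stimulus, cm/s.

    The mean of the spline derivative over the window equals the endpoint
    difference of the spline divided by the window length, and the spline
    interpolates the window boundary positions, so the estimate reduces to
    ``SI * (x(t0+window) - x(t0)) / window`` with the boundary positions
    obtained by linear interpolation between the flanking samples.  A
    stationary bee (fewer than two distinct positions) scores 0.
    """
    t0, t1 = event.t_stim, event.t_stim + window
    _check_window(trace, t0, t1)
    i0, i1 = _window_slice(trace, t0, t1)
    if np.unique(trace.x[max(i0 - 1, 0): i1]).size < 2:
        return 0.0
    x_start = _boundary_position(trace, t0)
    x_end = _boundary_position(trace, t1)
    return float(event.side_index * (x_end - x_start) / window)


def raw_attractance_integral(
    trace: Trace, event: StimulusEvent, chamber: ChamberConfig = DEFAULT_CHAMBER
) -> float:
    """Side-signed trapezoid integral of position over the 4-s window, cm*s.

    Boundary positions at exactly ``t_stim`` and ``t_stim + duration`` are
    obtained by linear interpolation between the flanking samples, so the
    trapezoid sum is exact for piecewise-linear traces with breakpoints on
    sample times.
    """
    t0, t1 = event.t_stim, event.t_stim + event.duration
    _check_window(trace, t0, t1)
    i0, i1 = _window_slice(trace, t0, t1)
    ts = np.concatenate(([t0], trace.t[i0:i1], [t1]))
    xs = np.concatenate(
        ([_boundary_position(trace, t0)], trace.x[i0:i1], [_boundary_position(trace, t1)])
    )
    keep = np.concatenate(([True], np.diff(ts) > _TOL))
    return float(event.side_index * np.trapezoid(xs[keep], ts[keep]))


def normalize_ai(
    cohort: CohortTable, method: Literal["minmax", "symmetric"] = "minmax"
) -> CohortTable:
    """Fill the AI column by population normalization of the raw integrals.

    ``minmax`` (default) maps the population minimum to -1 and maximum to
    +1 linearly; ``symmetric`` divides by max(|min|, |max|), preserving the
    zero point.  A degenerate cohort (all integrals equal) scores 0
    everywhere.
    """
    if not cohort.scores:
        raise ValueError("cannot normalize an empty cohort")
    raw = np.array([s.raw_integral for s in cohort.scores])
    lo, hi = float(raw.min()), float(raw.max())
    cohort.min_raw, cohort.max_raw, cohort.ai_norm = lo, hi, method
    if hi - lo < _TOL:
        for s in cohort.scores:
            s.ai = 0.0
        return cohort
    if method == "minmax":
        for s in cohort.scores:
            s.ai = float(2.0 * (s.raw_integral - lo) / (hi - lo) - 1.0)
    elif method == "symmetric":
        scale = max(abs(lo), abs(hi))
        for s in cohort.scores:
            s.ai = float(s.raw_integral / scale)
    else:
        raise ValueError(f"unknown AI normalization {method!r}")
    return cohort


def classify_response(ai: float) -> str:
    """Threshold classification of a normalized AI.

    AI >= 0.3 is typical for attraction, AI <= 0.1 for avoidance; the band
    in between is indeterminate.
    """
    if not -1.0 - _TOL <= ai <= 1.0 + _TOL:
        raise ValueError(f"AI must lie in [-1, 1], got {ai}")
    if ai >= 0.3:
        return "attraction"
    if ai <= 0.1:
        return "avoidance"
    return "indeterminate"


def score_cohort(
    records: Iterable[SessionRecord],
    ai_norm: Literal["minmax", "symmetric"] = "minmax",
    n_test_expected: int = 4,
) -> CohortTable:
    """Score every test stimulus of every session and normalize AI jointly.

    Records without the expected number of test events are skipped with a
    warning and counted in ``n_skipped``.  Scores are ordered by
    (bee id, stimulus index); normalization pools all scored stimuli.
    """
    table = CohortTable()
    for rec in sorted(records, key=lambda r: r.bee_id):
        tests = rec.test_events()
        if len(tests) != n_test_expected:
            logger.warning(
                "skipping bee %s: expected %d test events, found %d",
                rec.bee_id, n_test_expected, len(tests),
            )
            table.n_skipped += 1
            continue
        for ev in sorted(tests, key=lambda e: e.index):
            call = detect_escape(rec.trace, ev, rec.chamber)
            table.scores.append(
                StimulusScore(
                    bee_id=rec.bee_id,
                    stim_index=ev.index,
                    phase=ev.phase,
                    odor=ev.odor,
                    role=ev.role,
                    side_index=ev.side_index,
                    escape=call,
                    velocity=estimate_velocity(rec.trace, ev, rec.chamber),
                    raw_integral=raw_attractance_integral(rec.trace, ev, rec.chamber),
                )
            )
    if table.scores:
        normalize_ai(table, method=ai_norm)
    return table
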