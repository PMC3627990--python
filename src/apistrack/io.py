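"""Plain-text readers and writers for session logs.

One session is stored as a pair of TSV files sharing a stem:

``<stem>.trace.tsv``
    header line ``# apistrack-trace v1``, metadata lines ``#key<TAB>value``
    (bee id, provenance, chamber fields), a column-header line, then one
    ``t_s<TAB>x_cm`` row per sample (t to 3 decimals, x to 4).

``<stem>.events.tsv``
    header line ``# apistrack-events v1``, protocol metadata, then one row
    per stimulus with ``NA`` for absent shock fields.

Serialization is deterministic: the same record always produces the same
bytes, and reading a written pair reproduces the record exactly.  Files
violating a type invariant are rejected with the offending line number,
never silently coerced.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import yaml

from .chamber import ChamberConfig
from .records import SessionProtocol, SessionRecord, ShockSchedule, StimulusEvent, Trace

__all__ = ["read_trace_log", "write_trace_log", "TraceLogError", "load_config", "events_path_for"]

TRACE_MAGIC = "# apistrack-trace v1"
EVENTS_MAGIC = "# apistrack-events v1"
_TRACE_COLUMNS = "t_s\tx_cm"
_EVENT_COLUMNS = (
    "index\tphase\tt_stim_s\tduration_s\todor\trole\tside_index\tshock_onset_s\tshock_dur_s"
)


class TraceLogError(ValueError):
    """A session log violated the dialect or a data invariant."""

    def __init__(self, path, line_no: int | None, message: str):
        self.path = str(path)
        self.line_no = line_no
        where = f"{path}:{line_no}" if line_no is not None else str(path)
        super().__init__(f"{where}: {message}")


def events_path_for(trace_path) -> Path:
    p = str(trace_path)
    if p.endswith(".trace.tsv"):
        return Path(p[: -len(".trace.tsv")] + ".events.tsv")
    return Path(os.path.splitext(p)[0] + ".events.tsv")


def _fmt(value) -> str:
    # repr round-trips floats exactly through float()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_trace_log(record: SessionRecord, path) -> Path:
    """Serialize a session to its trace/events TSV pair.

    ``path`` names the trace file; the events file is written next to it.
    Returns the trace path.  The record is validated first; an empty trace
    is an error.
    """
    if len(record.trace) == 0:
        raise ValueError("refusing to write a session with an empty trace")
    record.validate()
    path = Path(path)
    ch, pr = record.chamber, record.protocol

    lines = [TRACE_MAGIC]
    lines.append(f"#bee_id\t{record.trace.bee_id}")
    lines.append(f"#provenance\t{record.provenance}")
    lines.append(f"#chamber_length_cm\t{_fmt(ch.length)}")
    lines.append(f"#chamber_width_cm\t{_fmt(ch.width)}")
    lines.append(f"#chamber_depth_cm\t{_fmt(ch.depth)}")
    lines.append(f"#n_sensors\t{ch.n_sensors}")
    lines.append(f"#sampling_rate_hz\t{_fmt(ch.sampling_rate)}")
    lines.append(_TRACE_COLUMNS)
    for t, x in zip(record.trace.t, record.trace.x):
        lines.append(f"{t:.3f}\t{x:.4f}")
    path.write_text("\n".join(lines) + "\n")

    elines = [EVENTS_MAGIC]
    elines.append(f"#bee_id\t{record.trace.bee_id}")
    elines.append(f"#csplus_odor\t{pr.csplus_odor}")
    elines.append(f"#training_order\t{pr.training_order}")
    elines.append(f"#test_order\t{pr.test_order}")
    elines.append(f"#iti_s\t{_fmt(pr.iti)}")
    elines.append(f"#stimulus_duration_s\t{_fmt(pr.stimulus_duration)}")
    elines.append(f"#test_gap_s\t{_fmt(pr.test_gap)}")
    elines.append(f"#t_first_s\t{_fmt(pr.t_first)}")
    elines.append(f"#side_assignments\t{','.join(str(s) for s in pr.side_assignments)}")
    shocks = [ev.shock for ev in record.events if ev.shock is not None]
    ref = shocks[0] if shocks else ShockSchedule()
    elines.append(f"#shock_pulse_rate_hz\t{_fmt(ref.pulse_rate)}")
    elines.append(f"#shock_pulse_width_s\t{_fmt(ref.pulse_width)}")
    elines.append(f"#shock_voltage_v\t{_fmt(ref.voltage)}")
    elines.append(_EVENT_COLUMNS)
    for ev in record.events:
        if ev.shock is None:
            onset, dur = "NA", "NA"
        else:
            onset, dur = _fmt(ev.shock.onset_offset), _fmt(ev.shock.total_duration)
        elines.append(
            f"{ev.index}\t{ev.phase}\t{_fmt(ev.t_stim)}\t{_fmt(ev.duration)}\t"
            f"{ev.odor}\t{ev.role}\t{ev.side_index}\t{onset}\t{dur}"
        )
    events_path_for(path).write_text("\n".join(elines) + "\n")
    return path


def _read_metadata(lines: list[str], path, magic: str) -> tuple[dict, int]:
    if not lines or lines[0].rstrip("\n") != magic:
        raise TraceLogError(path, 1, f"missing header {magic!r}")
    meta: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i].rstrip("\n")[1:]
        if "\t" not in body:
            raise TraceLogError(path, i + 1, "metadata line without tab separator")
        key, value = body.split("\t", 1)
        meta[key] = value
        i += 1
    return meta, i


def read_trace_log(path) -> SessionRecord:
    """Read a trace/events TSV pair back into a :class:`SessionRecord`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    meta, i = _read_metadata(lines, path, TRACE_MAGIC)
    for key in ("bee_id", "chamber_length_cm", "n_sensors", "sampling_rate_hz"):
        if key not in meta:
            raise TraceLogError(path, None, f"missing metadata key {key!r}")
    chamber = ChamberConfig(
        length=float(meta["chamber_length_cm"]),
        width=float(meta.get("chamber_width_cm", 2.0)),
        depth=float(meta.get("chamber_depth_cm", 0.6)),
        n_sensors=int(meta["n_sensors"]),
        sampling_rate=float(meta["sampling_rate_hz"]),
    )
    if i >= len(lines) or lines[i].rstrip("\n") != _TRACE_COLUMNS:
        raise TraceLogError(path, i + 1, f"expected column header {_TRACE_COLUMNS!r}")
    i += 1
    ts, xs = [], []
    for j in range(i, len(lines)):
        row = lines[j].rstrip("\n")
        if not row:
            continue
        parts = row.split("\t")
        if len(parts) != 2:
            raise TraceLogError(path, j + 1, f"expected 2 columns, got {len(parts)}")
        try:
            t, x = float(parts[0]), float(parts[1])
        except ValueError:
            raise TraceLogError(path, j + 1, f"non-numeric sample {row!r}") from None
        if not (chamber.position_min - 1e-9 <= x <= chamber.position_max + 1e-9):
            raise TraceLogError(
                path, j + 1,
                f"position {x} cm outside [{chamber.position_min}, {chamber.position_max}]",
            )
        if ts and t <= ts[-1]:
            raise TraceLogError(path, j + 1, f"non-monotone timestamp {t}")
        ts.append(t)
        xs.append(x)
    if not ts:
        raise TraceLogError(path, None, "trace contains no samples")
    trace = Trace(bee_id=meta["bee_id"], t=np.array(ts), x=np.array(xs))

    epath = events_path_for(path)
    if not epath.exists():
        raise TraceLogError(epath, None, "events file missing for trace")
    elines = epath.read_text().splitlines()
    emeta, k = _read_metadata(elines, epath, EVENTS_MAGIC)
    sides = tuple(int(s) for s in emeta.get("side_assignments", "").split(",") if s)
    protocol = SessionProtocol(
        training_order=emeta["training_order"],
        test_order=emeta["test_order"],
        csplus_odor=emeta["csplus_odor"],
        iti=float(emeta["iti_s"]),
        stimulus_duration=float(emeta["stimulus_duration_s"]),
        test_gap=float(emeta["test_gap_s"]),
        t_first=float(emeta["t_first_s"]),
        side_assignments=sides,
    )
    if k >= len(elines) or elines[k].rstrip("\n") != _EVENT_COLUMNS:
        raise TraceLogError(epath, k + 1, "expected event column header")
    events = []
    for j in range(k + 1, len(elines)):
        row = elines[j].rstrip("\n")
        if not row:
            continue
        parts = row.split("\t")
        if len(parts) != 9:
            raise TraceLogError(epath, j + 1, f"expected 9 columns, got {len(parts)}")
        try:
            shock = None
            if parts[7] != "NA":
                shock = ShockSchedule(
                    onset_offset=float(parts[7]),
                    total_duration=float(parts[8]),
                    pulse_rate=float(emeta.get("shock_pulse_rate_hz", 1.2)),
                    pulse_width=float(emeta.get("shock_pulse_width_s", 0.2)),
                    voltage=float(emeta.get("shock_voltage_v", 10.0)),
                )
            events.append(
                StimulusEvent(
                    index=int(parts[0]),
                    phase=parts[1],
                    t_stim=float(parts[2]),
                    duration=float(parts[3]),
                    odor=parts[4],
                    role=parts[5],
                    side_index=int(parts[6]),
                    shock=shock,
                )
            )
        except ValueError as exc:
            raise TraceLogError(epath, j + 1, str(exc)) from None
    record = SessionRecord(
        chamber=chamber,
        protocol=protocol,
        trace=trace,
        events=events,
        provenance=meta.get("provenance", "measured"),
    )
    try:
        record.validate()
    except ValueError as exc:
        raise TraceLogError(path, None, str(exc)) from None
    return record


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run configuration must be a YAML mapping")
    return cfg
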