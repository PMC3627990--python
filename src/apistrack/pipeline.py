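"""End-to-end orchestration: simulate -> score -> stats -> report.

A run directory contains the per-bee trace/event logs, the scored table
(``scores.tsv``), the inferential summary (``stats.json``), an HTML report
with the escape-rate and velocity/AI panels, the resolved configuration and
a run log.  Everything except the log timestamps is byte-reproducible from
the configuration.
"""

from __future__ import annotations

import base64
import io as _io
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import SCENARIOS, BehaviorParams
from .chamber import ChamberConfig, DEFAULT_CHAMBER
from .io import write_trace_log, read_trace_log
from .records import SessionProtocol, SessionRecord, StimulusEvent, Trace
from .scoring import CohortTable, score_cohort
from .simulate import simulate_cohort, simulate_session, build_protocol
from .stats import summarize_cohort

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "write_scores_tsv", "read_scores_tsv"]

logger = logging.getLogger(__name__)

SCORES_MAGIC = "# apistrack-scores v1"


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    scenario: str = "paper-recall"
    n: int = 174
    seed: int = 1
    out_dir: str = "run"
    ai_norm: str = "minmax"
    n_boot: int = 2000
    chamber: dict = field(default_factory=dict)  # ChamberConfig overrides
    behavior: dict = field(default_factory=dict)  # BehaviorParams overrides
    write_report: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; available: {sorted(SCENARIOS)}"
            )
        if self.ai_norm not in ("minmax", "symmetric"):
            raise ValueError("ai_norm must be 'minmax' or 'symmetric'")
        ChamberConfig(**self.chamber)  # type-check overrides early
        resolved = {**asdict(SCENARIOS[self.scenario]), **self.behavior}
        BehaviorParams(**resolved)

    def chamber_config(self) -> ChamberConfig:
        return ChamberConfig(**self.chamber)

    def behavior_params(self) -> BehaviorParams:
        return BehaviorParams(**{**asdict(SCENARIOS[self.scenario]), **self.behavior})


def write_scores_tsv(table: CohortTable, path) -> Path:
    """Serialize a scored cohort deterministically, constants in the header."""
    path = Path(path)
    lines = [SCORES_MAGIC]
    lines.append(f"#ai_norm\t{table.ai_norm}")
    lines.append(f"#min_raw\t{table.min_raw!r}")
    lines.append(f"#max_raw\t{table.max_raw!r}")
    lines.append(f"#n_skipped\t{table.n_skipped}")
    frame = table.to_frame()
    cols = list(frame.columns)
    lines.append("\t".join(cols))
    for row in frame.itertuples(index=False):
        vals = []
        for col, v in zip(cols, row):
            if col == "escaped":
                vals.append("1" if v else "0")
            elif col == "crossing_time_s":
                vals.append("NA" if pd.isna(v) else f"{v:.3f}")
            elif col in ("velocity_cm_s", "raw_integral_cm_s", "ai"):
                vals.append("NA" if pd.isna(v) else f"{v:.6f}")
            else:
                vals.append(str(v))
        lines.append("\t".join(vals))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_scores_tsv(path) -> pd.DataFrame:
    """Read a scores TSV back into a frame (header constants as attrs)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != SCORES_MAGIC:
        raise ValueError(f"{path}: missing header {SCORES_MAGIC!r}")
    meta = {}
    i = 1
    while i < len(lines) and lines[i].startswith("#"):
        key, _, value = lines[i][1:].partition("\t")
        meta[key] = value
        i += 1
    frame = pd.read_csv(
        _io.StringIO("\n".join(lines[i:])), sep="\t", na_values=["NA"]
    )
    frame["escaped"] = frame["escaped"].astype(bool)
    frame.attrs.update(meta)
    return frame


def _fig_to_base64(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _render_report(frame: pd.DataFrame, summary: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = ["1.CS+", "2.CS+", "1.CS-", "2.CS-"]
    rates = summary["escape_rates"]

    fig1, ax = plt.subplots(figsize=(5, 3.4))
    present = [c for c in classes if c in rates]
    vals = [100 * rates[c]["rate"] for c in present]
    err_lo = [100 * (rates[c]["rate"] - rates[c]["ci_low"]) for c in present]
    err_hi = [100 * (rates[c]["ci_high"] - rates[c]["rate"]) for c in present]
    colors = ["white" if "CS+" in c else "0.6" for c in present]
    ax.bar(present, vals, yerr=[err_lo, err_hi], color=colors, edgecolor="black", capsize=4)
    ax.set_ylabel("escape rate (%)")
    ax.set_ylim(0, 100)
    ax.set_title("Automatically detected escapes (95% Clopper-Pearson CI)")
    fig1.tight_layout()

    figs = [fig1]
    for value, label in (("velocity_cm_s", "velocity (cm/s)"), ("ai", "Attractance Index")):
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.4), sharey=True)
        for ax2, (title, key) in zip(
            axes,
            (
                ("all responses", f"{value}_by_class_all_responses"),
                ("escape subset", f"{value}_by_class_escape_subset"),
            ),
        ):
            comp = summary["group_comparisons"].get(key, {})
            groups = comp.get("groups", {})
            present = [c for c in classes if c in groups]
            if present:
                means = [groups[c]["mean"] for c in present]
                lo = [groups[c]["mean"] - groups[c]["ci_low"] for c in present]
                hi = [groups[c]["ci_high"] - groups[c]["mean"] for c in present]
                colors = ["white" if "CS+" in c else "0.6" for c in present]
                ax2.bar(present, means, yerr=[lo, hi], color=colors,
                        edgecolor="black", capsize=4)
            else:
                ax2.text(0.5, 0.5, "degenerate", ha="center", va="center",
                         transform=ax2.transAxes)
            ax2.axhline(0.0, color="black", lw=0.8)
            ax2.set_title(title)
        axes[0].set_ylabel(label)
        fig.suptitle(f"{label} by stimulus class (95% bootstrap interval)")
        fig.tight_layout()
        figs.append(fig)

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>apistrack run report</title></head><body>",
        f"<h1>apistrack run report</h1><p>version {__version__}; "
        f"{summary.get('n_bees', 0)} bees, {summary.get('n_stimuli', 0)} test stimuli.</p>",
    ]
    for fig in figs:
        parts.append(f"<p><img src='data:image/png;base64,{_fig_to_base64(fig)}'/></p>")
        plt.close(fig)
    corr = summary.get("correlations", {})
    parts.append("<h2>Rank correlations</h2><ul>")
    for k, v in corr.items():
        if "rho" in v:
            parts.append(f"<li>{k}: rho = {v['rho']:.3f} (SE {v['se']:.3f})</li>")
    parts.append("</ul></body></html>")
    path.write_text("\n".join(parts))


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate -> score -> stats -> report into a fresh directory.

    Stage failures abort with the stage name; the run log records versions,
    seeds and the AI normalization constants.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("apistrack")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("apistrack %s; scenario=%s n=%d seed=%d",
                    __version__, config.scenario, config.n, config.seed)
        (out / "config.yaml").write_text(
            yaml.safe_dump(asdict(config), sort_keys=True)
        )
        stage = "simulate"
        try:
            records = simulate_cohort(
                config.n,
                seed=config.seed,
                params=config.behavior_params(),
                chamber=config.chamber_config(),
            )
            traces_dir = out / "traces"
            traces_dir.mkdir(exist_ok=True)
            for rec in records:
                write_trace_log(rec, traces_dir / f"{rec.bee_id}.trace.tsv")
            manifest = {
                "generator": f"apistrack-{__version__}",
                "scenario": config.scenario,
                "n": config.n,
                "seed": config.seed,
            }
            (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

            stage = "score"
            table = score_cohort(records, ai_norm=config.ai_norm)
            write_scores_tsv(table, out / "scores.tsv")
            logger.info("scored %d stimuli; min_raw=%s max_raw=%s",
                        len(table), table.min_raw, table.max_raw)

            stage = "stats"
            frame = table.to_frame()
            summary = summarize_cohort(frame, n_boot=config.n_boot, seed=config.seed)
            (out / "stats.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True, allow_nan=True)
            )

            if config.write_report:
                stage = "report"
                _render_report(frame, summary, out / "report.html")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("run complete: %s", out)
        return out
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# test fixtures


def _hand_trace(bee_id: str, xs, dt: float = 0.2) -> Trace:
    xs = np.asarray(xs, dtype=float)
    return Trace(bee_id=bee_id, t=np.arange(xs.size) * dt, x=xs)


def make_fixtures(seed: int = 1) -> dict:
    """Canonical small fixtures used by the test-suite.

    Hand-constructed single-stimulus traces (stationary bee, monotone
    midline crossing, crossing with return) plus a short-session 8-bee
    simulated cohort.  Regeneration with the same seed reproduces every
    fixture exactly.
    """
    event = StimulusEvent(
        index=0, phase="test", t_stim=0.0, duration=4.0,
        odor="linalool", role="CS+", side_index=1,
    )
    stationary = _hand_trace("stationary", [5.0] * 21)
    ramp = np.concatenate([np.linspace(6.0, -6.0, 11), np.full(10, -6.0)])
    monotone = _hand_trace("monotone_crossing", ramp)
    recross = _hand_trace(
        "recross",
        np.concatenate([np.linspace(6.0, -2.0, 6), np.linspace(-1.4, 1.0, 5), np.full(10, 1.0)]),
    )
    cohort = simulate_cohort(
        8, seed=seed, protocol_kwargs={"iti": 5.0, "test_gap": 10.0, "t_first": 5.0}
    )
    return {
        "event": event,
        "stationary": stationary,
        "monotone_crossing": monotone,
        "recross": recross,
        "cohort": cohort,
    }
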