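# apistrack

Quantification of aversive olfactory conditioning in freely walking honey
bees, for labs running (or modeling) automated 1-D shuttle-chamber assays.
A bee walks in a narrow chamber monitored by a row of photo sensors at
5 Hz; odors enter from either end, and during training one odor (the CS+)
is paired with a mild electric shock. `apistrack` turns the resulting
position traces into the assay's behavioral readouts and statistics, and
ships a calibrated agent-based simulator of the whole experiment.

## Readouts

For each 4-s test stimulus with odor side index `SI` (+1 right, -1 left)
and position trace `P(t)`:

* **Escape** — the bee is on the odor side at onset and crosses the
  chamber midline without returning during the stimulation window.
* **Signed velocity** — mean derivative over the first 2 s of a natural
  cubic spline through the dwell-midpoint knots of the trace, in cm/s;
  movement away from the odor is negative. The mean-derivative form
  collapses to `SI * (P(t0+2) - P(t0)) / 2`.
* **Attractance Index** —

      AI_stim = SI * integral from t_stim to t_stim+4 of P(t) dt

  approximated with the trapezoid rule and normalized over the minimum
  and maximum integral of the whole scored population, so AI is
  dimensionless in [-1, 1]; positive means presence on (or movement
  toward) the odor side. AI >= 0.3 is typical for attraction, <= 0.1 for
  avoidance.

The inferential layer provides exact Clopper-Pearson rate intervals,
two-proportion chi-square and McNemar tests, tie-corrected Spearman
correlations with bootstrap SEs, bee-level cluster-bootstrap group
comparisons with overlap probabilities, and observer concordance. See
`docs/methods.md` for the model, calibration and all conventions.

## Worked example

Simulate the default recall experiment (174 bees), score it, and run the
statistics — either in Python or from the shell:

```sh
apistrack reproduce-recall --n 174 --seed 1 --out recall-run
```

```python
import json
from apistrack.pipeline import RunConfig, run_pipeline

out = run_pipeline(RunConfig(n=174, seed=1, out_dir="recall-run"))
stats = json.loads((out / "stats.json").read_text())
```

The run directory contains one trace/event TSV pair per bee, the scored
table `scores.tsv`, `stats.json` and an HTML report. With seed 1,
`stats.json` holds (rates with their 95% Clopper-Pearson intervals):

```
escape rates   1.CS+ 51.1% [43.5, 58.8]    1.CS- 17.2% [11.9, 23.7]
               2.CS+ 56.9% [49.2, 64.4]    2.CS- 19.5% [13.9, 26.2]
velocity       CS+ -1.50 cm/s   CS- -0.27 cm/s   CS+ escapes only -2.53 cm/s
AI             CS- +0.34        CS+ -0.06        CS+ escapes only -0.40
Spearman       velocity-escape -0.72   AI-escape -0.74   velocity-AI 0.84
```

Read: about half the bees flee the shock-trained odor on the first test
trial while under a fifth flee the safe odor (generalization); escaping
bees run away at -2.5 cm/s, twice the population average, and their
strongly negative AI shows they also end up far from the odor. The three
correlations say the binary escape call, the velocity and the AI rank the
same bees the same way — the continuous readouts carry the escape signal
plus graded information the binary call misses.

Individual operators are plain functions:

```python
from apistrack.scoring import detect_escape, estimate_velocity
from apistrack.io import read_trace_log

rec = read_trace_log("recall-run/traces/bee0000.trace.tsv")
ev = rec.test_events()[0]
detect_escape(rec.trace, ev, rec.chamber)   # EscapeCall(escaped=..., ...)
estimate_velocity(rec.trace, ev, rec.chamber)  # cm/s, odor-relative sign
```

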