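# Methods

## The assay and what the package quantifies

A single honey bee walks freely in a narrow 1-D conditioning chamber
(14.8 cm x 2.0 cm x 0.6 cm) whose interior carries an electric grid. A row
of 26 infrared photo sensors reports the bee's position along the chamber
axis at 5 Hz. Odors can be injected at either end. During training the bee
receives 8 odor presentations of 4 s each (inter-trial interval 34 s) in a
pseudorandomized order (ABBABAAB or BAABABBA): the CS+ odor is paired with
a mild pulsed electric shock (10 V, 1.2 pulses/s, 200-ms pulses, 3 s
total), the CS- odor is not. The shock starts 2 s after odor onset on the
bee's first CS+ and 1 s after onset on later ones. Five minutes after
training, memory is probed with 4 unreinforced test stimuli (ABBA or
BAAB). During the test, the odor is delivered on the side where the bee
is located at onset, giving it the opportunity to withdraw.

The package computes, per test stimulus:

* **escape**: the bee is on the odor side at onset and crosses the
  chamber midline without returning for the remainder of the 4-s window.
  Sides are evaluated on the 5 Hz samples; a sample exactly on the
  midline inherits the side of the previous sample. "Without returning"
  means a single sample back on the odor side cancels the call.
* **signed velocity** (cm/s): the mean rate of position change over the
  first 2 s of the window, positive toward the odor injection. The
  dwell-time construction (consecutive samples at the same sensor
  collapse to one knot at the dwell's time midpoint) defines a natural
  cubic spline; the mean of its derivative over the window equals the
  endpoint difference divided by the window length, so the reported value
  reduces to `SI * (x(t0+2) - x(t0)) / 2` with boundary positions linearly
  interpolated between the flanking samples. The spline itself is exposed
  for profile inspection and is exact on linear traces.
* **raw attractance integral** (cm*s): `SI` times the trapezoid-rule
  integral of position over the 4-s window, with boundary positions
  interpolated at the exact window edges. Exact for piecewise-linear
  traces with breakpoints on sample times.
* **Attractance Index (AI)**: the raw integral normalized over the pooled
  minimum and maximum of all scored stimuli of the cohort, linearly to
  [-1, 1] (default), or divided by max(|min|, |max|) (zero-preserving
  variant behind a flag). Because bees start on the odor side, AI has a
  positive bias: avoidance does not necessarily produce a negative AI.
  AI >= 0.3 is typical for attraction, <= 0.1 for avoidance.

All side-dependent quantities are multiplied by the side index SI of the
stimulus, which makes every score invariant under mirroring the chamber
(x -> -x together with SI -> -SI); this is tested exactly.

Training-phase behavior is simulated (startle jumps at shock pulses,
agitated post-shock walking) but never scored: at 5 Hz, and with odor
onset uncontrolled relative to the bee's position during training,
acquisition cannot be quantified reliably, so the scoring layer only
consumes the test phase.

## The behavioral simulator

No raw traces were published for this paradigm, so the package ships an
agent-based simulator whose default parameters are calibrated to the
published recall-phase statistics; it also generates all test fixtures.
A bee is a point on the chamber axis with four modes:

* **explore** — constant-speed walking (default 2.0 cm/s, several chamber
  traversals per inter-trial interval) with reflection at the walls and
  Poisson random turns (0.1 /s). A `left_bias` parameter can skew turn
  directions; the default is symmetric.
* **startled** (training CS+ only) — an instantaneous 1.5-cm jump away
  from the odor at shock onset, then agitated walking at twice the
  explore speed for the shock period plus 5 s.
* **escaping** (test, with probability 0.540 per CS+ stimulus and 0.178
  per CS-) — after a uniform latency in [0.2, 1.0] s the bee moves so
  that its displacement at exactly 2 s after onset is twice the drawn
  signed velocity, then commits to a run that crosses the midline and
  settles at a rest depth drawn uniformly between 2.5 cm and the far wall,
  arriving no later than 3.8 s after onset. Faster drifts settle sooner
  (settle-time scale 1.2 s).
* **attracted / non-escape drift** — the bee drifts at the drawn velocity
  for the first 2 s, then settles toward a set-point inside the odor side:
  the center of the attraction band plus 4 s times the drawn drift
  velocity. For a CS- the band is the innermost position from which the
  bee spends `attraction_dwell` (default 0.8) of its dwell time in the
  odor-side third of the chamber; for a CS+ the floor is 0.8 cm. A bee
  whose drift carried it across the midline is forced back to the odor
  side well before the window closes, so a non-escape draw can never be
  scored as an escape.

Per-stimulus velocities are drawn from normal distributions with the
configured means (escape: -2.5 cm/s CS+, -1.8 cm/s CS-; non-escape drift:
-0.33 cm/s CS+, +0.15 cm/s CS-; SD 1.2 cm/s) truncated *symmetrically*
about the mean to the wall-feasible interval. Symmetric truncation is what
makes the scoring module's velocity estimator recover the configured means
without bias; one-sided feasibility clipping (an earlier design) biased
recovered escape velocities by up to 0.45 cm/s.

The hidden path is piecewise linear, built event-by-event, evaluated on an
internal 50 Hz grid, and only then passed through the sensor model
(sampling at 5 Hz, quantization to the nearest of 26 sensor-field centers,
error at most half the 0.569-cm pitch). Scoring never sees the hidden
path. Given (protocol, parameters, chamber, seed) the whole session is
reproducible bit for bit; cohort members get independent seeds from a
seed sequence.

### Calibration

The non-escape drift means are moment matches: with escape probability p
and escape-velocity mean v_esc, the drift mean solves
`p*v_esc + (1-p)*v_non = population mean` for the published population
means (-1.5 cm/s CS+, -0.2 cm/s CS-). The velocity SD (1.2 cm/s) was
calibrated by simulation sweep so the velocity-escape Spearman correlation
of a default 174-bee cohort lands at the published -0.73; the analytic
rank-biserial identity `rho = sqrt(12 p q) (AUC - 1/2)` gives the same
answer. The escape rest-depth range, settle time and the drift-to-set-point
gain were set so the escape-subset means (velocity -2.5 cm/s, AI -0.32 for
CS+) and the AI-escape (-0.76) and velocity-AI (0.84) correlations are
reproduced; the velocity-AI value is structural — both metrics derive from
the same traces — not directly configured. `attraction_dwell = 0.8`
reproduces the pooled CS- AI of 0.37 under the default min-max
normalization.

### What the simulator does and does not emulate

It reproduces the recall-phase marginal statistics (rates, velocity and
AI means, their correlations) and the qualitative behavioral repertoire.
It does not model odor identity effects (the published linalool/nonanol
asymmetries), habituation or extinction across test trials, 2-D posture,
buzzing, air flow, or pheromone accumulation; training-phase dynamics are
schematic. Tests passing on simulated cohorts therefore validate the
scoring and inference machinery and the calibration targets — they are
not evidence about real bees beyond the statistics the calibration pins.

## Statistics

Response rates carry exact Clopper-Pearson 95% intervals (inverted
binomial tails). Rates between independent groups are compared with a
1-df chi-square (Yates correction by default, configurable off — the
published chi-squares correspond to the uncorrected variant). Rates of
paired stimulus groups within bees use McNemar's test on the discordant
pairs, uncorrected `(b-c)^2/(b+c)` by default with the continuity
correction behind a flag; because the pairing that produced the published
within-method chi-squares is not documented, the cohort summary reports
both a per-trial variant (first trials, second trials) and a per-bee
pooled variant (any escape per role), labeled as such. Spearman rank
correlations use the tie-corrected average-rank formula with a case
bootstrap SE.

Group means of velocity and AI by stimulus class are compared with a
bee-level cluster bootstrap instead of the original mixed model with bee
as random effect: bees are resampled with replacement within each group,
giving per-group means, 95% percentile intervals and an overlap
probability — the fraction of one group's resampled means falling inside
the other group's interval — which mirrors the original significance rule
(probability of a simulated parameter from one group lying within the
compared group's 95% interval). With no informative priors the original
intervals resemble confidence intervals of the observed data, which the
cluster bootstrap estimates directly; this avoids re-implementing REML
and posterior simulation while preserving the deliverables. With
singleton clusters the procedure reduces to the ordinary case bootstrap.
No multiple-testing adjustment is applied; raw p-values are reported.

## Numerical choices and degenerate inputs

* Sample times are multiples of 0.2 s; logs store t to 3 decimals and x
  to 4, and the simulator emits exactly those values, so write-read
  round-trips are identities and repeated writes are byte-identical.
* Window slicing uses a 1-microsecond tolerance; stimulus onsets need not
  coincide with sample times, in which case boundary positions are
  linearly interpolated between flanking samples (the nearest sample is
  extended at the trace ends).
* A stationary bee (fewer than two distinct positions in the velocity
  window) scores velocity 0. A degenerate cohort (all raw integrals
  equal) scores AI 0 everywhere. An empty cohort refuses to normalize.
* Records lacking the expected four test events are skipped with a
  logged warning and counted, never silently dropped.
* Sensor quantization maps the exact midline to the right-hand sensor
  (tie to the upper bin); side preservation is guaranteed for any
  position more than float-rounding away from 0. Escape dashes overshoot
  the midline by 0.25 cm so quantization cannot flip a crossing.
* The cluster bootstrap reports percentile intervals; groups with fewer
  than two clusters raise, and the pipeline records such comparisons as
  degenerate instead of failing (relevant for n = 1 cohorts).

## Problem sizes

Default cohorts are 174 bees (the published cohort size), scored in under
a second; the full simulate-score-stats pipeline on 174 bees with 2000
bootstrap resamples runs in a few seconds. The test suite simulates
cohorts of 60-300 short-protocol sessions for recovery checks and uses
1000-trace oracle comparisons for escape detection.

## Known limitations

* The escape definition is the literal reading of "crossing the middle
  without returning" on 5 Hz samples; the original implementation's
  figure-level details were not available, so borderline cases (single
  -sample excursions, exact-midline dwells) follow the documented
  tie-breaks rather than any reference output.
* The exact spline construction from dwell times is under-specified in
  the source description; knots at dwell-time midpoints are one
  defensible reading, and the reported velocity is insensitive to the
  choice because it reduces to the window-endpoint form.
* Whether AI normalization pooled both signs jointly is not documented;
  joint pooling is used, with the symmetric variant available.
* Calibration matches means and rank correlations, not full
  distributions; quantities outside the calibrated set (e.g. crossing
  -time distributions) should not be read as predictions of real data.
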