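# Methods

This note documents the models, conventions, and numerical choices behind
`reachtime`, in the spirit of a statistical package's methods appendix.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Coordinate frame and calibration geometry

All geometry is expressed in meters in a right-handed frame with +y up and
+z the participant's forward; the origin is arbitrary because every
quantity is relative to the sternum anchor *b*. Calibration records *b*,
the extended-arm anchor *r*, and *d* = |r − b| (coincident anchors are
rejected). The nine stimulus locations are

  loc(row, col) = b + d · (cos e sin a, sin e, cos e cos a),

with elevation e ∈ {+30°, 0, −30°} by row and azimuth a ∈ {−35°, 0, +35°}
by column (negative a = participant's left), numbered row-major 1–9 with
5 central. This parameterization is chosen over sequential rotations for
the corner locations because it keeps *every* location exactly at
distance *d*; for the non-corner locations it coincides with explicit
single-axis rotations, which the test suite verifies against a
rotation-matrix oracle. The base sphere has radius 0.028 m with an
inclusive boundary. Cube stimuli have 0.10-m edges; the front-face center
sits on the grid location and the body extends away from the participant.
A moving cube travels in a straight line at constant speed and continues
past its target location until stimulus offset (the protocol does not
require it to stop, and stopping would create a speed discontinuity).

## Protocol generation

Trial decks are counterbalanced exactly and shuffled with a seeded
`numpy` generator, so color proportions are equal by construction, not in
expectation, and a (config, seed) pair reproduces a schedule bit for bit.
Inter-stimulus intervals are continuous-uniform over the closed configured
range. "20 trials per stimulus type" is read per go/no-go *category* by
default (simple phase: 20 trials, 5 per color; choice phase: 40 trials,
10 per color); `phase1_count_mode="color"` switches to 20 per color.
Training trials (4 in phase 1, 2 in reach tasks) follow the same
generative rules, are flagged, and are excluded from all metrics. Dynamic
speed staging is by test-trial position (first nine at 0.6 m/s, then
0.75, then 0.9) regardless of seed; origins are randomized under the
three-per-location constraint; the 27 colors come from a shuffled
28-card deck truncated to 27 (counts 7/7/7/6). Dynamic training trials
use the first staged speed.

## Scoring conventions

* RT validity window: [100, 1000] ms, both endpoints inclusive (the
  boundary rule is a convention; the cutoffs themselves are protocol
  constants).
* No-go trials: any response is a false alarm regardless of latency;
  otherwise a correct rejection.
* Movement displacement subtracts the 0.028-m base radius from the
  onset-to-touch controller gap, aligning displacement with MT, which
  starts only at base exit. The onset position is the most recent
  controller sample at or before stimulus onset.
* MT > 600 ms removes that trial's MT and MV from central values (robust
  cutoff against corrective double movements) but keeps its RT; the trial
  counts toward the over-600 rate.
* A movement omission is a trial with a valid RT and no touch before
  stimulus offset.
* ICV uses the sample SD (n − 1). Medians of even counts are midpoints.
* A base exit before a trial's onset marks the run as paused at that
  trial; paused trials are excluded from every denominator and reported
  as a separate count.
* Responses are attributed to the trial window from onset to the next
  onset, so a response slower than the display persists with its trial.

## Synthetic participants

The generator exists to give the scoring and agreement layers inputs with
known ground truth; it is a stand-in for behavior, not a cognitive model.

* **Latency.** Ex-Gaussian per task family (press/button, center-reach,
  spatial-reach, dynamic-reach): RT = μ_family + latent + bias_VR·[VR] +
  cost_choice·[go/no-go phase] + N(0, σ) + Exp(τ), resampled if ≤ 0.
  Defaults (ms): press (205, 16, 35), center (280, 30, 40), spatial
  (322, 30, 40), dynamic (280, 28, 40); bias_VR = 32, cost_choice = 120.
  These central values were set once so that simulated group statistics
  sit near a published 48-participant cohort of healthy adults (computer
  simple-RT mean ≈ 240 ms, headset ≈ 272 ms, choice cost ≈ 121 ms, reach
  task medians ≈ 341/386/345 ms); the self-consistency test checks the
  generator against its *own* implied values, not against that cohort.
* **Population.** Across participants the latent speed is
  N(0, 18 ms), the choice cost N(120, 30 ms) truncated at 0, and the
  reach-duration scale lognormal(0, 0.2). The shared latent speed is what
  produces cross-test correlation; the variance-components identity
  r = s²/(s² + σ²_w) is verified by simulation.
* **Reaching.** Minimum-jerk path p(s) = start + (target − start)·(10s³ −
  15s⁴ + 6s⁵), sampled at 72 Hz (a common headset controller rate; the
  true rate is configurable). Reach durations are lognormal with
  task-family medians 187/191/147 ms and log-SD 0.25.
* **Aiming and errors.** Anticipations (<100 ms), lapses, false alarms,
  and give-ups are explicit Bernoulli processes (defaults 0.005, 0.005,
  0.08, 0.01). Touch failures additionally *emerge* from aiming noise:
  the participant aims at the cube's predicted front-face center at
  arrival, misjudging arrival time by N(0, 40 ms) when the cube moves —
  an error that scales with cube speed — plus isotropic endpoint noise
  (12 mm; doubled in the spatial task, where location uncertainty
  plausibly degrades endpoints). The hand stops at the face plane; a
  contact outside the face on a *static* cube triggers one corrective
  movement (total MT × 3.2) that produces the very long MTs the 600-ms
  cutoff is designed to catch, while a miss on a *moving* cube ends the
  trial untouched. This yields the qualitative pattern of high movement
  omissions in the dynamic task and over-600 rates concentrated in the
  spatial task without hard-coding either rate.
* **Not modeled.** Learning/fatigue across trials, biomechanics, eye
  movements, hardware latency jitter, dropped frames. Passing tests
  therefore certify the *pipeline* (scheduling, scoring, statistics) on
  realistic-shaped data, not any claim about human cohorts.

## Agreement statistics

* **Bland–Altman.** bias = mean(a − b), limits of agreement =
  bias ± 1.96·SD(a − b) with the sample SD; proportional bias is the OLS
  slope of differences on pairwise means with its t-test p. The 1.96
  multiplier is the 95% convention.
* **Repeated-measures ANOVA.** One-way, complete data only (no
  imputation). F and partial η² come from the classical sums-of-squares
  decomposition; Mauchly's W and the Greenhouse–Geisser ε come from
  `pingouin`; when Mauchly rejects at p < .05 both degrees of freedom are
  multiplied by ε. With two conditions sphericity holds trivially
  (ε = 1, W = 1) and F equals the squared paired-t statistic.
* **Nonparametric tests.** Wilcoxon signed-rank drops zero differences
  (Wilcoxon's original rule) and uses the exact null distribution for
  small tie-free samples, otherwise the normal approximation (scipy's
  selection); Friedman uses the chi-square approximation. At three
  conditions and n ≈ 48 that approximation is known to be mildly
  anticonservative (measured ≈ 0.0545 true type-I at α = 0.05 over
  20,000 null replicates), which is why the calibration test asserts
  |rate − α| ≤ 0.015 at 2,000 replicates: 2-SE Monte-Carlo noise
  (±0.010) plus approximation error (±0.005), rather than a band the
  approximation itself cannot satisfy.
* **Power.** The a priori sample size for a correlation test integrates
  Hotelling's exact density of the sample correlation under bivariate
  normality (log-space gamma functions plus ₂F₁, adaptive quadrature)
  and returns the smallest n whose exact two-tailed test of ρ = 0
  reaches the requested power — for r = 0.4, α = .05, power = .80 this
  gives n = 46, matching dedicated power software. The Fisher-z route
  (n = ((z_{α/2} + z_β)/atanh r)² + 3 → 47) is provided and labeled
  approximate.
* **Multiplicity.** Bonferroni-adjusted α is reported at 4 decimals
  (0.05/7 → 0.0071, 0.05/12 → 0.0042), matching the convention of the
  validation literature this layer serves.

## Problem sizes and determinism

The test suite uses 8–200 simulated participants depending on what a check
needs (200 for bias recovery, where the Monte-Carlo SE of the recovered
bias is ≈ 0.8 ms; 500 draw-level participants for the latency
self-consistency check; 2,000 replicates for type-I calibration). All
randomness flows from named integer seeds; identical seeds give
byte-identical session files, summary tables, and reports.

## Known limitations

* The simulator's error processes are independent across trials; real
  lapses cluster.
* The pause mechanic is modeled only as a scoring flag, not as schedule
  mutation, so simulated sessions never pause.
* External session files are accepted only in the documented JSONL
  schema; proprietary headset capture formats need conversion upstream.
* The agreement layer covers the validation designs implemented here
  (paired two-method comparison, one-way within-subject contrasts);
  mixed-effects trial-level modeling is out of scope.
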