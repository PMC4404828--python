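# Methods

## Scope and data model

The package analyzes three behavioral tests that together profile a
rodent's exploratory strategy and coping style:

* a 30-min **multivariate concentric square field (MCSF)** session
  (typically two trials a week apart), tracked as one body point at a
  nominal frame rate, scored into zone visits;
* a 5-min **novel cage** session and a 10-min **home cage change**
  session, scored manually as timed behavior bouts (an ethogram).

The atomic MCSF record is the *visit*: a maximal interval during which
the tracked point stays in one zone.  All descriptive parameters
(latency LAT, frequency FRQ, duration DUR, DUR/FRQ, distance, mean
velocity) derive from visits; manually scored counts (rearings,
stretched attend postures, grooming, nose pokes, urine spots, fecal
boli) enter through a sidecar table because they cannot be derived from
a single tracked point.

## Arena geometry

Only the outer field (100 × 100 cm), the central field (70 × 70 cm) and
the central-circle diameter (22 cm) are fixed by the apparatus
description.  The bundled default config fills in the rest as documented
assumptions: a 15-cm frame around the central field split into corridor
A (left), corridor B (bottom), corridor C (right), the DCR (top-left
corner, reachable only through corridor A), the hurdle, the slope, the
bridge entrance and the bridge along the top.  Elevated structures are
modeled as planar polygons because tracking is 2-D overhead video.

Zone geometries are closed sets; a boundary point is resolved
deterministically to the deepest containing zone, ties broken by config
order.  The central circle is a child of the center and its time is
never double-counted as center time.  Validation enforces unique zone
ids, symmetric adjacency, containment of children in parents,
non-contradictory role tags and the single-access invariant for shelter
zones.

## Visit extraction

Sample *i* covers the half-open interval [t_i, t_{i+1}); the last sample
carries no duration.  This makes the time budget exact: zone time +
unassigned time + missing time = total tracked time.  The step from
sample *i* to *i+1* is credited to the zone of sample *i*, including
boundary-crossing steps, so total distance is conserved; steps starting
at unassigned samples or spanning missing-data gaps belong to no visit.

Tunables:

* `min_visit_duration` (s, default 0): zone runs shorter than this are
  absorbed into the preceding visit.  The default makes extraction
  exactly equal to a per-frame run-length scan, which is the oracle the
  tests use.  Commercial trackers apply undocumented smoothing; this
  parameter is a transparent stand-in, not a reconstruction of any
  product's rule.
* gap tolerance (default min(2 s, 5 frame intervals)): missing-detection
  gaps up to this long, flanked by the same zone, do not break a visit —
  brief dropouts should not inflate FRQ.

Velocity is mean velocity (distance/duration), not an instantaneous
estimate.

## Missing-value policy

When a rat never enters a zone, within-trial analyses treat that zone's
measures as missing; between-trial (paired) analyses set DUR and FRQ to
0 and impute LAT at the session duration (1800 s), so "never entered"
is comparable across trials.  DUR/FRQ is undefined at FRQ = 0 in both
modes.  Index values with a zero denominator are missing rather than
clamped — an absent value stays absent.  Both rules are idempotent.

The %DUR denominator is ambiguous between "total time in zones" and
"total trial time" in common usage; both are implemented
(`denominator_mode`), with total-visits time as the parameter-table
default.

## Trend analysis

For each parameter, all rats across both groups (and both trials, when
present) are pooled and ranked ascending with mid-ranks; parameters
flagged inverse (mean corridor visit duration, corridor and center
durations) are negated first so that high ranks always read as high
expression of the category.  A category score is the rank sum over the
category's parameters.  Mid-rank ties preserve the per-parameter rank
sum m(m+1)/2, and scores are invariant under strictly monotone
transforms of any parameter.

A missing rank is imputed at the pooled mid-rank (m+1)/2 for score
summation so that rats with different missingness stay comparable;
listwise exclusion is available (`missing_rank="listwise"`).

Rank sums are close to normal, so category scores are tested
parametrically: unpaired t within trials; with two trials, a mixed
(group × trial) repeated-measures ANOVA (pingouin) with
Bonferroni-corrected paired t contrasts across trials within each group.
Rats missing a trial are excluded listwise from the ANOVA with a
warning.

## Statistical battery

* **Mann-Whitney U** (group comparisons): exact two-sided p from the
  in-package subset rank-sum null distribution when both groups have
  ≤ 12 observations and the pooled data are tie-free; otherwise a
  tie-corrected normal approximation *without* continuity correction
  (at n = 12/group the correction visibly over-corrects discrete count
  parameters).  The exact path is verified against full enumeration of
  all group assignments.
* **Wilcoxon matched pairs** (trial comparisons): zero differences are
  dropped before ranking; all-zero differences give p = 1 by convention.
  Up to 15 non-zero differences the p-value is the exact sign-flip
  enumeration (tie-safe via mid-ranks, computed by subset-sum DP);
  beyond that, the normal approximation.
* **Friedman + Dunn** (10-min-bin time courses): the Friedman statistic
  is reported in its chi-square form (df = bins − 1); some commercial
  packages print an F-approximation instead, which differs numerically.
  Dunn's pairwise post-hoc compares within-subject rank means with
  z = ΔR̄ / sqrt(k(k+1)/6n) and Bonferroni adjustment over the three bin
  pairs (hand-written; no installed package provides it).
* **Fisher's exact** (occurrence) and **Spearman** (monotone
  association) via scipy; correlation strength bands: |r| < 0.40
  weak/none, 0.40–0.59 moderate, 0.60–0.79 strong, ≥ 0.80 very strong.
* Labels: significant at p ≤ 0.05, trend at 0.05 < p ≤ 0.1 (boundaries
  inclusive).

## Multivariate profiling

Parameters are unit-variance scaled and mean-centered; zero-variance
columns are dropped with a warning; missing cells are imputed at the
column mean after scaling (i.e., 0) and counted in the output — rows are
never discarded.  PCA reports scores, loadings and per-component R²X.
PLS-DA (scikit-learn's NIPALS PLS) relates X to a two-group indicator;
X-weights **w** rank parameter importance, Y-weights **c** describe the
response side, and separable groups land on opposite sides of the first
latent variable.  No cross-validated Q² is computed: its value depends
on the segmentation scheme of the software computing it and is not
well-defined without one.

## Synthetic cohorts

The simulator's defaults are the study conditions: 2 groups × 12 rats,
two 1800-s MCSF trials, one 300-s novel-cage and one 600-s home-cage
session per rat, frame rate 5 Hz.

* **Arena sessions** are a semi-Markov walk: per-zone exponential dwell
  times (default means 5–40 s by zone; gamma can be substituted),
  transitions drawn from weights over arena-adjacent zones, start in the
  center (where animals are released).  A habituation factor (default
  0.85 per 10-min bin) divides dwell rates and multiplies event rates,
  reproducing the qualitative within-trial activity decline that
  bin-wise analyses need.  Expected visit count follows renewal theory
  (duration / mean dwell), which the tests check at 3 SE.
* **Frame-level tracks**, when requested, place a persistent random walk
  at the profile's nominal speed inside each visited zone (rejection
  against the zone polygon minus child zones).  Dwell times are floored
  at two frame intervals so every generated visit contains at least one
  sample and extraction can recover the exact schedule up to one frame
  interval per boundary.
* **Point behaviors** are per-bin Poisson counts with habituation decay
  (defaults: rearings 2.0, SAPs 1.0, grooming 0.5, nose pokes 1.5 per
  minute).
* **Bout logs** are alternating renewals: behavior chosen with
  probability proportional to its rate, exponential bout lengths,
  exponential inter-bout gaps, so a behavior's expected relative
  frequency equals its normalized rate.  Home-cage logs of cage mates
  are generated jointly: each dominant/aggressive bout triggers, with
  configurable probability (default 0.5), a time-locked submissive
  response in the partner's log.
* The two group profiles are identical by default; differences are
  injected only through named effect multipliers applied to group 2
  (`rate:<behavior>`, `dwell:<zone>`, `speed:<zone>`,
  `transition:<zone>`, `habituation`).  Every output is a pure function
  of (config, master seed), with per-rat seeds spawned from the master
  seed.

What the simulator does **not** emulate: body posture and orientation,
wall-following and thigmotaxis, home-base return loops, inter-zone
travel time (transitions are instantaneous between frames), and any
empirical strain's parameter values.  Passing tests therefore show that
the *analysis chain* is correct and calibrated on data with known
structure — not that any biological conclusion is reproduced.

## Problem sizes and calibration checks

The recovery harness runs cohorts at the default design (12 + 12 rats,
single trial, visit-level fast path).  The suite checks type-I
calibration of the per-parameter Mann-Whitney tests and the trend-
analysis group t-tests over 1000 null cohorts (acceptance band
0.03–0.07 at α = 0.05), and power ordering over 200 cohorts with a
doubled SAP rate: the affected parameter must reject more often than
every unaffected one, with risk assessment the top category.  The
acceptance script reports the same quantities at 300/100 replicates to
keep its runtime at a few minutes on one CPU.

## Known limitations

* The default arena's corridor/DCR/hurdle/slope/bridge dimensions are
  assumptions; analyses depending on exact zone areas should supply a
  measured config.
* Visit extraction from one tracked point cannot reproduce multi-point
  tracker rules (e.g., requiring the tail base inside a zone); counts
  from such systems will differ systematically.
* The mixed ANOVA requires complete group × trial data per rat;
  unbalanced rats are dropped, not modeled.
* PLS-DA supports exactly two groups.
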