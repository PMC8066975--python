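# Methods

## Event model and frame semantics

The raw capture of a trial is an ordered stream of pointer events
(`down`, `move`, `up`) with integer millisecond timestamps (t = 0 at the
start signal) and pixel coordinates, origin top-left, y downward. Per
pointer lifetime the phase grammar is exactly `down (move)* up`; pointer
ids may be reused after `up`. Validation rejects any stream violating
the grammar, unsorted timestamps, or coordinates outside the device's
screen bounds. Pixel densities are per axis and mandatory inputs — the
package never assumes a display density.

Scoring treats positions as piecewise-constant between events: a pointer
is "in contact" on its closed interval [t_down, t_up], and its position
at time t is its most recent coordinate at or before t. Extrema
(pincer distance, hull area) are therefore evaluated exactly by visiting
every event timestamp; all events sharing a timestamp are applied before
the frame is read, and a pointer lifting at t is still part of the frame
at t. This makes every scorer a pure, order-stable function of the
stream: re-serialising simultaneous events cannot change a score.

## Scorers and their parameters

* **Tapping** (`tap_window_s` = 10 s): taps are counted on `down` events
  with 0 ≤ t < window. Counting on `down` (not `up`) matches capacitive
  hardware semantics and makes window-edge behaviour unambiguous.
* **Isolated-finger tapping** (`spot_radius_cm` = 1.25,
  `required_resting_contacts` = 4): a down counts iff it lands within
  the spot radius of the calibrated centre and, at that instant, at
  least 4 *other* pointers are in contact. The protocol does not state
  the spot size; 1.25 cm is a plausible touch-target radius and is
  configurable. The resting-contact requirement is 4 under a strict
  reading of "all other digits in contact", but configurable because
  capacitive panels merge adjacent fingertips.
* **Pincer grasp**: over every instant with *exactly two* concurrent
  contacts, the Euclidean distance between the two positions; the
  outcome is (max, min). Frames with any other contact count (palm or
  nail touches) are excluded rather than failing the trial; a trial with
  no two-contact instant at all is unscorable — an error distinct from
  a zero distance. The subtest is untimed; the trial ends with the
  stream.
* **Hand opening/closing** (`min_area_contacts` = 3): over every instant
  with ≥3 concurrent contacts, the convex-hull area of the contact
  points; outcome (max, min). The hull — rather than the
  contact-ordered polygon — is used because it is invariant to hardware
  pointer reordering; degenerate (collinear) frames measure 0 cm²
  rather than erroring, since a fully closed hand can produce
  near-collinear contacts.
* **Graphomotricity** (`grapho_resample_n` = 200): both trace and
  template are resampled to n points equally spaced by arc length, and
  the dissimilarity is ½[Σ d(traceᵢ, template) + Σ d(templateⱼ, trace)]
  with point-to-polyline (segment, not vertex) distances, in cm. This
  is a symmetric premetric on curves: non-negative, zero on identity,
  and invariant under simultaneous rigid motion. For a straight template
  translated perpendicularly by d, the score is exactly n·d, which fixes
  the scale interpretation: scores are n times the average
  point-to-curve deviation. n is configurable and recorded with the
  config; published scores for this family of assessments are of the
  order of tens of cm, consistent with n = 200 and deviations of a few
  millimetres.
* **Oculo-manual coordination** (`target_radius_cm` = 1.0,
  `oculo_timeout_s` = 120): 32 targets on a 4×8 grid, acquirable in any
  order; a target is acquired by the first down within its radius, and
  the outcome is the time of the down that acquires the last distinct
  target, in seconds. If the stream (or the timeout) ends with targets
  unacquired, the scorer raises an incomplete-trial error reporting how
  many were acquired. The three conditions (finger, pen, pen with
  drop-and-grasp) differ only in exercise id; the outcome definition is
  identical.

Template figures ("M", "3", "S", spiral) are generated programmatically
as smooth polylines of screen size; the exact proportions of the
original figures are unknown, and scoring treats templates purely as
inputs, so any template set in the same CSV dialect can be substituted.

## Psychometric battery

**ICC(2,1)** uses the two-way ANOVA without replication (rows =
participants, columns = sessions/raters):

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

with the p-value from the row-effect F = MSR/MSE on (n−1, (n−1)(k−1))
degrees of freedom (the significance test behind reliability tables is
rarely named; the row-effect F is the standard choice). Zero total
variance, and the degenerate case of a vanishing denominator, raise an
undefined-statistic error rather than returning a number.

**SEM** = SD·√(1−ICC), with the SD taken over the pooled scores of the
intra-rater session pair (n−1 denominator). Which SD feeds the SEM is
a genuine convention choice (baseline, pooled, or subsample SDs all
appear in the literature); pooled-pair is used here and recorded in the
report metadata so alternates can be swapped. **MDC95** = 1.96·√2·SEM;
every emitted report enforces this identity internally.

By protocol, three sessions are recorded: two by rater A (intra-rater
pair, sessions 1–2) and one by rater B (session 3). The inter-rater ICC
pairs session 1 with session 3; which of rater A's sessions to pair is
unstated in such protocols, and the first was chosen.

**Convergent validity** is Pearson r with two-sided p. Band boundaries
are half-open downward (exactly 0.8 is "strong") because the verbal
definitions ("greater than 0.8", "0.6 to 0.8") are ambiguous at shared
endpoints; bands apply to |r| since validity coefficients against
time-scored instruments are legitimately negative. The validity matrix
flags |r| > 0.4 (moderate or stronger) and marks pairs with fewer than
3 shared observations unavailable rather than erroring.

**Outliers**: cells with |z| > 3 per measure are removed (two-sided — the
conservative reading of a "three SDs" rule), and participants flagged in
more than two measures are dropped entirely. Zero-SD measures are
skipped with a warning. z-scores use the measure's own mean and n−1 SD
including the candidate outlier.

**Severity**: FMA-UE 19–46 is moderate and ≥47 mild. A literal reading
of "between 19 and 46" vs "higher than 47" leaves 47 unassigned; 47 is
classified mild for contiguity. Scores below 19 (severe impairment)
are outside the population this battery targets and raise. Group
comparison is the two-sided equal-variance Student's t
(df = n₁+n₂−2); Welch's correction is available behind a flag, off by
default, because the equal-variance form is what "Student's t-test"
names.

## Simulator

The simulator exists because no raw assessment streams are publicly
available; it generates data with exactly the statistical structure the
scorers and statistics assume, which defines both the power and the
limits of what the test suite shows.

**Streams.** Each session draws its primary outcome from the configured
profile — normal with the group's (mean, SD), truncated at the physical
bound by resampling — and then constructs a deterministic event stream
that scores to that value exactly: tap trains of evenly spaced down/up
pairs, a two-contact radial trajectory attaining the drawn pincer
extrema, a five-contact regular-pentagon cycle whose circumradius is set
from the drawn areas, a template traversal with i.i.d. per-vertex
Gaussian jitter (`trace_jitter_cm`: 0.15 cm mild, 0.30 cm moderate —
chosen as plausible tremor scales; the graphomotricity outcome has no
published per-group generating parameter, so stream-level checks for it
are the exact zero-jitter identity and monotonicity in jitter), and a
uniform-rate sweep of the 32 targets completing at the drawn time. The
outcome variate is the *first* draw of the per-session RNG, so sessions
sharing a seed share it across exercises (common random numbers). All
streams pass full grammar validation by construction, verified by fuzz.

**Profiles.** The default mild/moderate profiles are the published
group summaries for this assessment family (counts per 10-s window,
pincer extrema in cm, areas in cm², completion times in s), including
the cohort sizes 69 mild / 19 moderate used in severity-pattern checks.
Group FMA-UE scores are integer-uniform within each group's range (only
group-level summaries are published; uniform is the least-informative
choice and is configurable).

**Cohorts.** Outcome-level tables draw each participant's value from
the group profile; with repeated sessions, values follow the two-way
model y_ij = μ + p_i + e_ij with participant variance ρσ² and residual
(1−ρ)σ² (default ρ = 0.85). Clinical columns are built as
ρ·standardised(anchor) + √(1−ρ²)·noise, so the induced outcome–clinical
correlation is controlled. Reliability matrices follow
y_ij = μ + p_i + s_j + e_ij with explicit variance components;
theoretical ICC(2,1) = σ²_p/(σ²_p+σ²_s+σ²_e).

**What the simulator does not model**: anatomical hand kinematics,
learning/fatigue across sessions, heteroscedastic or skewed outcome
distributions, merged-contact artefacts, nail contact, or missing data.
Passing tests therefore demonstrate correctness of the scoring and
statistical machinery under the stated model, not clinical validity on
real patients.

## Numerical choices and problem sizes

* Geometry is exact floating-point: hulls and point-segment distances
  via computational-geometry routines, verified against brute-force
  oracles (hull-vertex construction by triangle containment; dense
  arc-length sampling) at 1e-9 / 1e-3.
* ICC agrees with a pure-Python sum-of-squares oracle to 1e-12 across
  all shapes up to 6×4 with small integer entries.
* Monte-Carlo checks use 500 sessions per exercise, 200 replicates for
  ICC recovery (±0.05 band around 0.9), and 500 simulated cohorts for
  the severity pattern (≥90% significance-rate bands) — sizes at which
  the sampling error of each check is several times smaller than its
  tolerance band. End-to-end mean-recovery checks compare against the
  analytic truncated-normal mean implied by the generator, with a
  2-standard-error band. All seeds are explicit; there is no global
  random state.

## Known limitations

* The original estimators for hand area and trace dissimilarity are not
  publicly documented; the convex hull and the symmetric resampled
  nearest-neighbour metric are this package's own definitions, flagged
  as such. In particular, published hand-*closing* areas (~2.5 cm²)
  are small relative to opening areas (~95 cm²) in a way that may
  reflect an undocumented normalisation; none is applied here.
* A priori sample-size computation for validity studies is out of
  scope.
* The CLI scores one session per invocation (batch behaviour via
  `--append`); very large batch orchestration is left to the caller.
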