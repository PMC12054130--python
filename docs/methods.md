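# Methods

## The measurement and its model

A cover-test trial records horizontal gaze of both eyes at 30 Hz over a
window spanning 10 s before to 10 s after occlusion onset (t = 0,
pre-onset negative). The signed deviation signal is the difference between
the two eyes' gaze, oriented so that exodeviation (temporal excursion of
the covered eye) is negative whichever eye is covered: with gaze positive
rightward, the deviation is `covered − fixating` for a covered left eye and
`fixating − covered` for a covered right eye. Traces store absolute gaze
per eye; the deviation definition and its sign handling live in one place
(`fitting.deviation_signal`).

The deviation is modelled as a four-parameter logistic

    f(t) = L0 + a / (1 + exp(−k (t − t0)))

with pre-occlusion level `L0` (deg), asymptote difference `a` (deg, the
deviation angle), steepness `k` (1/s, bounded to (0.01, 200]) and midpoint
`t0` (s). This is the minimal smooth form with two asymptotes; asymmetric
sigmoids (Richards etc.) are out of scope. Derived statistics:

- **Peak deviation speed** `b = |a|·k/4` — the maximum absolute slope of
  the logistic, attained at `t0`.
- **Stabilization time** `t* = t0 + ln(9)/k` — the first time after onset
  at which `|f(t) − L0| ≥ 0.9·|a|`, measured from occlusion onset. If the
  midpoint lies far enough before onset that the 90% level is already
  exceeded at t = 0, the function returns 0 with a warning.
- **Overshoot depth** — see below.

## Fitting

Nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective) on the non-missing samples inside the window; missing (blink)
samples are excluded from the loss, never interpolated, and at least 8
usable samples are required on each side of onset. Initialization is taken
from the data: `L0` from the pre-onset median, `a` from the median of the
last quarter of the window minus `L0`, `t0` from the first crossing of the
half level on a 3-sample median-smoothed signal, and `k = 2·ln3 / (t₇₅ −
t₂₅)` from the quartile-crossing interval. Tolerances are tight
(`1e−14`), so noise-free model data are recovered to well below `1e−6` in
every parameter. A fit is flagged non-converged when the optimizer fails
or ends on a steepness bound.

A fitted amplitude that is not clearly above the noise — `|a| < 2·rmse`,
or `|a|` below twice its own standard error from the Jacobian at the
optimum — sets a `small_deviation` flag and issues a warning. The second
condition matters on near-flat traces, where the optimizer can chase a
noise lump into a spurious step of ~3·rmse with an essentially
unidentified amplitude.

## Overshoot depth

A symmetric logistic is monotone and cannot overshoot, so the transient is
measured on the data: the maximum deviation `d` is the most extreme
post-onset value of the 3-sample running-median-smoothed deviation signal
in the direction of `a`, and the depth is how far it goes beyond the final
position, `max(0, |d − L0| − |a|)`, with depth 0 for a monotone approach.
Depth is measured relative to the far asymptote (the final position), not
the baseline.

Estimating the final position needs care: a least-squares logistic leans
its asymptote *into* the transient (a 1.2° transient on a −6° trace pulls
the fitted `a` by ≈ 0.3° and would be measured as ≈ 0.8°). The final
position is therefore re-estimated from the late tail of the record, where
the transient has decayed: the median of `(y − L0)/σ̂(t)` over the last
quarter of the window (restricted to `σ̂ ≥ 0.5`), where `σ̂` is the fitted
logistic's completed fraction. Dividing by `σ̂` undoes whatever part of
the approach is still outstanding, so the estimate is exact for slow
monotone approaches (where a plain tail median would fabricate depth) and
transient-robust for fast ones. When the tail is uninformative (midpoint
near the window end) it falls back to the fitted `a`.

Categories follow the clinical bands: `gt1` (> 1°), `mid` (0.5–1.0°),
`lt0p5` (< 0.5°), applied to the floored depth.

**Noise floor.** Depth is an extreme-value statistic: with 0.2° per-eye
noise at 30 Hz over a 10 s window, pure-noise traces show a median depth
of ≈ 0.45° (3-sample median smoothing attenuates but does not remove
single-trial extremes). Measured depths below ~0.5° are therefore not
evidence of a real transient; the category boundary at 0.5° coincides
with this floor.

## Rebound-saccade detection

Tropic refixation is saccadic and can overshoot, followed by a corrective
saccade in the opposite direction (rebound-saccade). The detector runs on
the refixating eye's median-smoothed finite-difference velocity after
onset: flag true iff speed first exceeds a threshold (default 30°/s,
configurable) in one direction and subsequently exceeds it in the opposite
direction within 1 s. Phoric drifts (peak speeds of a few deg/s) never
reach the threshold. The model-free maximum finite-difference speed of the
deviation signal is also reported (`raw_peak_speed_deg_s`) as the
companion to the fitted `b`: for saccadic refixations the fitted logistic
under-resolves the true peak velocity at 30 Hz, while for noise-only
traces this raw statistic has a floor of roughly 20°/s and should be read
as an upper bound, not an estimate.

## Units and cohort statistics

Prism-diopter conversion uses the exact orthoptic definition
`PD = 100·tan θ` (domain |θ| < 90°) and its inverse; the small-angle
approximation is not used. Group conversions are computed per subject and
then averaged — converting a group-mean angle instead differs visibly
(e.g. a mean of per-subject conversions can be −13.1 PD where
`100·tan(mean)` gives −13.0).

Spearman rank correlation uses average ranks for ties. The two-sided
p-value is exact — full enumeration of the permutation null — whenever the
sample is small enough and untied: automatically for n ≤ 9, and via an
opt-in `exact_s` method up to n = 13, which the cohort summary uses since
the target cohorts have 13 phoric subjects. The exact null distribution of
`T = Σ i·R_i` (affinely related to `S = Σ dᵢ²` and `r_s`) is computed by
subset dynamic programming over rank assignments (2ⁿ × Σi² table, ~0.4 s
at n = 13, cached). For reference, at n = 13 and S = 576 (r_s ≈ −0.582)
the exact two-sided p is 0.0402; base R's `cor.test(exact=TRUE)` reports
0.0403 there because it switches to an Edgeworth series above n = 9, an
error of ~6·10⁻⁵. Larger or tied samples use the usual
`t = r_s·√((n−2)/(1−r_s²))` approximation on n − 2 df; the method used is
recorded in the result. All tests are two-sided; no multiple-testing
correction is applied.

The device-vs-APCT comparison is a paired t-test on APCT minus the device
deviation converted to PD, over all subjects; zero-variance differences
raise a degenerate-test error.

## The simulator

The simulator provides ground-truth-annotated data with the statistical
structure the analysis assumes; it is the forward model of the fit plus
the features the fit must be robust to.

**Phoric traces.** Covered eye = `baseline + a·σ(k(t − t0))` + optional
overshoot transient + i.i.d. Gaussian noise; fixating eye = zero-mean
noise; blink dropouts are explicit missing markers (never zeros, which
would corrupt fits silently). Defaults: a = −6°, k = 2/s, t0 = 1.5 s,
noise 0.2°, 30 Hz, ±10 s. The noise SD and blink probability of real VOG
hardware are not published for this class of device; 0.2° and a 0–few %
blink rate are stipulated as realistic for pupil/corneal-reflex trackers.

**Overshoot transient.** Additive pulse `sign(a)·c·x·e^(1−x)` with
`x = (t − t0)/τ` (smooth, single extremum, decay constant τ = 1 s
default). The coefficient `c` is calibrated numerically (bisection on a
dense grid) so that the realized excursion beyond the asymptote equals the
nominal amplitude exactly — the raw pulse rides on a logistic that has not
yet saturated, so an uncalibrated coefficient would understate the true
depth. Ground truth `overshoot_depth_deg` is therefore the nominal
amplitude.

**Tropic traces.** Before onset the fellow eye sits at the manifest
deviation and the to-be-covered eye fixates; at onset (after a 0.1 s
latency) the fellow eye refixates with a raised-cosine velocity profile
whose peak speed matches the requested value (duration `2·|A|/v_peak`),
overshoots by the rebound amplitude and corrects back; the covered eye
moves conjugately while the deviation transitions smoothly (rebased
logistic, zero before onset) to its fusion-free value. Saccades too fast
to be represented at the sampling rate trigger a warning but are still
emitted. The raised-cosine profile is smooth, bounded and gives
finite-difference peak speeds within a few percent of nominal at 30 Hz.

**Cohorts.** Deviation amplitudes uniform over 2–10° (exodeviation), with
the logistic rate coupled to amplitude, `k = 2.7·(|a|/6)^1.5` with
log-normal scatter (σ = 0.25), so peak speed rises and stabilization time
falls with deviation magnitude — the coupling exponent and reference rate
were chosen so a 13-subject cohort lands near the reported phoric ranges
(speeds of order 1–15°/s, stabilization ≈ 2–4 s). Midpoints are
N(2.0, 0.3) s clipped to [0.5, 4]. Overshoot amplitude is proportional to
peak speed with log-normal scatter, scaled so about 7/13 of subjects
exceed 0.5°, and clipped to the phoric transient range 0–1.5°. The APCT
value is the device angle converted to PD plus a systematic offset
(default +4.45 PD, i.e. the clinical test reads less exotropic than the
device — near targets induce convergence) plus N(0, 2 PD) noise. All
randomness flows from one explicit seed per call; per-subject trace seeds
are drawn from the cohort seed.

**What the simulator does not emulate.** Pupil-size changes, vertical or
torsional components, calibration drift, head movement, asymmetric or
multi-stage drifts, and serially correlated noise. Passing recovery tests
show the estimator is correct *under the model and white measurement
noise*; they do not certify behavior on pathologies outside it.

## Problem sizes and tolerances

Test ensembles are sized for tight statistical checks at interactive
runtimes: 50-point noise-free recovery grids (tolerance 1e−6), 200-trace
noisy ensembles (bias tolerances 0.1° / 0.1 s), 100-seed cohort
sign-pattern checks (≥ 95/100), 100-vector brute-force cross-checks of the
exact permutation p (equality to 1e−12), and a 10,000-draw null
calibration of the exact test at n = 13 (rejection 5% ± 1%; the exact
attainable level there is 0.0499). Numerical tie-breaks: the exact-p
comparison uses a 1e−9 slack on the rank-statistic deviation so floating
ranks cannot flip a boundary permutation; category bounds follow the
strict/inclusive pattern > 1°, [0.5°, 1.0°], < 0.5°.

## Known limitations

- The logistic's `b = |a|k/4` understates saccadic refixation speed at
  30 Hz; use the raw finite-difference speed for tropic cases.
- Overshoot depth inherits an extreme-value noise floor (~0.45° median at
  0.2° noise); per-trial depths below 0.5° are not individually meaningful.
- The exact permutation test is capped at n = 13 by the 2ⁿ dynamic
  program; larger cohorts fall back to the t approximation.
- The trace CSV dialect is this package's own; no native eye-tracker
  export formats are parsed.
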