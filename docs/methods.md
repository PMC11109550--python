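# Methods

## The experiment being analysed

A fly tethered to a torque meter generates yaw torque around its
vertical body axis. The torque's sign partitions behaviour into two
*domains*: negative = left-turning, positive = right-turning
maneuvers. In an operant self-learning experiment, training periods
make heat (an infrared laser) contingent on one domain — heat is on
exactly while the torque is in the punished domain, with no
hysteresis — and test periods without heat measure whether the fly
keeps avoiding that domain. Two protocols are supported: the 9-period
Tang protocol (pretest ×2, training ×2, test, training ×2, test ×2,
all 120 s; learning score = PI of period 8) and the 17-period protocol
of the newer devices, which adds four 30-s optomotor periods before
and after the same nine torque periods (learning score = PI of period
12). In both cases the learning score is the performance index of the
first test period after the last training period.

The punished domain alternates between consecutive experiments, so
any device- or population-level turning bias cancels across a group.

## Performance index

For each torque period, PI = (ta − tb)/(ta + tb), where tb is time
punished and ta time unpunished. During training, tb is read off the
recorded heat flag (so any device latency present in real data is
honoured); during pretests and tests, tb is the dwell time in the
(to-be- or formerly) punished domain, obtained by segmenting the
trace at every torque sign change. Segmentation assigns each sample
the half-open window [t, t + step), so interval durations equal
per-sample counts times the step exactly, and ta + tb equals the
period duration to within one sample.

Boundary rule for torque exactly zero at a sample: the sample
inherits the previous sample's domain; a leading zero-run inherits
the first nonzero sample's domain; if an entire period is zero the PI
is undefined and the period is flagged (the fly was not flying). The
measure-zero boundary has no principled assignment; inheritance keeps
segmentation antisymmetric under sign flips.

## Synthetic fly

The generator is a two-state semi-Markov domain process with
exponential dwell times:

* `baseline_switch_rate` (default 0.5 Hz): hazard of crossing zero
  torque. Spontaneous dwell times of a couple of seconds are typical
  of tethered flight, and give roughly 60 domain switches per 120-s
  period.
* `heat_escape_factor` (default 5, ≥ 1): multiplies the hazard of
  leaving the punished domain while heat is on (escape behaviour
  during training).
* `learned_bias` b ∈ [0, 1) (default 0): from the first training
  period onward — with no forgetting, since the scored test
  immediately follows training — the hazard of leaving the unpunished
  domain is multiplied by (1 − b) and of leaving the punished domain
  by (1 + b). The stationary unpunished dwell fraction is then
  (1 + b)/2, so the **expected test-period PI equals b**, and a 3:1
  dwell ratio corresponds to b = 0.5 and expected PI 0.5
  (`learned_bias_for_dwell_ratio`).
* Within a domain, torque = domain sign × `torque_scale` (default
  3 a.u.) plus AR(1) noise (`torque_noise_sd` default 0.5 a.u.,
  correlation time 0.2 s), clipped at 5 % of the scale so torque
  never crosses zero except at switch events.
* Optomotor periods follow a first-order saturating exponential
  toward ±gain (`om_gain_cw`/`om_gain_ccw`, default 3 a.u.;
  `om_tau_s` default 3 s) plus the same noise. After training the
  punished-side gain is multiplied by (1 − `om_coupling` · b). Gains
  may be set negative to model a direction-incongruent ("shifted")
  response.
* Sampling: 20 Hz by default; any uniform rate is accepted on input.

One known, intended consequence of escape behaviour: a fly with
b = 0 but `heat_escape_factor` > 1 starts each test period more
often in the unpunished domain and relaxes to symmetry with time
constant 1/(2·rate) ≈ 1 s, contributing a mean PI of about +0.005.
This carryover is an escape artefact, not learning, and is small
enough that the joint verdict's type-I rate stays within its bound
(measured ≈ 0.4 % over 500 null cohorts of n = 30).

What the generator does **not** emulate: saccadic torque spikes,
slow drift of the torque baseline, torque-magnitude (as opposed to
dwell-time) learning, device-specific noise spectra, and any
within-period non-stationarity of the switching rate. Passing tests
therefore demonstrate the pipeline's correctness under the stated
dwell-process assumptions, not robustness to every artefact of real
traces.

## Optomotor fitting

Each 30-s optomotor period is fitted separately per rotation
direction.

**Model selection.** A least-squares line is fitted first; the
double-sigmoidal model is selected iff the line's slope is
significantly nonzero (|t| > 3) *and* the implied total rise over the
window exceeds 20 % of the trace's interquartile range. An earlier
candidate rule — comparing the rise against 3× the line's residual
standard deviation — was rejected: a saturating rise inflates the
line's residuals, so that rule fails to detect exactly the responses
it is meant to catch once realistic noise is added. The slope
t-statistic is scale-free and keeps the classification stable across
noise seeds for both flat and rising traces.

**Double-sigmoidal model.** f(t) = B + A·σ(k₁(t−t₁))·[1 − (1−r)·σ(k₂(t−t₂))]
with σ the logistic function, k₁, k₂ > 0, t₂ = t₁ + Δ ≥ t₁, r ∈ [0, 1];
the optomotor magnitude is the late-time asymptote B + A·r. Fitting
is trust-region nonlinear least squares with analytic Jacobian and
eight deterministic multi-starts over onset time, steepness and decay
fraction; starts stop early once two consecutive starts fail to
improve the best cost by 0.1 %. The trace is normalised by its span
before fitting, which makes the procedure exactly scale- and
sign-equivariant up to floating-point rounding (verified to ~1e-5
relative). If no start converges, the line fit is returned with a
fallback flag. Lines report the fitted value at the window midpoint
as the magnitude — a literal t = 0 intercept would depend on an
arbitrary time origin for a near-flat response.

**Asymmetry index.** Per phase (before/after training), the two
clockwise periods' magnitudes are rectified to their
direction-congruent sign and averaged (right magnitude R), likewise
the counterclockwise ones (left magnitude L); a wrong-signed response
contributes 0 to its own direction, producing the boundary indices ±1
when one direction's response is absent or inverted. The raw index is
(R − L)/(R + L), undefined when both magnitudes are zero (the fly is
flagged as having no optomotor response). The adjusted index flips
the sign for flies punished on the right, so positive always means
"shifted toward the unpunished domain".

## Quality control

Four exclusion rules, applied per fly; exclusion never removes data
from the dataset, it only drops the fly from group statistics:

1. **laser_lethality** — post-experiment laser survival ≥ 15 s
   (boundary inclusive) fails; missing survival metadata fails
   conservatively, since the exposure test is part of the protocol.
2. **omr_presence** — fails when both before-training magnitudes fall
   below a noise floor (default 10 % of the global torque standard
   deviation) or when the response is "shifted": both directions'
   signed magnitudes share a sign, or the pre-training |raw
   asymmetry| exceeds 0.8. The quantitative definitions of "shifted"
   and the floor are declared defaults, configurable per dataset.
3. **laser_experience** — fails when the heat flag is never true
   during any training period; heat outside training additionally
   raises a corrupt-data warning.
4. **flight_performance** — flight stops are maximal runs of 1-s
   sliding windows whose torque standard deviation is below 1 % of
   the trace's global standard deviation; the rule fails at ≥ 5 stops
   or > 10 % of torque-period time stopped. These thresholds are
   declared defaults for an unquantified criterion ("constant
   stopping of flight").

## Statistics

* **Wilcoxon signed-rank vs zero**, two-sided; exact zeros dropped;
  exact enumeration for n ≤ 25 without tied absolute values, normal
  approximation with continuity correction and average ranks
  otherwise.
* **JZS Bayes factor** BF₁₀ vs zero, Cauchy prior scale √2/2 on the
  standardised effect, computed by adaptive quadrature over the
  g-mixture representation (tolerance 1e-8); cross-checked in the
  test suite against an independent implementation (pingouin) to
  ~1e-6 relative. The two-sample version uses the pooled t statistic
  with effective sample size n₁n₂/(n₁+n₂).
* **Verdict**: *intact* iff p < α (default 0.005) and BF₁₀ >
  bf_upper (default 5); *impaired* iff p > 0.05 and BF₁₀ < bf_lower
  (default 1); otherwise *inconclusive*. The 0.05 bound of the
  impaired rule is fixed; α and the BF thresholds come from the
  dataset descriptor. No multiple-testing correction is applied
  across groups — each group is tested against zero independently
  and all p-values and Bayes factors are reported verbatim.
* **Group comparison**: two-sided Mann–Whitney U plus the two-sample
  JZS Bayes factor. **Preference–asymmetry relation**: OLS of the
  adjusted after-training asymmetry on the learning PI.

## Problem sizes used in the test suite

Calibration checks run at the sizes the analyses are designed for:
verdict calibration uses 500 null cohorts and 200 effect cohorts of
n = 30 flies on the 9-period protocol (whose torque periods, and
hence learning scores, are identical to the newer protocol's);
dwell-ratio recovery uses 200 flies; optomotor recovery uses a
100-fly cohort with a 30 % punished-side reduction, and the
preference–asymmetry regression a 50-fly cohort with heterogeneous
learned bias (with a common bias, per-fly PI and asymmetry
fluctuations are independent and the true slope is zero — the
regression contract only holds across flies that differ in how much
they learned).

## Known limitations

* The reader for this package's own XML dialect does not parse the
  originally deposited raw-data schema; an adapter would need to be
  validated against an actual deposited file.
* The double-sigmoidal asymptote is ill-determined if a response has
  not begun to saturate within the 30-s window (rise time ≫ 5 s);
  the fit then degrades gracefully toward the line fallback.
* Bayes factors are reported for the default JZS prior only;
  sensitivity analyses over prior scales are out of scope.
* With very low switch rates (≪ 0.1 Hz) a 120-s period may contain a
  single dwell, making per-fly PIs bimodal at ±1; group statistics
  remain valid but the PI distribution is then far from normal,
  which is why rank-based tests are the default.
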