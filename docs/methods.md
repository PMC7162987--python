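# Methods

This note records the scientific model behind `vibropsych`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish.

## The battery

Eleven paradigms are parameterized exactly as administered by the standard
flutter-range battery, each in a short version and a long version with twice
the trials: simple/choice reaction time (25 Hz, 300 μm, 40 ms probes, ITI
3 s, 20/40 trials), static detection threshold (start 20 μm, 500 ms, ITI
5 s, 24/48 trials), dynamic detection threshold (2 μm/s ramp after a 0–2.5 s
delay, ITI 10 s, 7/14 trials), amplitude discrimination without/with
dual-/single-site adaptation (100 μm standard, comparison starting 200 μm,
1-s 100-μm adaptors, 20/40 trials), sequential/simultaneous frequency
discrimination (30 Hz standard, comparison starting 40 Hz, 200 μm, 500 ms,
20/40 trials), and temporal order judgement without/with a 25-Hz 20-μm
carrier (two 40-ms 200-μm pulses, starting ISI 150 ms, 20/40 trials). The
long no-adaptation amplitude-discrimination task starts the comparison at
300 μm (a known administration anomaly, kept as the default so simulated
long runs share its larger tracking range).

Two battery-level choices are not published and are exposed as
configuration:

* **Step size.** The tracking software's step schedule is proprietary. We
  default to 10% of the initial tracked value (sDT 2 μm; AD 10 μm, 20 μm
  for the long nAD; FD 1 Hz; TOJ 15 ms), which gives at least ten descending
  steps before the floor and resolution comparable to typical adult
  thresholds. **Floor** is one step: the tracked value never reaches zero,
  where a 2AFC trial would be undefined.
* **Tracked scale.** Amplitude- and frequency-discrimination thresholds are
  the comparison-minus-standard *difference*. Reported adult AD means
  (~20–50 μm) and FD means (~7 Hz) sit far below the standards (100 μm,
  30 Hz), so the difference scale is the only consistent reading; a config
  override can shift it.

Session plans assign Short(1), Short(2) and Long to the three sessions in a
uniformly random order per subject; the task order within a session is
fixed.

## Staircase and estimators

Tracking is one-up/one-down for the first 10 trials and two-up/one-down
afterwards; the 2u1d rule converges on the 2^(−1/2) ≈ 70.7%-correct point.
Thresholds are the mean of the levels *presented* on the final five trials.
We fix the presented-level convention (rather than including post-update
levels) because those are the trials actually used to estimate thresholds;
the real software's convention is not recoverable from published sources.
The convergence score is the number of correct responses among the same
final five trials (tracked tasks only; the ramping dynamic-detection task
has no staircase). Reaction-time summaries are the median (correct trials
only for choice RT) and, after MAD screening at 2.5 within the trial set,
the standard deviation (ISV). Dynamic detection is the mean amplitude at
the button press over correct trials, deliberately uncorrected for reaction
time. Truncation keeps the *first* n_short trials in presentation order and
recomputes every measure, mimicking a short administration embedded in a
long run. All-incorrect dynamic-detection runs raise an
insufficient-data error (no published handling exists).

## Simulated observers

The observer model is deliberately minimal: a latent threshold per domain,
a Weibull-family 2AFC psychometric function

    P(correct | d) = 1/2 + (1/2 − λ)(1 − c^((d/θ)^β)),
    c = 1 − (2^(−1/2) − 1/2)/(1/2 − λ),

calibrated so that P(correct | θ) = 2^(−1/2) for any lapse rate λ, making
the 2u1d staircase converge to θ by construction (a log-logistic family is
available as an alternative). Task variants act multiplicatively on the
effective difference: g_dual > 1 (dual-site adaptation sharpens
discrimination), g_single < 1, a simultaneous-FD gain slightly below 1, and
a TOJ carrier gain below 1. Reaction times are log-normal (positive skew)
with a fixed decision-time increment for choice RT; the dynamic threshold
adds ramp × motor-delay to the felt amplitude and Gaussian trial-to-trial
noise.

The default population calibration places group means near commonly
reported adult values — θ_sDT ≈ 5.1 μm, dDT ≈ 8.3 μm (θ_dDT 7.9 μm + 2 μm/s
× 0.2 s), θ_AD ≈ 34 μm with g_dual ≈ 34/22 and g_single ≈ 34/50, θ_FD ≈
6.9 Hz, θ_TOJ ≈ 24 ms with carrier gain ≈ 24/35 — so the canonical effect
directions (dDT > sDT; sAD > nAD > dAD; TOJc > TOJs) follow from the gains
rather than from fitting any human dataset. Between-subject SDs and
per-session multiplicative jitter CVs (thresholds ~10–28%, RT ~9% on the
log-median) were chosen once to put between- and within-subject CVs in the
ranges reported for these measures; the staircase itself contributes
estimation noise on top of the latent jitter. One reported human effect the
default generator does *not* reproduce is a version effect on the plain
temporal-order task (shorter thresholds in the long version): no mechanism
for it is established, so we document rather than emulate it.

## Measure-level generator

For validating the reliability statistics directly, matrices are generated
as entry(i,j) = μ + b_i + c_j + e_ij with b_i ~ N(0, σ_b²), fixed session
offsets c_j, and e_ij ~ N(0, σ_w²), where σ_w = CV_ws/100 × grand mean,
σ_b² = (mean per-session variance) − σ_w² (clamped at zero with a warning),
and c_j = session mean − grand mean. Draws are clamped strictly positive;
at the default parameter ranges the clamp is hit with probability < 1%, so
moment distortion is negligible. Under this model the population value of
the average-measures absolute-agreement ICC is
σ_b² / (σ_b² + (σ_c² + σ_w²)/k), which the test suite recovers by
simulation.

## Reliability statistics

Outliers are screened per measure with the MAD rule (|x − median| >
2.5 × 1.4826 × MAD), collapsing all sessions to estimate dispersion; a zero
MAD flags nothing. Screening removes individual measurements, not subjects:
CVs use all remaining data, while the ICC drops subjects with an incomplete
row. The ICC is McGraw & Wong's ICC(A,k) computed directly from the two-way
ANOVA mean squares — equivalent to the two-way mixed-effects
absolute-agreement average-measures form, without iterative fitting.
Negative estimates are clamped to zero for reporting and kept raw in the
results (small negative estimates legitimately occur at low reliability).
Sample (n−1) standard deviations are used throughout. Matrix columns are
battery versions (Short1/Short2/Long) by default, matching how the
descriptive tables are laid out; chronological sessions are a switch, and
the ICC can be restricted to a column subset (e.g. the two short
administrations, k = 2). Bland–Altman agreement is tabulated as pair means
against percentage differences, 100(a−b)/mean.

## Mixed models

Version (Short1/Short2 collapsed vs Long), training (linear session index
1–3 by default; categorical coding available through the model surface) and
within-domain task effects are tested with the random-intercept LMM fitted
by maximum likelihood. ML rather than REML is used throughout, so variance
components are biased low at small n; LRT comparisons require it.
Within-domain task models carry the version indicator as a nuisance
covariate so task contrasts are version-adjusted. Post-hoc pairwise
comparisons report z statistics on the fitted level contrasts
(normal reference, matching how such contrasts are conventionally reported)
with Holm-Bonferroni step-down correction; the studentized-range reference
is deliberately not used. Effect sizes are the proportional reduction in
residual variance, clamped to [0, 1]. The numerical optimization is
delegated to statsmodels `MixedLM` (ML, default optimizer with a fallback
ladder to Powell/Nelder-Mead when a boundary variance makes the Hessian
singular; variance estimates at the boundary are accepted as zero).

## Determinism and problem sizes

Every random stream descends from a single master seed through named
spawn keys (seed, subject, session, task index), so adding a task or
subject never perturbs other streams and every artifact is bit-identical
under a fixed seed. The validation suite uses problem sizes chosen for
tight Monte-Carlo error at interactive runtimes: 500 replicate studies for
calibrated ICC reproduction, 1,000 random matrices for the ANOVA oracle,
50 × 600-trial runs for staircase convergence, 2,000 replicates for LRT
type-I calibration, and 20 full-study seeds for effect directions.

## Known limitations

* No fatigue, attention, learning or circadian structure: inter-trial and
  inter-session intervals are carried as metadata only, and session effects
  enter only through latent jitter (trial mode) or fixed offsets (measure
  mode).
* No omission/timeout model for RT tasks and no practice-trial gate.
* Digit sites are abstract labels; there is no skin-mechanics or probe
  geometry model, and site choice is uniform Bernoulli rather than a
  constrained pseudorandom sequence.
* Passing reliability checks on synthetic data validates the *statistical
  pipeline* under its assumed variance structure; it does not establish the
  reliability of any human measure.
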