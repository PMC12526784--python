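# Methods

`gaitsev` implements a complete gait-based dementia-severity analysis
pipeline around a synthetic cohort of four groups — healthy controls
(CDR 0), mild cognitive impairment (CDR 0.5), mild dementia (CDR 1) and
moderate dementia (CDR 2) — with default group sizes 54/34/25/26
(139 subjects).  This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data can and cannot show.

## Cohort model

Each subject carries demographics (age, sex, height, weight, BMI) and a
ground-truth gait parameter set.  Group-conditional distributions are
normal, calibrated to published per-group summaries: parameters reported as
median (Q1–Q3) use mean = median and SD = (Q3 − Q1)/1.349 (the normal IQR
factor); parameters reported as mean ± SD use those moments directly.
Draws are truncated to physiological bounds (e.g. velocity 0.25–2.0 m/s,
stance 52–75%).

Internal consistency is enforced by construction rather than by rejection:

* cadence (steps/min) is the primary temporal draw; cycle time = 120/cadence
  and step time = 60/cadence are derived.  The published cycle-time and
  cadence summaries are mutually inconsistent for the moderate group
  (1.6 s vs 120/83.8 = 1.43 s); cadence wins, so the moderate cycle-time
  median is deliberately not reproduced.
* walking velocity is drawn; step length = velocity × step time, clamped to
  the pendulum-geometry and walkway limits (step length < walkway/4 and
  < 1.9 × leg length, with velocity re-derived when the clamp binds).
* stance% is drawn; swing = 100 − stance.  With a half-cycle contralateral
  offset, bilateral averaging makes the initial and terminal double-support
  phases algebraically equal to stance − 50 and single support equal to
  100 − stance, so these are derived, not drawn: an independently drawn
  double-support target cannot survive left/right averaging (the
  side-specific deviations cancel exactly).
* hip/knee/ankle sagittal ROMs are drawn, then clamped to the
  waveform-feasible bands described below (binding mostly for the ankle in
  slow walkers; see Limitations).
* leg length = 0.53 × height (standard anthropometric fraction,
  configurable).

Per-subject randomness is keyed by hashing (master seed, subject id), so a
subject's draws do not depend on cohort composition or iteration order.
This is what lets single-group simulations reuse full-cohort runs verbatim.

## IMU signal synthesis

Seven sensor sites (pelvis, both thighs, shanks, feet) emit 3-axis
gyroscope (deg/s) and accelerometer (m/s²) traces at 100 Hz.  Each of the
8 trials on the 8 m walkway starts with 2 s of static standing (the
calibration window), a 0.5 s smooth walk-up ramp, then
floor(walkway / (2 × step length)) strides (minimum 2).  Trials share the
deterministic waveform and differ only in the sensor-noise realization.

Sagittal segment angles are first harmonics of the gait phase
χ = 2πt/T plus a smooth staircase on the foot:

* shank = B·sin(χ − ψs), with 2B the pendulum sweep needed so that
  step length = 2·L·sin(sweep/2) inverts exactly; ψs puts the shank maximum
  at mid-stance and minimum at mid-swing.
* foot = staircase + w₁·sin(χ − ψs).  The staircase rises by ΔA at each
  heel strike and falls by ΔA at each toe-off through Gaussian CDF steps of
  width σ (30–50 ms), so the foot angular velocity is exactly a +A pulse at
  heel strike and a −A pulse at toe-off with A = ΔA/(σ√2π) held inside the
  80–150 deg/s band — the signature the ±50 deg/s peak detector keys on.
  A small antisymmetric correction cancels the slope of the w₁ background
  at each event, so the net foot-gyro extremum falls exactly on the event
  time (without it the detected peaks shift by ≈ m·σ²/A ≈ 1 ms and bias the
  double-support phases).
* ankle = shank − foot = (B − w₁)·sin(χ − ψs) − staircase.  In the design's
  "primary regime" (ΔA ≤ (1 + cos(π·stance))·(B − w₁)) the per-cycle ankle
  range is exactly 2(B − w₁) − ΔA; the solver picks (w₁, ΔA) in closed form
  on a stair-height grid, subject to the background-slope cap
  (|w₁·ω| ≤ 38 deg/s) and an event-detectability margin (net pulse peak
  ≥ 62 deg/s after the in-phase background is subtracted).
* knee = (K/2)·sin(χ − ψk) with thigh = shank + knee curve; ψk is solved
  from the two-harmonic resultant identity so that hip = pelvis − thigh
  (pelvis flat) has range exactly H.

Angular velocities are the analytic time derivatives of these angles, and
accelerometers read the gravity projection (g·sinθ, g·cosθ) of the same
angle, so gyro integration, accelerometer inclination and the true angle
are mutually consistent — the extraction pipeline inverts the simulator to
better than 0.1% in the noiseless limit (round-trip tests).

Noise defaults: white gyro noise SD 5 deg/s, accelerometer noise SD
0.2 m/s², per-subject left/right phase asymmetry SD 0.01 cycles.  These are
invented (the source system's noise characteristics are unpublished) and
configurable; `noiseless()` zeroes them.

## Extraction pipeline

1. **Filtering** — zero-phase (forward–backward) 4th-order Butterworth
   low-pass at 20 Hz on all consumed channels.  Zero-phase is chosen
   because event timing feeds every downstream parameter.
2. **Event detection** — heel strikes are strict local maxima of the foot
   sagittal angular velocity above +50 deg/s, toe-offs strict minima below
   −50 deg/s; at most one event of each type per 0.25 s; plateaus resolve
   to the earlier sample; the weaker of any same-type adjacent pair is
   discarded to enforce alternation.  Peak times are refined to sub-sample
   precision by parabolic interpolation.
3. **Cycles** — consecutive same-side heel strikes containing exactly one
   toe-off; contralateral events inside the window are attached for the
   double-support phases.
4. **Kinematics** — a complementary filter
   θ_t = α(θ_{t−1} + trapezoidal gyro increment) + (1 − α)·θ_accel
   per segment (α = 0.98 at 100 Hz, standard practice), initialised and
   referenced on the static calibration window (0.25–1.75 s).  Joint angles
   are proximal-minus-distal differences re-zeroed to standing; ROM is the
   per-cycle max − min.  Flexion is positive for hip and knee, dorsiflexion
   positive for the ankle.  The published "joint angle" summaries are
   interpreted as sagittal ROM; per-cycle maximum flexion is computed as
   well so either reading is available.
5. **Step length** — pendulum inversion 2·L·sin(sweep/2) from the per-cycle
   shank sweep (the study gives no estimator; this choice is
   inverse-consistent with the simulator).
6. **Features** — the 11 parameters (cycle time; stance/swing %; velocity;
   cadence; initial/single/terminal support %; hip/knee/ankle ROM) are
   subject-level means over all valid cycles pooled across trials and sides
   (medians by flag).  Cadence × step time = 60 exactly by construction.

## Feature ranking and models

* **ReliefF** (Kononenko's multiclass form): k = 10 neighbours, all
  instances scored, Manhattan distance on range-normalized features, miss
  contributions weighted by P(C)/(1 − P(class)); |W| ≤ 1.  Classic
  two-class Relief is the k = 1 equal-prior reduction.  Ties in the ranking
  break lexicographically.  The sklearn-style `ReliefFSelector` exposes the
  ranking as a feature-selection transformer.
* **SVM** — RBF soft-margin SVC, C = 1, one-vs-one multiclass with
  one-vs-rest decision scores, kernel scale by the median heuristic on the
  training-fold standardized features; stratified 5-fold cross-validation
  with out-of-fold predictions pooled into one 4×4 confusion matrix; macro
  one-vs-rest accuracy/PPV/sensitivity/specificity/NPV, F1 as the harmonic
  mean of macro PPV and macro sensitivity, and macro one-vs-rest AUC.
  Only cross-validated figures are reported (the study's validation
  protocol is unreported).
* **Logistic regression** — healthy controls vs. dementia (CDR ≥ 1, MCI
  excluded by default), maximum likelihood via in-module IRLS with
  pseudo-inverse Newton steps.  Wald 95% CIs exp(β ± 1.96·SE); Cox–Snell
  R² = 1 − exp((2/n)(LL₀ − LL₁)); max-rescaled (Nagelkerke)
  R² = Cox–Snell / (1 − exp(2·LL₀/n)); classification accuracy at the 0.5
  threshold.  Quasi-separation (common here: knee/hip ROM separate healthy
  from dementia by ≈ 4 SD) is flagged explicitly, with a warning that ORs
  and CIs are then unreliable, rather than erroring out or reporting
  silently.
* **Group statistics** — Lilliefors-style KS normality screening (seeded
  Monte-Carlo calibration, 10⁴ replicates, because mean and SD are
  estimated); tie-corrected Kruskal–Wallis with χ² p-values; Bonferroni
  post hoc over the six labelled pairs (a–f) at α/6 = 0.0083, two-sided
  rank-sum by default with Dunn's z-test by flag; Fisher's exact test
  (hypergeometric enumeration for 2×2, seeded Patefield Monte Carlo with
  ≥10⁵ margin-preserving tables otherwise).

## What the synthetic data shows — and does not

The generator reproduces the *parameter level* of the study groups: group
locations and spreads of the 11 features, the event signatures the detector
needs, and the geometric consistency that makes the pipeline invertible.
Passing tests therefore demonstrate that the signal-processing chain,
feature formulas, ranking and model protocols are implemented correctly
and recover known ground truth.  They do not demonstrate performance on
real pathological gait: features are drawn independently within subject
(no velocity–cadence–ROM covariance), waveforms are low-harmonic
idealisations without turning, variability between strides, or
morphological abnormality, and magnetometers, 3-D kinematics and soft
tissue artefacts are absent.

Three consequences are worth naming:

* With independent draws, cadence and cycle time carry nearly identical
  discriminative information, so ReliefF ranks cadence and cycle time
  interchangeably; velocity is reliably 1st, but the exact published top-4
  list {velocity, knee ROM, cycle time, hip ROM} is not stable.
* The healthy-vs-dementia contrast in knee/hip ROM is nearly separable
  (≈ 4 SD), so the two-predictor logistic model reaches ≈ 99% CV accuracy
  — far above the study's 77.9% on real data — and quasi-separation is the
  norm at full cohort size.
* The mild-vs-moderate contrast is weak by construction (velocity 0.7 vs
  0.6 m/s at SD ≈ 0.15; knee ROM 39.4 vs 38.9).  The Bayes-optimal 4-class
  accuracy on the top-4 feature subset under this generative model is
  ≈ 85% (Monte-Carlo with the known densities), and the rank-sum power for
  the mild–moderate velocity pair at p < 0.0083 is ≈ 0.4, so the
  corresponding published figures act as ceilings the synthetic cohort
  cannot exceed, not floors it clears.

## Numerical choices and degenerate inputs

* Event threshold strictly exceeded (a 50.0 deg/s peak is rejected);
  min-separation 0.25 s (shorter than any plausible half cycle in the
  cohort's cadence range).
* Filter preconditions: cutoff < Nyquist; series length ≥ 3×(order+1);
  NaN input errors with the sample index.
* Complementary filter: α = 1 reduces to trapezoidal integration, α = 0 to
  the accelerometer inclination; zero-norm accelerometer samples take a
  pure integration step.  Constant gyro bias b gives a steady-state error
  bounded by b·Δt·α/(1 − α) (verified against the closed form).
* Zero-variance input to the normality screen fails with an explicit
  reason; all-identical Kruskal–Wallis input returns H = 0, p = 1; a
  zero-margin contingency table returns p = 1 with a warning.
* Subjects with zero valid cycles are excluded from the feature table and
  listed; cycles with negative support intervals are rejected and counted.
* Evaluation runs use 20 master seeds for group-level recovery summaries,
  10 for the cross-validated models and 100 for the ranking-stability
  estimate, balancing seed-to-seed variance against a single-CPU budget.

## Known limitations

* Ankle ROM draws are clamped to the waveform-feasible band implied by the
  subject's step geometry and the event-detectability margin; for slow
  walkers this raises the group mean by a few degrees relative to the
  published ankle summaries (the ankle row is the least faithful of the
  eleven).
* Double-support percentages are tied to stance (see Cohort model), so the
  published initial-double-support row is emulated only through the stance
  draw.
* The moderate-group cycle-time median follows 120/cadence (≈ 1.43 s), not
  the published 1.6 s, by the consistency-precedence rule above.
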