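# Methods

This note documents the models implemented in groovesync, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a reader would otherwise have to
reverse-engineer from the code.

## Study design emulated by the generator

The generator reproduces the structure of a seated music-listening
experiment: `n_participants = 30`; three syncopation levels (Low/Middle/High)
× three rhythmic patterns per level × three movement conditions
(Free/Static/Dynamic), i.e. 27 trials per participant; 16-s stimuli at
120 bpm; movement sampled at 100 Hz. The Free condition always comes first
(participants should not yet be attending to their own movement), and the
Static/Dynamic order alternates deterministically with participant parity
(0-based even index: Static then Dynamic). Stimulus order within a section
is shuffled under the design seed; identical seed and spec reproduce
bitwise-identical tables.

Patterns are categorical labels (1..K per level). No audio is rendered and
no syncopation index is computed: syncopation enters all analyses as a
three-level factor, dummy-coded against the Low reference.

## Movement signal and phase coupling

A trial's neck-angle magnitude is synthesized as

θ(t) = baseline + A₁ sin(2π·1·t + ε₁(t)) + A₂ sin(2π·2·t + ε₂(t)) + broadband noise,

with amplitudes in degrees. The baseline posture offset defaults to
A₁ + A₂ + max(1°, 6·noise SD) so the magnitude never rectifies at zero —
important because the analysis signal is a norm (non-negative), and a
zero-mean oscillation run through a norm would double its frequency. Real
neck-angle magnitudes likewise oscillate about a nonzero postural offset.

Phase coupling is controlled per component by a von Mises concentration κ
(∞ = perfectly locked). Two jitter modes exist:

- **Stationary (default).** ε(t) is a slowly varying process with an exact
  von Mises(0, κ) marginal, built by mapping a unit-variance Gaussian AR(1)
  through the Gaussian CDF and the von Mises quantile function. The
  correlation time (`jitter_timescale_s`, default 8 s) is deliberately slow
  relative to the ±0.3 Hz analysis band: the band-pass filter then passes
  the jitter essentially unchanged, and the pipeline's measured PLV agrees
  with the circular mean of the realized jitter (the closed-form check: the
  asymptotic PLV is the Bessel ratio I₁(κ)/I₀(κ)). Fast per-sample jitter
  would instead be averaged away by the narrow filter and every κ > 0 would
  measure as PLV ≈ 1, destroying the controllability the generator exists
  for. `simulate_phase_samples` retains the plain iid von Mises definition
  for direct tests of the PLV statistic itself.
- **Random walk** (`phase_drift_sd` > 0): ε(t) accumulates Gaussian
  increments, for drift-style decoherence.

**Finite-sample bias.** With 14 s of analyzable phase (after edge trim) and
an 8-s jitter correlation time, one trial contains few independent jitter
excursions, so single-trial PLV estimates of weak coupling sit well above
the asymptotic Bessel ratio (the resultant length of a few unit vectors is
biased upward). This mirrors real short-trial PLV analyses and is the main
reason condition effects, not absolute PLV levels, are the meaningful
output. Recovery tests that need the closed form use long phase records
instead of trial-length movement signals.

Default per-condition movement profiles (amplitudes, noise, and a coupling
shift) are chosen so that instructed movement (Dynamic) is larger and more
tightly locked than spontaneous movement (Free), which exceeds suppressed
movement (Static); mean PLV2 then orders Static < Free < Dynamic by
construction.

## Body template and forward kinematics

The body template places the 11 markers in an anatomically plausible seated
rest pose (x lateral, y anterior, z vertical; head-top 15 cm above the ear
midpoint; thoracolumbar center directly below the neck pivot so the rest
pose is the neutral orientation). Forward kinematics rotates the head
markers (head top, both ears) rigidly about the neck pivot along a chosen
axis (default: lateral axis, i.e. flexion) by the angle series; torso
markers stay at rest, optionally with a slow anterior sway.

The neck pivot is computed from the rest pose **with the same joint-center
convention the analysis uses**, so forward and inverse passes agree by
construction and the round trip is a genuine end-to-end test (amplitude
error < 2 %, dominated by the low-pass filter's small passband loss).

## Kinematic analysis chain

Order of operations: gap handling → trim to the stimulus window (trigger
sample + 16 s) → zero-phase low-pass → joint centers → angles → norm.

- **Gaps:** linear interpolation for dropouts ≤ 10 samples per coordinate;
  anything longer rejects the trial (no imputation of long gaps).
- **Filtering:** 4th-order Butterworth, 5 Hz cutoff, applied forward and
  backward (`sosfiltfilt`), which cancels phase and doubles the effective
  order. The cutoff is fixed; the residual-analysis procedure for choosing
  it is out of scope.
- **Joint centers:** neck = ear midpoint (optionally projected toward C7 by
  a configurable fraction; default 0 because the ear midpoint is a fixed
  point of pure head rotation, making the center motion-invariant);
  shoulder = acromion midpoint; thoracolumbar = T8/T12 midpoint. This is a
  documented geometric convention implemented as one swappable function —
  a regression-based joint-center method can replace it without touching
  the rest of the chain.
- **Angles:** head frame from the ear line and ear-midpoint→head-top
  vector; torso frame from the acromion line and thoracolumbar→neck axis;
  the relative rotation is decomposed as intrinsic X-Y-Z (flexion, lateral
  bending, axial rotation) about torso-fixed axes. The order is a
  convention; the downstream norm is insensitive to it for small angles
  (large-angle order dependence is a known limitation).
- **Units:** metres, degrees, 0-based samples, time = index/rate.

## Synchrony measures

PLV1 (1 Hz) and PLV2 (2 Hz) are computed by band-pass (target ± 0.3 Hz,
4th-order Butterworth, zero-phase — the same family as the kinematic
filter, for consistency), Hilbert instantaneous phase, and the circular
mean against a reference sinusoid anchored at stimulus onset. One second
per side is trimmed from the phase series before averaging
(`edge_trim_s = 1.0`, configurable): the analytic signal is unreliable near
record boundaries, and a 16-s trial leaves N = 1400 phase samples. PLV is
offset-invariant, so the reference-phase origin affects interpretability
only. Frequencies other than 1/2 Hz are accepted but flagged with a
warning, keeping the tool usable at other tempi.

## Ratings and the structural data-generating process

Urge-to-Move and Pleasure composites are means of three 0–6 items each.
The generating path model (raw scale) defaults to: Middle syncopation
raises Pleasure (+0.8) and Urge (+0.6), High lowers both (−1.0, −0.9),
Pleasure→Urge +0.55, Urge→PLV1 +0.015, Urge→PLV2 +0.035; participant
random-intercept SDs of 0.5 (ratings) and 0.03/0.05 (PLVs); residual SDs
0.9/0.8/0.06/0.08; intercepts 3.3/1.4/0.12/0.18. These produce the
inverted-U syncopation profile, mid-scale ratings with rare clipping, and
PLVs inside [0, 1]. Magnitudes are plausible placeholders: no movement
amplitudes or raw-scale path coefficients are published for this paradigm,
so acceptance rests on parameter *recovery*, not on matching real effect
sizes.

Two generation modes: **recursive** (acyclic, default — generated
sequentially in causal order) and **simultaneous** (feedback paths such as
PLV→Urge; solved through (I−B)⁻¹, which must be invertible). Scores are
clipped to [0, 6] (PLVs to [0, 1]) after noise; unclipped latent values are
retained in the ground truth so recovery tests are not biased by censoring.
If more than 20 % of scores clip, the generator warns that the DGP is
poorly scaled.

## Inferential layer

- **ANOVA.** Two balanced two-way modes, both with full sums of squares
  retained: *pooled* (fixed-effects partitioning on participant-by-cell
  means; with 30 participants and a 3×3 design the error df is 261) and
  *repeated* (each within-subject effect tested against its own
  effect-by-subject interaction). Partial η² = SS_e/(SS_e+SS_err); the
  generalized variant uses all subject-related SS in the denominator in
  repeated mode. The partitioning is implemented directly (the SS detail is
  part of the output contract); statsmodels' `anova_lm`/`AnovaRM` serve as
  independent cross-checks in the tests.
- **ART.** Aligned rank transform for non-normal responses: per effect,
  subtract all other estimated effects (cell-mean construction), midrank,
  run the factorial ANOVA on ranks, keep the target row. The normality
  gate is Shapiro–Wilk on within-cell residuals at α = 0.05 (configurable;
  the choice of gate is a convention).
- **Post hoc.** Paired t-tests with Holm correction by default, Bonferroni
  by flag.
- **Correlations.** Pearson r per movement × syncopation cell (n = 90 at
  the default design), two-sided p from the t distribution on n−2 df,
  95 % CI via Fisher z: tanh(atanh r ± z₀.₉₇₅/√(n−3)). Degenerate |r| = 1
  returns a point interval; empty/degenerate cells are flagged, never
  silently dropped.
- **Mixed model.** dv ~ fixed terms + (1 | participant), maximum
  likelihood. The residual variance is profiled out and the likelihood is
  reduced to a one-dimensional search over θ = σ_b²/σ²; at each θ the
  fixed effects have the closed GLS form using the analytic inverse of
  I + θJ per participant block. Inference is Wald z
  (Satterthwaite/Kenward–Roger df corrections are out of scope). The
  boundary σ_b = 0 is detected and flagged. Within-person centering
  (participant mean vs deviation) separates trial-level from
  between-person associations.

## Path-analysis engine

- Covariance-only fitting (no mean structure): the model concerns
  covariance-structure paths, and the dummy-variable means enter through
  Φ and Γ.
- F_ML is minimized by L-BFGS-B with **analytic gradients** (trace-form
  derivatives of the implied covariance), regression-based starting values
  from the sample covariance, and up to 10 jittered restarts; convergence
  at gradient norm < 1e-8 and F changes < 1e-14.
- T = (N−1)·F_ML. N−1 (Wishart) scaling was chosen over N; at realistic
  sample sizes this moves the indices in the third decimal. df =
  p(p+1)/2 − q. Baseline for CFI/TLI: independence (diagonal Σ), variances
  free. SRMR averages squared correlation-metric residuals over the lower
  triangle including the diagonal.
- Standard errors come from the finite-difference Hessian of the
  discrepancy: Var(θ̂) = 2/(N−1) · H⁻¹; the tests verify them against
  bootstrap SEs. The standardized solution rescales estimates by
  model-implied standard deviations.
- Residual variances are bounded below at 1e-10; a solution at the bound
  is reported with a Heywood flag rather than failing, so multi-group
  searches can proceed.
- Non-recursive systems (e.g. reciprocal Urge↔PLV paths) are estimable
  through the (I−B)⁻¹ formulation; identification is pre-checked by
  parameter counting plus the rank of the numerical Jacobian of the
  implied moments at a perturbed start, and unidentified specifications
  are rejected with a diagnostic. Both a recursive and a feedback variant
  of the groove–synchrony model ship as fixtures, because either reading
  of the reciprocal-path topology is defensible.
- Multi-group fitting minimizes Σ_g (N_g−1)·F_g with equality-labelled
  parameters shared; the stepwise release procedure frees, at each step,
  the constraint whose release most improves fit (chi-square difference),
  stopping when no release is significant at α = 0.05. RMSEA in the
  multi-group case uses the √G convention.
- Trial-level rows are treated as independent in the SEM likelihood.
  Participant clustering is thereby ignored — a deliberate simplification
  matching common practice for this analysis; under clustered data the
  chi-square difference test is mildly anticonservative, which is why the
  null-calibration tests use an iid-trial generator.

## What passing tests do and do not show

The generator produces stationary sinusoidal coupling, linear-Gaussian
ratings with known paths, and a rigid head segment on a noiseless marker
model. Passing recovery and round-trip tests therefore demonstrates that
the estimators are correctly implemented and unbiased under their own
assumptions. They do not demonstrate robustness to soft-tissue marker
artifacts, non-stationary tempo drift, item-level response styles,
censoring-induced bias when ratings pile up at the scale ends, or
violations of the SEM independence assumption beyond what the mixed model
captures. Absolute synthetic effect sizes are placeholders, not estimates
of real ones.

## Problem sizes used in the test suite

Recovery tests run at ~5,000 trials (190 synthetic participants);
multi-group null calibration uses 200 replicates of two 324-trial groups;
mixed-model recovery uses 200 replicates of the 30 × 27 design; Bessel-ratio
convergence uses 2·10⁴–10⁵ phase samples. These sizes make the Monte-Carlo
error small relative to every tolerance asserted.
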