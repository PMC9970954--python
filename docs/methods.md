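# Methods

This note documents the models, the reconstructed measure definitions, the
synthetic-data generator, the numerical choices, and the known limitations
of `digibrain`.

## The analysis model

Two cross-sectional analyses relate per-subject measures (16 digital + 5
clinical) to 36 regional structural MRI outcomes (34 normalized volumes in
mL; corpus callosum and upper cervical cord as cross-sectional areas in
mm²), with normalized total brain volume carried alongside.

**Adjusted rank correlation.** Digital measures are plausibly confounded by
age, sex and BMI. Each variable is residualized on the three confounders
with a robust linear model — iteratively reweighted least squares with the
Huber ψ, tuning constant c = 1.345, intercept always included, convergence
on coefficients at 1e−8 or 50 iterations — and the residuals are Spearman
rank-correlated (average ranks on ties). "Residualize both sides, then
rank-correlate" is the only reading of a robust-model adjustment that still
yields a Spearman coefficient; it is isolated in `residualize()` so an
alternative (covariate-included fit of y on x) can be swapped in. Two-sided
p-values use the t-approximation with degrees of freedom n − 2 − k, where k
is the number of covariates consumed by residualization (the standard
partial-correlation correction; without it the test is measurably liberal —
raw type-I rate 5.7% instead of 5.1% at n = 62, k = 3). Missing cells are
handled pairwise-complete per measure–region pair. On complete tables the
implementation residualizes each column once, which is mathematically
identical and ~13× faster; a test asserts the equality.

**Multiplicity.** Benjamini–Hochberg step-up q-values, computed per measure
(families of 36 region tests, the primary layout) or globally over the
36 × 21 grid (the conservative layout). Significance is q < 0.05.
BH, not BY; configurable.

**Explained variance.** Per measure, a Bayesian ridge regression (zero-mean
isotropic Gaussian prior on weights; weight and noise precisions estimated
by evidence maximization, fixed-point iteration to 1e−6 or 300 iterations —
scikit-learn's `BayesianRidge`, which implements exactly this) is evaluated
by leave-one-out cross-validation: R² = 1 − Σ(yᵢ−ŷ₋ᵢ)²/Σ(yᵢ−ȳ)², with
predictors re-standardized inside every fold and the response on its native
scale. Negative LOO R² is reported as 0 (the convention implied by reported
"R² = 0.23 vs 0" contrasts); `signed=True` disables the floor. The **Whole
Brain** model uses [total brain volume, age, sex, BMI]; the **Parcellation**
model uses [36 regions, age, sex, BMI] — demographics enter both.
Complete-case analysis; constant predictors are dropped with a warning;
non-convergence of the evidence iteration is surfaced as `converged=False`
and treated as a failure by the tests.

**Power.** Fisher z-transform normal approximation for a two-sided
correlation test, power = Φ(δ−z₁₋α/₂) + Φ(−δ−z₁₋α/₂) with
δ = √(n−3)·atanh(ρ). At ρ = 0.33, n = 70: 80.1%. The approximation is good
to ~0.015 at n = 30 against the exact Monte-Carlo rejection rate.

## Reconstructed measure definitions

The deployed apps' exact formulas are not published; the definitions below
are documented reconstructions, chosen to be consistent with each measure's
name, unit and direction-of-better, and each is overridable:

* **Trace accuracy** — fraction of the reference shape's waypoints with at
  least one trace sample within a tolerance radius of 5% of the shape's
  bounding-box diagonal. **Celerity** = accuracy / drawing time (1/s),
  anchoring "accuracy over time". **Velocity CVs** — population SD/mean of
  segmentwise linear speed; angular and radial velocities (magnitudes,
  about the reference shape's centroid) only for the round shapes (circle,
  figure-of-8, spiral) — signed radial velocity has mean ≈ 0 on closed
  round shapes, making SD/mean ill-posed. Lines and square report NaN.
* **SFI30** — correct-response rate in the final 30 s divided by the rate
  in the first 60 s (boundary t = 60 s belongs to the first window); 0 when
  the first-window rate is 0. **Max gap** — largest inter-arrival time
  between correct responses, 0 with fewer than two.
* **Pinch** — a gesture is two concurrently-down pointers; success requires
  both down-positions inside the active target and decreasing inter-pointer
  distance. Gap time = median end-to-next-start interval; asynchrony =
  median |Δt| of the two contact times over successful pinches. No
  gestures ⇒ missing (NaN), never 0.
* **Sway path** — Σ‖Δa‖ of the mean-removed horizontal acceleration
  trajectory (m/s², the only definition consistent with the unit).
* **Walk** — vertical axis detrended by removing its < 0.5 Hz component
  (2nd-order Butterworth, zero-phase); steps by peak-picking (min height
  max(0.05 m/s², 0.3·SD), min spacing 1/4 s) with quadratic sub-sample
  refinement; step frequency/variance from reciprocal inter-step intervals;
  step power = mean per-step ∫a² dt. The unit m²/s³ fixes this form — an
  additional division by step duration would give m²/s⁴.
* **Turn speed** — contiguous |yaw rate| > 0.3 rad/s intervals, turned
  angle by trapezoidal integration, turns below π/2 rad discarded; median
  of angle/duration. Threshold detection trims a smooth burst's tails, so
  simulated raised-cosine turns read ~25% above π/duration; rank order is
  preserved, which is what the downstream correlation uses.

Medians (not means) aggregate within-test gap/asynchrony/turn values for
robustness. Missing values propagate to aggregation and the
pairwise-complete correlation stage.

## Quality control and adherence

Flag thresholds are reconstructions and configurable (`QCThresholds`):
play-to-quit at < 3 e-SDMT responses, drawn trace < 20% of the reference
path length, zero pinch gestures, or a gait/balance stream shorter than 50%
of the nominal duration; device-on-table when the gravity-removed
acceleration variance is below 1e−3 (m/s²)² (walking tests) or below a
1e−6 (m/s²)² hardware noise floor (static balance). A flagged test is
invalid; QC is idempotent.

Adherence pools all active tests and requires ≥ 1.5 valid tests per week
*averaged over the 24-week study window*, inclusive at the boundary. The
fixed window (rather than the first-to-last-record span) is what makes
inclusion monotone in added valid tests; the span-based window remains
available via `study_weeks=None`. 1.5/week under a daily schedule is
21.4% ≈ 21% adherence. Missing MRI is a join-time exclusion, not a QC flag.

## The synthetic cohort generator

One latent disability factor L ~ N(0, 1) per subject drives everything.
Each region r gets z_r = λ_r·L + covariate terms + √(1−λ_r²)·ε and volume
μ_r·(1 + cv_r·z_r); each digital measure m gets its own driver
z_m = λ_m·L + covariate terms + √(1−λ_m²)·ε mapped *monotonically* onto the
simulator parameter that controls it (drawing noise 6·e^{0.5z} px, speed
jitter 0.08·e^{0.4z}, pinch asynchrony mean 0.08·e^{0.35z} s, gap mean
0.7·e^{0.3z} s, e-SDMT rate 0.35·e^{−0.25z}/s with gamma-renewal
burstiness, sway amplitude 0.12·e^{0.4z} m/s², cadence 1.85 − 0.12z Hz,
step amplitude 2·e^{−0.25z} m/s², turn duration 1.8·e^{0.3z} s). Because
the downstream statistic is rank-based, any monotone mapping preserves the
planted association: for Gaussian drivers the population Spearman
correlation between measure m and region r is ≈ (6/π)·asin(λ_mλ_r/2),
attenuated a few percent by extraction noise. Covariates (age, sex, BMI)
enter both sides with small slopes, creating genuine confounding for the
adjustment to remove.

Defaults are the study conditions: 62 subjects; age N(39.7, 7.5²) clipped
to 20–57; 68% female; BMI N(24.4, 4.4²) clipped to 17.1–37.6; two MRI
scans with 1% measurement noise and three clinical visits; 7
administrations per test type spread over 24 weeks (1.75 valid tests/week,
comfortably above the 1.5 cutoff); inertial sampling at 50 Hz, touch events
at ~60 Hz; test durations 90/30/30/120/45 s. Region population means and
CVs are invented but anatomically plausible; total brain volume is the
scaled sum of the mL regions (≈ 1471.9 mL population mean) plus
measurement noise, so a globally driven measure really is recoverable from
the parcellation. Optional `n_low_adherence` / `n_missing_mri` groups give
the QC stage realistic exclusions (the 76 → 62 accounting). All randomness
flows from a single config seed through per-record `SeedSequence` spawning;
identical configs are bit-identical.

**What the generator does not emulate:** real touch digitizer noise and
palm rejection, device orientation changes and magnetometer drift, gait
asymmetry and turning strategies, learning/practice effects across
administrations, site effects, non-monotone disability–performance
relationships, and realistic missingness mechanisms. Passing tests
therefore demonstrate that the *pipeline* recovers planted monotone
structure under Gaussian-latent conditions — not that the reconstructed
measure formulas equal the deployed ones.

## Problem sizes used in tests and the acceptance script

Monte-Carlo sizes are the package's own choices: 200 replicates for FDR
control, confounded-null bias and LOO-R² recovery in the test suite
(100 in the faster acceptance script); 400-replicate oracle for the
planted-ρ sampling interval; 100 seeds (50 in the script) for the
Parcellation > Whole-Brain contrast; 2000 replicates for the type-I check;
4·10⁴ vectorized replicates for the power Monte-Carlo. The planted-recovery
check runs the full sensor pipeline once at n = 200.

## Known limitations

* Measure formulas are reconstructions (above); constants such as the 5%
  accuracy tolerance or the 0.3 rad/s yaw threshold shift absolute values
  but not ranks, which is what the analysis consumes.
* The robust-residualization adjustment removes linear covariate effects
  only; strongly non-linear confounding would leak.
* LOO R² with evidence-maximized precisions is mildly pessimistic (mean
  recovered R² ≈ 0.43 at a true explainable fraction of 0.5, n = 62).
* The e-SDMT simulator plants fatigue as a rate change; it does not model
  response-level learning of the symbol–digit key.
* Sway-path magnitudes scale with sampling rate (a path length over
  samples); comparisons are only meaningful at a fixed rate, here 50 Hz.
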