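# Methods

## Viewing geometry and coordinate conventions

All projections use a cyclopean frame: origin midway between the eyes,
x rightward, y upward, z toward the screen, eye nodal points at
(±I/2, 0, 0) and the screen plane at z = d.  Screen coordinates are cm;
stimulus coordinates are degrees of visual angle via the tangent mapping
x_cm = d·tan(x_deg).  Angles are degrees at public interfaces and
radians internally.  Slant is rotation about the vertical axis through
fixation; positive slant puts the right side of the surface farther from
the observer.  Defaults: viewing distance 29.3 cm for the screen
experiment, 35 cm for hand-held objects, interocular distance 6.2 cm
(population-typical; every prediction takes it as a parameter).
The vergence angle uses the exact form μ = 2·arctan(I/2d); the
small-angle I/d approximation appears only in documented cross-checks.

Monocular magnification is modelled as pure scaling of one eye's screen
coordinates about the screen centre (the fixation point), which matches
how such stimuli are produced on a stereoscopic display and is also the
idealisation of a meridional spectacle magnifier.  No prismatic,
torsional or optical-aberration effects are modelled.

## From magnification to slant

For a vanishingly small patch at fixation, magnifying one eye scales
that eye's angular sizes by the magnification factor, so the
interocular size ratios are HSR = f_Rh/f_Lh and VSR = f_Rv/f_Lv with
f_e the per-eye scale factors.  The disparity-specified slant is

    σ = arctan( ln(HSR/VSR) / μ ).

This reproduces the classical geometric effect (horizontal
magnification, slant toward the magnified eye), the induced effect
(vertical magnification, opposite slant) and the uniform null
(HSR = VSR).  The implementation computes ln(HSR/VSR) as a difference of
per-eye log factors so that the eye-swap and horizontal/vertical
antisymmetries are exact in floating point.  The formula is treated as
valid for magnifications up to 20%; the experimental grids stay at or
below 12%.

### Independent numerical check

`predicted_slant_numeric` is a brute-force oracle for the closed form:
a grid patch is projected to both eyes, the magnification applied, and
the slant of a physically slanted plane searched so that the plane's
un-magnified two-eye projections match the magnified images in the
least-squares sense.  Two modelling choices make this fit well-posed:

* the quantities that carry no slant information are free nuisance
  parameters — a per-eye uniform scale (an overall interocular
  magnification is not a slant cue) and a width/height aspect ratio
  shared between the eyes (the object's shape is exactly what is in
  question).  With raw coordinates instead, the monocular shape
  mismatch dominates the interocular disparity signal and no slanted
  plane can reproduce a uniform interocular vertical size ratio, so the
  induced effect would be unrecoverable;
* the patch is small (default half-width 0.2 cm at 29.3 cm) because a
  slanted plane's monocular keystone distortion — a perspective cue the
  disparity-isolating stimuli deliberately withhold — is absent from
  the magnified target images and enters the residual at second order
  in patch size.  At the default size the fit agrees with the closed
  form to better than 0.3° over the full 3–12% × axis × eye grid.

The search is deterministic: a 1° grid over ±60° followed by bounded
scalar refinement to 0.01°, with the nuisance aspect solved by nested
bounded minimisation and the per-eye scales in closed form.

## From slant to shape

A square of half-width w at distance d whose retinal image is
reinterpreted at slant σ is perceived as the trapezoid with right/left
height ratio (d + w·sin σ)/(d − w·sin σ) — equivalently, the cyclopean
projection ratio of a square physically slanted by −σ.  The nulling
setting that cancels the percept is the reciprocal.  The cyclopean (not
per-eye) projection is used for perspective convergence.  Predictions of
shape-task settings from slant-task settings map each recorded slant
response through this ratio and fit an ordinary (unweighted)
least-squares cubic in signed magnification — left-eye conditions
negative, right-eye positive — evaluated at the shape-task grid.  The
cubic is a smoothing choice, not the true functional form: even
noise-free generative data leave a lack-of-fit of order 5×10⁻⁴
(horizontal) to 3×10⁻³ (vertical, where the generative saturation is
strongest) in ratio units.

## Stimuli

The slant stimulus is a 16°-diameter random dot cloud with a two-zone
density profile: 0.31 dots/deg² in the central 8° disc and
0.062 dots/deg² in the surrounding annulus (16 and 9 dots by
area × density, rounded).  A smooth taper is not modelled.  Dots are
placed by uniform rejection sampling per zone from a seeded generator.
Setting the cloud's slant back-projects each dot's cyclopean screen
position onto the slanted plane through fixation, re-projects to each
eye and applies the magnification — so the on-screen (cyclopean) layout,
outline and density histogram are invariant to the slant setting by
construction and binocular disparity is the only slant cue.  The shape
stimulus is a quadrilateral with a fixed 16° left side; a target ratio
moves the two right corners symmetrically.  Rasterisation (white dots /
near-black quad on a 2%-luminance gray field, 0.27 mm pixel pitch,
1920×1080) is deterministic; temporal interlacing, anti-aliasing and
luminance calibration are out of scope.

## Synthetic observers

The generative observer converts the closed-form slant σ_cf into a
percept:

* horizontal: σ_p = gain_h·σ_cf + ε;
* vertical: the magnitude passes through a saturation
  sat·tanh(|σ_cf|/sat) before the gain, preserving the (opposite) sign —
  the induced effect plateaus at higher magnifications;
* uniform: σ_p = gain_u·σ_cf of the *horizontal-equivalent*
  magnification — pure geometry predicts a null, but observers show a
  small residual drift in the horizontal-magnification direction;
* ε ~ N(0, slant_noise_sd²) per trial.

Task responses are the nulling settings: −σ_p for the slant task and
the nulling ratio of coupling·σ_p (times log-normal setting noise) for
the shape task; the coupling λ ∈ (0,1] expresses that shape percepts
reflect the slant geometry only partially.  Real-object drawings use the
perspective ratio of coupling·σ_p; binary slant reports fire when
|σ_p| exceeds a threshold τ (with lapse-rate coin flips) and report the
correct direction only with probability `direction_reliability`.

Defaults: gain_h = 1.0, gain_v = 0.85, gain_u = 0.35, sat = 15°,
λ = 0.8, slant_noise_sd = 2°, ratio_noise_sd = 0.01 (log units),
τ = 4°, lapse = 0.05, direction_reliability = 0.55.  These were chosen
once to reproduce the qualitative phenomenology — a robust drawn-shape
illusion, slant awareness in only part of the cohort, near-random
reported direction — and are not fitted to any dataset.  Individual
differences are modest truncated-normal perturbations of the gains,
coupling and noise (SDs 0.05–0.08 for gains, 0.05 for coupling); report
parameters are homogeneous by default.  Each participant owns an
independent random stream spawned from the cohort seed (so enlarging a
cohort never perturbs existing participants), with separate child
streams for the parameter draw and the three sessions.

What the generator does *not* emulate: adaptation over time, diplopia at
high magnification, vergence noise, corner-asymmetry idiosyncrasies in
drawings, or object-familiarity effects.  Passing tests therefore show
that the pipeline is correct and well calibrated on data obeying the
generative model, not that human data will match the model.

## Statistical pipeline

Repetitions are averaged within condition before correlations and fits
(per-condition means; raw-trial mode is available).  Per-participant
Pearson correlations of response against signed magnification are
summarised by one-sample t tests with Cohen's d = mean/SD.  Prediction
fits report r² both as the squared Pearson correlation between predicted
and observed (primary) and as 1 − SSE/SST, plus RMSE in ratio units.
The 2×2 within-participant ANOVA (spectacles × object) uses the standard
decomposition in which each effect is tested against its
effect-by-participant interaction — computed via per-participant
contrasts, whose one-sample t² equals F(1, n−1); this is cross-checked
against an independent implementation in the test suite.  The
permutation variant relabels the four cells within each participant
(default 5000 permutations, seeded) with p = (1 + #{F* ≥ F})/(1 + B);
its type-I error at the 5% level is verified at 5% ± 2% over pooled
seeded null-cohort replicates.  Cochran Q follows the standard
column-total formula with all-constant-row data flagged as degenerate;
McNemar uses the continuity-corrected statistic clamped at zero (exact
binomial p optional) and odds ratios follow the control-over-
experimental (or square-over-phone) convention with a Haldane–Anscombe
0.5 correction for empty cells.  Pairwise p values are corrected by
Benjamini–Hochberg FDR at 5%.  The Cohen's d convention for paired
contrasts is mean difference over SD of differences; no claim is made
that this matches any particular published convention for derived
summary statistics.

## Problem sizes and determinism

Simulated cohorts default to 20 participants × 4 repetitions over
magnification grids {0, 3, 6, 9, 12}% (slant task) and {0, 1, 2, 3, 4}%
(shape task) for horizontal/vertical/uniform axes in either eye.
Calibration checks in the test suite use 100 low-noise cohorts for
parameter recovery and 2000 null cohorts (199 permutations each) for the
type-I rate, sizes chosen to keep the estimates' sampling error small
against the asserted bounds.  All randomness flows from explicit seeds
through `numpy.random.SeedSequence`; identical configurations reproduce
all output files byte-identically.

## Known limitations

* The pure-scaling magnifier ignores the shape/power factors of real
  meridional lenses.
* The closed-form slant is a small-patch (first-order) description;
  large stimuli carry disparity gradients it does not capture.
* The numerical slant oracle shares the small-patch limit by design; it
  validates the closed form, not large-field slant estimation.
* The uniform-magnification residual effect is a phenomenological gain,
  not a geometric derivation.
* Drawing measurements are modelled as exact ratio readouts; motor and
  measurement error of real ruler drawings is folded into one log-normal
  noise term.
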