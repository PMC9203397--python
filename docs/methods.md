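# Methods

## The analysis model

Each exam is one eye: age in years, laterality, 37 integer thresholds in
dB on the annular grid (one central locus, twelve each at 2.3°, 4°, 6°),
and a fixation-stability index. Left-eye exams are reflected across the
vertical axis into right-eye orientation before any pooled computation,
so anatomically corresponding loci align. Two device conventions are kept
as numeric facts throughout: the dynamic range 0–36 dB (0 dB = 317.04
cd/m², attenuation dB = 10·log10(max/stimulus)), and the −1 dB sentinel
for a stimulus not seen at maximum luminance. The sentinel enters means,
regressions and deviations as the value −1; an alternative
(floor-censoring at 0) would bias healthy references upward at loci where
−1 actually occurs, and the export convention is unambiguous, so −1 is
the default and only behaviour.

### Quantile reference

At each locus, sensitivity is regressed on age at τ = 0.025 and τ = 0.5
by exact minimization of the pinball loss, formulated as a linear program
(residual splitting, HiGHS solver, feasibility tolerances 1e−10). The LP
is solved directly rather than through a packaged quantile-regression
routine so the fit is testable in isolation; a brute-force enumeration of
all two-point interpolating lines — an optimal basic solution always
interpolates two data points — serves as the independent oracle in the
tests, and `statsmodels.QuantReg` as a cross-check.

Degenerate inputs (fewer than 2 points, constant ages) are rejected.
Multiple optimal lines are resolved deterministically: two further LP
phases select the smallest |slope|, then the smallest intercept, over the
optimal face, and the candidate is accepted only when its recomputed loss
genuinely matches the first-phase optimum (within 1e−12·max(1, L)); this
keeps collinear and constant-response inputs exactly interpolated while
leaving unique optima untouched.

The reference records the training age range and size. Default minimum
training size is 20 eyes with a warning below 50: the 2.5th-percentile
line is determined by the lower extreme of the data and is noisy at small
n. Predictions outside the training age range are permitted but raise an
`ExtrapolationWarning` rather than clamping — the linear extrapolation is
made visible instead of silently altered. Because the two τ-lines are
fitted independently, they can cross outside the data — and, at small n,
right at the sparse boundary of the training ages (observed: ≤ 0.04 dB at
the extreme age of an 80-eye cohort). The ordering τ=0.025 ≤ τ=0.5 holds
throughout the interior; consumers who need guaranteed ordering at
boundary ages should train on larger cohorts.

### Deviation and aggregation

Pointwise deviation = observed − median-line prediction at the subject's
age; abnormal ⇔ observed strictly below the τ = 0.025 line (a value
exactly on the line is normal). Eye summaries average the deviation over
all 37 loci (mean sensitivity deviation) and count abnormal loci by ring
(inner 13 = centre + 2.3°, middle 12 = 4°, outer 12 = 6°). Cohort
summaries report t-based 95% CIs (the t construction is a documented
choice; bootstrap is not implemented), per-locus flag percentages, ring
mean/SD of those percentages (n−1 denominator), a Welch two-sample t-test
of MS with Welch–Satterthwaite df, and OLS fits of MS on age (constant
response handled as slope 0, R² = 0 by convention). No multiple-testing
correction is applied across the 37 loci; the flag counts are
descriptive, matching how such maps are read clinically. The reference is
fitted on the full healthy cohort without leaving out any tested eye;
held-out calibration is checked separately on synthetic data.

### Fixation stability

BCEA(P) = 2π·k·σx·σy·√(1−ρ²), k = −ln(1−P), with sample (n−1) SDs and
sample correlation; ρ is set to 0 when one axis has zero variance (a
legitimate zero area), and fewer than 3 samples is an error. Inclusion
uses BCEA(0.63) < 5 deg², read strictly. Exams with no recorded BCEA are
excluded with a log message (conservative; an unmeasured fixation cannot
attest stability).

## The synthetic cohort generator

Healthy eye i, locus j:

    s_ij = round(intercept − age_slope·age_i − ecc_gradient·ecc_j + b_i + ε_ij)
    clipped to [−1, 36],   b_i ~ N(0, subject_sd²),  ε_ij ~ N(0, locus_noise_sd²)

Defaults: intercept 29.8 dB, decline 0.03 dB/year (the published healthy
MS trend), eccentricity gradient 0.3 dB/deg (sensitivity falls with
eccentricity; magnitude a plausibility choice, it only shifts locus
baselines), subject SD 1.0 dB, locus noise SD 1.5 dB (together giving
between-eye MS spread of ~1.1 dB, the right order for healthy adults),
ages truncated-normal 53.5 ± 14.6 years on [18, 90], BCEA uniform on
[0.5, 4] deg² so default cohorts pass the filter. Patient cohorts use the
published patient trend (29.9 dB, 0.06 dB/year, ages 48.5 ± 12.4) and
then subtract, at a per-eye sample of loci, lesion depths
N(depth_mean, depth_sd²) clipped at 0 — defaults 5 loci, 6 ± 2 dB —
drawn with ring weights 1 : 1.5 : 1.3 (inner : middle : outer), biasing
lesions away from the centre as observed clinically. Injected loci and
depths are returned as ground truth.

Rounding to integer dB emulates the device's discrete staircase output;
optionally each threshold can instead be measured by a simulated 4–2
staircase: steps of 4 dB (dimmer after seen, brighter after not seen)
until the first response reversal, then 2 dB, terminating at the second
reversal with the last-seen level — the conventional rule, since the
device documentation does not specify one — returning −1 when the floor
stimulus is not seen and 36 when the ceiling is seen. For a deterministic
observer this lands within 2 dB of the true threshold across the working
range (verified exhaustively).

What the generator does **not** emulate: spatial correlation between
loci beyond the shared subject effect, test–retest and learning effects,
non-linear age effects, media opacity, and lesion morphology. Passing
tests therefore demonstrate that the *pipeline* is calibrated and
sensitive under its stated assumptions, not that those assumptions hold
in any clinical population.

## Validation experiments and problem sizes

* **Null calibration**: reference from 2,000 synthetic healthy eyes,
  scored on 2,000 held-out eyes from the same model; the flagged fraction
  of locus observations averages ~2.5% (integer-dB discreteness makes the
  strict-below rule only approximately 2.5%; measured well within ±1
  point).
* **Trend recovery**: |OLS slope| of MS on age from a 500-eye default
  cohort. The estimator's SE at this design is ≈ 0.003 dB/year
  (age SD ≈ 14.3, residual MS SD ≈ 1.04), so single-cohort estimates
  scatter accordingly around 0.03; the test suite averages nine replicate
  cohorts to check the ±0.005 band reliably.
* **Dissociation**: the package's core claim in miniature. Patients are
  drawn from the *healthy* trend with exactly five 6-dB lesions each —
  the lesions are the only systematic group difference (ΔMS ≈ 0.8 dB
  against a between-eye SD of ≈ 1.1 dB). Group size is deliberately
  small (6 vs 6, reference from 400 independent eyes): at this size the
  Welch MS test has ~12% power while the abnormal-locus count (≈ 5 per
  eye vs null expectation 0.925) remains decisive, so a single seeded run
  shows a non-significant MS comparison alongside a CI for the abnormal
  count that excludes the null. At clinical-study group sizes (tens of
  eyes per arm) the 0.8 dB MS shift would itself reach significance under
  this noise model — the
  dissociation is a statement about effect size per locus, not one that
  survives arbitrary n.

These sizes keep the full suite around a minute of CPU while leaving
Monte-Carlo error well inside each check's band.

## Known limitations

Linear-in-age quantiles only (no splines, no covariates beyond age);
reference JSON serialization is limited to the standard 37-locus grid;
cohort CIs are t-based; the generator's Gaussian location-shift noise is
an assumption, not an estimate from data.
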