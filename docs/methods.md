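# Methods

## The forward model

Each vertex's population receptive field is an isotropic 2D Gaussian in the
visual field, w(p) = exp(−((pₓ−x₀)² + (p_y−y₀)²)/2σ²), unnormalised (peak 1).
The stimulus is reduced to a stack of binary apertures, one per scanning
volume, marking where the bar is; the neural drive at volume t is the
pixel-wise overlap of w with that volume's aperture. The BOLD prediction is
the drive convolved (causally, at TR) with a haemodynamic response function,
scaled by an amplitude β and offset by a baseline b. The model is linear in
(β, b) and nonlinear in (x₀, y₀, σ).

**HRF.** A canonical double gamma: the difference of two gamma densities
(shape = delay/dispersion, scale = dispersion) with peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot ratio 6, evaluated
on a 0.1-s lattice, truncated at 32 s and normalised to peak 1. The study
that motivates this package used an empirical group-average HRF whose
numeric shape is not published; the canonical parameters are the standard
stand-in and every parameter is configurable, so a measured HRF table can be
substituted by adjusting `HRFSpec`.

**Aperture geometry.** The bar is a 2.4°-wide strip perpendicular to its
travel direction, swept in 25 steps of 0.7°. 25 × 0.7° = 17.5° slightly
exceeds the 16° square, so the step path is centred on fixation and the
strip starts/ends partly outside the 8°-radius stimulus disc ("beginning at
one edge, ending on the opposite side"). Pixels sit on a uniform half-open
lattice over the square; a pixel belongs to a region iff its centre does
(strict inequalities), and the strip is clipped to the disc at render time.
Direction vectors at multiples of 45° are constructed exactly, which makes
reversing a sweep reproduce the time-reversed frames bit for bit — a useful
regression invariant. Default grid: 100 × 100 pixels (0.16°/pixel,
sub-bar-width resolution at low cost).

## Preprocessing

Per run: discard any leading pre-equilibrium volumes, remove the best-fit
line, standardise to mean 0 / sd 1; runs of a condition are then averaged
elementwise. A constant (or purely linear) run raises a degenerate-series
error rather than propagating NaNs. Because the observed series is
standardised, the baseline is ≈0, but it is still estimated as a free
intercept in the fit for robustness on real data.

## Two-stage fitting

**Coarse.** One standardised prediction is precomputed per point of a
search grid (defaults: x₀, y₀ 15 points uniform on [−8.5°, 8.5°]; σ 12
points log-spaced on [0.1°, 8°]; 2700 points). Grid points whose prediction
has zero variance (pRF never overlaps the bar) are flagged unusable. For
each vertex the point maximising the *signed* Pearson correlation is
selected — anti-correlated solutions score below uncorrelated ones and are
never preferred — with ties resolved in (σ, y₀, x₀) scan order.

**Fine.** Nelder–Mead simplex over (x₀, y₀, σ) seeded at the coarse
optimum (x/f tolerances 1e-4, max 400 iterations); at each candidate, β and
b are ordinary least squares of the observed series on the convolved drive,
so maximising correlation and minimising residual sum of squares coincide.
The fine stage never returns a worse R² than its seed (it falls back to the
seed, flagged unconverged). Candidates with σ ≤ 0 are rejected inside the
objective. Near-constant predictions are treated as zero-correlation to
avoid rounding-noise correlations.

R² is the squared Pearson correlation between the observed series and the
final prediction; "responsive" means R² > 0.05 by default.

**Threshold p-value.** `r2_to_pvalue(r2, n_obs, n_params=2)` converts an R²
threshold to a two-tailed p through t = √(r²·df/(1−r²)) with
df = n_obs − n_params. The two linear parameters absorbed by the
correlation (amplitude, baseline) reduce the df; the three spatially
searched parameters do not. This convention reproduces the reference value
p = 0.000367 for R² = 0.05 at 250 volumes and matches a Monte-Carlo null of
correlations between white-noise series and a fixed prediction (checked in
the test suite and in `scripts/acceptance.py`).

Note an important and deliberate asymmetry: that p-value describes a
*single* correlation. The fitted R² is the maximum over thousands of
correlated grid predictions, so the fraction of pure-noise vertices
exceeding the threshold is substantially larger than p (measured ≈1.6%
rather than 0.04% under white noise). The test suite states the
single-correlation expectation and records the measured exceedance; the
discrepancy is a property of any max-selected statistic, not a bug.

## Synthetic cortex

The generator stands in for the study data (no accessions exist) and is a
first-class, tested module. Six areas (V1, V2, V3, V3A, V3B, MT+), each
with:

* **Geometry** — polar angles uniform; eccentricities with density ∝ r up
  to 8° (uniform over the disc); σ = intercept + slope·ecc with 10%
  lognormal jitter. Size laws (degrees): V1 0.5 + 0.15·ecc,
  V2 0.6 + 0.20·ecc, V3 0.8 + 0.25·ecc, V3A 1.2 + 0.35·ecc,
  V3B 1.4 + 0.35·ecc, MT+ 2.0 + 0.5·ecc — magnitudes in the range routinely
  reported for these areas, ordered so median size rises up the hierarchy.
  The large sizes in higher areas matter: a 2.4°-wide bar covers a small
  fraction of a 5° pRF, which is what couples pRF size to signal-to-noise
  ratio.
* **Drive** — drive(t) = (bar_gain·overlap(pRF, bar) +
  background_gain·overlap(pRF, disc∖bar)) / overlap(pRF, disc). The
  normalisation makes the full-field response amplitude σ-independent, so
  β (lognormal, median 1, log-sd 0.2) is in the z-units of the preprocessed
  data. Null trials follow each condition's rule: blank for `bar_only`,
  full-field background drive otherwise; the pre-run period is modelled as
  steady-state background so the HRF convolution has no spurious onset
  transient (and with zero background the simulation reduces *exactly* to
  the forward model).
* **Neural visibility** — background_gain ∈ [0, 1] per (area, condition)
  encodes how strongly the condition's background dots drive the area
  relative to the bar dots. The default table gives the plain bar zero
  background everywhere, nearly bar-strength background in V1 for the
  global-like conditions (suppressing its bar-locked modulation), and a
  clear bar/background contrast in V3A/V3B. These values are illustrative
  calibration knobs chosen once so that the qualitative area × condition
  responsivity pattern emerges; they are not estimates of any measured
  quantity.
* **Noise** — Gaussian, default sd 1.5 per run (z-units) with AR(1)
  coefficient 0.3. Autocorrelated noise is both more realistic for BOLD at
  TR = 1 s and behaviourally important: smooth noise is what makes weakly
  responding vertices fit with large, poorly constrained σ, reproducing the
  empirically familiar negative association between R² and fitted pRF size.
  Under white noise the same fits collapse to the smallest grid σ instead.

With this calibration, four averaged runs give: high responsivity in every
area for the plain bar; V1 suppressed and V3A/V3B peaking for the
global-like conditions; and a selection effect — restricting the bar-only
fits to a weak condition's surviving vertices lowers the median fitted σ in
the large-pRF areas even though no vertex's true σ differs between
conditions. The acceptance tests exercise exactly these properties.

**What the generator does not emulate:** cortical surface geometry and
smoothing, vascular/partial-volume mixing (one vertex = one pRF), scanner
drift and motion artefacts, attention and task effects, and any quantitative
match to the study's per-area numbers. Passing tests therefore demonstrate
that the pipeline recovers what it simulates and that the selection
mechanism operates as described — not that real cortex has these gains.

## Map-level statistics

Polar angle is atan2(y₀, x₀) (0 at the right horizontal meridian,
counterclockwise positive); eccentricity is √(x₀²+y₀²). Circular
correlations of polar-angle maps use the Jammalamadaka–SenGupta
sine-product estimator (cross-checked against an independent implementation
in the tests); group averaging is Fisher-z with a one-sample t test,
uncorrected, with |r| = 1 clipped at 1−1e-6 before the transform. Note the
estimator is unstable when both angle marginals are near-uniform (the
circular means are then ill-defined); the tests document this. Area
summaries report the responsive fraction and medians of R² and σ over
responsive vertices only; empty cells carry NaN medians rather than zeros.
σ-vs-eccentricity and visibility-vs-eccentricity lines are ordinary least
squares (statsmodels); R²–σ association is Spearman rank correlation; gaze
stability is the per-axis median absolute deviation with runs under 10
valid samples excluded. Observer-task scoring collates 4AFC responses by
absolute bar-centre offset (11 discrete eccentricity levels; the 22
positions are the 25 sweep steps minus the 3 ambiguous central ones),
with slope contrasts against a reference condition via an interaction OLS
on the binned proportions.

## Problem sizes and determinism

All stochastic stages take explicit integer seeds (numpy Generator);
per-run sub-seeds are derived by hashing the master seed, so results are
independent of execution order. The test suite runs its simulations at
deliberately desk-scale sizes — 300 vertices for parameter recovery, 25–40
vertices per area for the mechanism checks, 2000 vertices for the null
calibration — chosen so the whole suite completes in a few minutes while
keeping the medians it asserts stable across seeds.

## Known limitations

* The fine stage optimises a non-convex objective from a single seed; with
  very high noise it can remain at a local optimum (it never degrades the
  seed, but it need not find the global one).
* σ estimates are biased slightly downward at low SNR under white-ish
  noise and upward under strongly autocorrelated noise; x₀/y₀ recovery is
  much more robust.
* The dot simulator models kinematics and membership, not photometry; it
  renders dot tables, not anti-aliased images.
* No multiple-testing correction is applied to correlation matrices, by
  design (matching the reporting convention the package follows).
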