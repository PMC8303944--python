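# Methods

## Forward model and its assumptions

The diffusion approximation for steady-state, spatially-resolved diffuse
reflectance from a semi-infinite homogeneous turbid medium is used as the
forward model.  A single isotropic source is buried at z₀ = 1/µt′ below the
surface and the boundary condition is imposed through an extrapolated
boundary at −z_b, z_b = 2AD, D = 1/(3µt′).  The internal-reflection
parameter A = (1 + r_d)/(1 − r_d) uses the Groenhuis empirical polynomial
r_d = −1.440 n⁻² + 0.710 n⁻¹ + 0.668 + 0.0636 n.  Defaults for the relative
refractive index: n = 1.33 for aqueous phantoms, n = 1.35 for fruit flesh;
both configurable.

Assumptions inherited from the model: homogeneous semi-infinite medium,
µa ≪ µs′ for the diffusion approximation to be accurate, flat sample
surface (no curvature correction — fruit curvature biases µs′ upward and is
out of scope here), single wavelength.

## Inverse fit

`fit_optical_properties` minimizes the sum of squared differences between
the log of measured intensity and log(amplitude · R(r)).  Choices:

- **Log-intensity loss.**  The profile spans two to three decades between
  the saturated core and the noise floor; a linear loss would be dominated
  by the few near-saturation bins.
- **Free amplitude.**  Measured intensities are camera digital numbers with
  an unknown gain, so a multiplicative amplitude is always fitted; at fixed
  coefficients its optimum is closed-form (mean log residual) and it is
  concentrated out, leaving a 1- or 2-parameter bounded problem.
- **Fit window.**  From two bins past the saturated plateau (clipped pixels
  carry no shape information) to the first bin under 5 % of the plateau
  (noise floor / quantization regime).
- **Optimizer.**  scipy's bounded trust-region least squares, three starts
  (box center and the two diagonal corners, nudged inside); ties within a
  1e-10 cost tolerance break toward the lower µa.  µa is floored at 1e-10
  because the model requires µa > 0.
- **Modes.**  Open range (wide default box), pre-classified (box = the class
  ranges predicted from the profile descriptors), or fixed-µa (known
  absorber, only µs′ fitted).  Fixed-µa plus an explicit µa bound range is
  rejected as contradictory.

## Profile extraction

Radial profiles are means over 1-pixel-wide annuli centered on the centroid
of the saturated area (equal-area circle radius of the saturated pixel
count gives DIP); sub-pixel annuli were rejected as adding nothing at the
0.01 cm pixel pitch.  The profile plateau is its maximum — the saturation
ceiling when the core clips — and the 75/50/25 % radii are first downward
crossings after the plateau, linearly interpolated between bins.  SLP is
the magnitude of the least-squares slope of ln(intensity) vs radius over
bins between Q1R and Q3R; natural logarithm.  Specular reflection spots are
scrubbed by replacing pixels that exceed 3× their annulus median (outside
the saturated core) with that median.

## Phantom calibration

The liquid-phantom design is a full factorial of 4 Intralipid 20 %
scattering levels (3.12–9.36 %) × 14 ink absorption levels (0–0.65 % in
0.05 % steps), 56 phantoms.  Composition maps to reference coefficients via
two measured calibration lines: µs′* = −0.003272 + 2.985451·C·20 % and
µa* = −0.0816·A − 0.0624.  The absorbance line as printed returns negative
values for positive absorbance — physically impossible — so the default
policy takes the magnitude, floored at 1e-10; a literal mode preserves the
raw line for audit.  Synthetic phantoms use a linear ink→µa map placing the
highest ink level at 0.70 cm⁻¹.

Class ranges partition the nominal levels at midpoints between neighbors.
A literal policy reproducing the published scattering ranges (0.1–2.5,
2.6–3.6, 3.7–4.8, 4.9–6.5 cm⁻¹) is provided because those printed ranges
differ slightly from exact midpoints.  The 14 absorption levels merge into
8 classes (six low pairs, two high singletons); the original grouping is
unpublished, so the mapping is configurable.

## Pre-classification

Flexible discriminant analysis by optimal scoring: ridge-regularized
(λ = 1e-8, for the strongly collinear radius descriptors) regression of
class indicators on standardized features, a generalized symmetric
eigenproblem for the optimal scores, and classification by weighted
distance to class centroids in score space minus 2·log(prior).  The weights
are inverse pooled within-class variances of the score coordinates, which
makes the rule exactly Mahalanobis — with a linear basis the decisions
coincide with classical LDA (verified against an independent implementation
in the tests).  The original analysis used an external FDA routine with an
unspecified basis; linear is the default here for determinism and because
the feature space is only five-dimensional, with an optional degree-2
polynomial expansion.  Pre-classification quality is reported by
leave-one-out cross-validation, per class and overall.

## Severity grading

Fruit are imaged at four positions (1, 2 equatorial; 3, 4 stylar end) and
features are aggregated as position means per region (se, eq) or whole
fruit (wf).  Cohorts are heavily imbalanced, so evaluation uses balanced
subsample sets — every severe fruit plus equally many randomly drawn sound
and moderate fruit — and, for two-class screening, pooling of sound +
moderate at a fixed ratio with largest-remainder rounding.  The default
per-class accuracy protocol is the confusion matrix of the fitted model on
its subsample set (matching how the original per-class tables were
produced); leave-one-out cross-validation is available and gives the less
optimistic estimate.  Severe-class screening quality is summarized by
precision, recall and F1 = 2PR/(P+R), with zero-denominator cases reported
as 0 and flagged.

## Synthetic data

Generators are pure functions of (spec, seed).  Images and radial profiles
are rendered as DN = clip(round(amplitude · R(r) · ε)), ε log-normal with
σ = 0.05 (a shot/speckle proxy; the real camera noise is uncharacterized),
8-bit ceiling, 10 frames averaged per acquisition, pixel pitch 0.01015625
cm, 1280 × 1024 sensor.  The source amplitude is calibrated once per study
(to saturate inside 0.1 cm for the mean design composition) and held fixed
across samples, as a constant-power laser would — the size of the saturated
area then varies with the sample and carries information.  Cohort and
phantom generators default to rendering the radial profile directly rather
than full frames (identical radiometry, far cheaper); full-frame rendering
is exercised on smaller sensors in the tests.

Fruit cohorts default to 320 sound / 64 moderate / 12 severe.  The effect
model is multiplicative on sound-class means (µa = 0.20 cm⁻¹, µs′ = 3.0
cm⁻¹, chosen inside the phantom calibration range; with multiplicative
effects and a multiplicative CV the class separation is invariant to this
choice): severe ×1.3 on µa and ×1.35 on µs′, moderate ×1.2 on µs′ only,
10 % coefficient of variation between fruit, full effect at the stylar end
and half at the equator (injury develops from the stylar end).

What the generators deliberately do not emulate: fruit surface curvature,
skin/flesh layering, trichome scattering, wavelength dependence, flat-field
or stray-light artifacts, and — most consequentially — any mismatch between
the rendering model and the fitting model.  Passing round-trip tests
therefore demonstrate the correctness of the extraction and inversion
machinery, not field performance on real fruit, where model mismatch
dominates the error budget.

## Known limitations

- With matched forward and inverse models, open-range inversion of
  synthetic profiles is nearly unbiased; the large over-estimation of µs′
  observed on measured low-scattering phantoms (an instrument/model
  mismatch effect) is not reproduced by these study conditions.
- The whole-fruit severity signal under the default effect model supports a
  severe-class true-positive rate in the mid-80s (%): the equatorial
  half-effect dilutes severe-vs-moderate separation to ≈2σ, which an
  optimal classifier on the true coefficients cannot exceed either.
  Stylar-end features classify severe injury best, whole-fruit next,
  equatorial worst.
- The absorption pre-classifier is close to chance at the default 8-class
  resolution on noise-free synthetic phantoms; absorption steps of
  ~0.1 cm⁻¹ barely move the profile descriptors.  Coarser partitions
  improve it at the cost of wider fit bounds.
- Problem sizes in the test suite (sensor crops, cohort sizes for CLI
  smoke tests, replicate counts) are the package's own desk-scale choices;
  the study-level defaults (56 phantoms, 320/64/12 cohorts, 10 subsample
  sets, 20 replicates) match the study conditions.
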