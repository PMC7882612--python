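# Methods

This note records the modeling choices behind `flymosaic`: what each stage
assumes, which knobs matter, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Spectral plumbing

Spectra live on a uniform wavelength grid; the default is 300–700 nm at 1 nm,
which spans both the near-UV band where the orange daisies carry a secondary
reflectance peak and the 400–700 nm visible band. CSV input requires strictly
increasing, uniformly spaced wavelengths; negative reflectance values
(spectrometer noise around dark samples) are clipped to zero with a logged
warning, and reflectance above 1.5 is rejected as a calibration error rather
than clipped. Resampling is linear interpolation; a coverage shortfall of up
to 5 nm at either grid edge is filled with the terminal value, anything
larger is an error — silent extrapolation of spectra is never acceptable.

The bundled illuminant is the CIE D65 relative spectral power table (5 nm,
300–830 nm). Because photoreceptors count photons, the table is converted to
relative photon flux (power × λ) before quantum-catch integration and
max-normalized; the conversion is exposed as `photon_units` because some
published catch calculations work in energy units. An equal-energy
illuminant is available for sensitivity analysis. Note the von Kries step
makes all vision-plane coordinates invariant to any *scalar* rescaling of
the illuminant, so the photon/energy choice only matters through its
λ-dependent shape.

Receptor sensitivities for hoverfly-like eyes are not tabulated here; the
package ships a visual-pigment template instead: the A1 rhodopsin alpha-band
nomogram (the Govardovskii-type exponential form), max-normalized, with
default peaks R7p 330 nm, R7y 350 nm, R8p 460 nm, R8y 530 nm. These defaults
are documented stand-ins — two UV-peaking R7 classes, a blue and a green R8
class — and are overridable per receptor, or replaceable wholesale by
tabulated CSV curves. The beta (UV) band of the template is deliberately
omitted so each sensitivity is unimodal; for the R8 classes a beta band
would add a spurious UV shoulder that the opponency pairing would
misinterpret, and its parameters for these flies are unknown anyway.

## The opponency plane

Quantum catches are trapezoidal integrals of R·I·S on the common grid
(verified in tests against 0.1 nm brute-force integration to 0.1%). Per
image, catches are averaged across floret regions *before* the excitation
transform — averaging catches first matches how multi-region image data are
reduced, and at the catch level the mean is the physically meaningful
photon average.

The published description of this fly color-vision model fixes the receptor
pairing (R7p vs R8p, R7y vs R8y) but not the excitation transform. We use
the hyperbolic form e = q/(q+1) after von Kries adaptation because it (a)
maps the adapting background to the exact origin, which is required for
"distance from the origin" to mean contrast against the background, and (b)
bounds both coordinates in (−1, 1). A `linear` transform (e = q/2) is
available as a sensitivity check; it preserves the origin property but not
boundedness.

Quadrant membership is decided by coordinate signs with a 1e−12 tolerance:
coordinates within tolerance of an axis are labeled `boundary` rather than
being pushed into an arbitrary quadrant, so detectability verdicts cannot
flip on floating-point noise. Discrimination thresholds are only known for
two quadrants (0.021 in p−y−, 0.059 in p+y−); verdicts elsewhere are
`unknown` by design, and applying the thresholds to centroid *separations*
(discriminability) is a guide only, not a calibrated test. Welch's t-test
(unequal variances, Welch–Satterthwaite df) compares detectability across
soils; it is two-sided by default with a `one_sided` flag for the
directional native-soil question.

## Mosaic regressions

Site density is the sum over plant species of flies-per-flowerhead ×
flowerheads-per-m²; it is additive and scale-linear by construction, and the
density covariate enters the regression untransformed (no log or
standardization — a config hook exists, but the default mirrors a
plain density-in-individuals-per-m² analysis).

Ordinary logistic MLE uses Newton–Raphson with step-halving, score tolerance
1e−8, 100 iterations. Separation is flagged — not "solved" — two ways:
a coefficient guard (|β| > 50) and a perfect-prediction check (all fitted
probabilities within 1e−4 of their outcomes at a stationary point), because
under complete separation the score can vanish numerically while the true
maximizer is at infinity.

The Firth fit maximizes the Jeffreys-penalized likelihood
ℓ*(β) = ℓ(β) + ½ log det I(β) by modified-score Newton iterations
(score component j: Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) x_ij with hat values hᵢ of the
weighted design). The penalized surface is extremely flat in the slope
direction under separation, so the Firth solver gets a larger budget (500
iterations) and also accepts convergence when the accepted step length falls
below 1e−7 with the estimate stabilized. Primary inference is the penalized
likelihood-ratio test (refit with the slope fixed at zero); Wald z/p are
reported as secondary output. On the canonical 2×2 separated table the
penalized maximizer reproduces the half-cell-correction closed form
(slope ln 49), which the tests verify against an independent dense grid
search.

Sites where no focal species occurs have no color code and are excluded
from the regression — the analysis is conditional on occupancy. A site with
both colors present violates the binary coding's premise and raises an
error instead of being silently recoded.

## GEE choice analysis

One row per recorded choice, response 1 = orange chosen, treatment coding
with fixed reference levels (white-community fly species, pale soil, pre
phase) so coefficient signs are reproducible. Flies that never visited
flowers on both soil types are excluded at design-build time (they carry no
within-fly information about the soil effect), with a log entry listing
them.

Estimation is Liang–Zeger Fisher scoring on the estimating equations with an
exchangeable working correlation. Dispersion φ is fixed at 1 for binary
data (moment estimation available behind `estimate_phi`); α is
moment-estimated from within-cluster Pearson residual cross-products each
iteration and clipped into its admissible range with a warning if needed.
With singleton clusters the fit reduces exactly to the independence logistic
MLE (tested to 1e−8).

"Approximate jackknife" variance is implemented as the one-step
(influence-function) leave-one-cluster-out jackknife:
β₍ᵢ₎ = β̂ + (H − Hᵢ)⁻¹ Uᵢ, covariance (K−p)/K Σ (β₍ᵢ₎ − β̄)(β₍ᵢ₎ − β̄)ᵀ. A
full-refit jackknife is available behind `jackknife="full"` as the
validation oracle (tests check the two agree), and the plain sandwich
covariance is always reported alongside. Simulations in the test suite show
95% EMM intervals cover the generating marginal preference in far more than
85% of replicates and the species Wald test holds its nominal 0.05 size
(within [0.02, 0.09]) at 60 clusters.

Estimated marginal means fix the factors named in `at` and average the
linear predictor over the remaining factors' levels with equal weight; CIs
are back-transformed from the link scale, so they always lie inside (0, 1).
Genus pairs are analyzed separately (pooling is possible but non-default),
matching how such experiments are run — each fly is tested per genus pair.
Conditioning is tested as a phase term in a per-species GEE whose clusters
span a fly's pre and post choices.

## Synthetic data

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

*Spectra* are a flat base + logistic step + Gaussian peaks + truncated
Gaussian noise, clipped to [0, 1]. White daisies: step to a high plateau at
~410 nm (UV-dark). Orange daisies: step at ~565 nm plus a near-UV Gaussian;
the two orange species differ in that peak's position and intensity
(350 nm/0.22 vs 336 nm/0.30) while the two white species are nearly
identical — the qualitative contrast the real spectra show. Pale granite
soil is moderately bright and gently rising; red sand is dark below ~550 nm.
What this does **not** emulate: within-capitulum reflectance gradients,
specular effects, sensor noise correlated across wavelengths, or soil
granularity — so passing tests demonstrate the pipeline's correctness on
well-behaved spectra, not robustness to instrument pathologies.

*Landscapes* default to 54 sites. Per-site fly density is zero-inflated
log-normal: the orange-community fly with absence probability 0.35 and
log-normal(log 0.35, 0.9), the white-community fly with 0.5 and
log-normal(log 0.8, 0.9) — chosen so the upper range of draws reaches the
field maxima of roughly 1.7 and 3.7 individuals m⁻² respectively. Site
color is Bernoulli(logit⁻¹(−1.5 + 3.0·density)); `separation_mode` instead
codes a site orange exactly when the white-community fly is absent,
reproducing complete separation. Densities are factored into
flies-per-flowerhead × flowerheads-per-m² across 3 plant species (Dirichlet
shares; flowerhead densities uniform on 2–30 m⁻²) so the reassembled site
density equals the drawn one to machine precision. Not emulated: spatial
autocorrelation between sites, observation error in the surveys.

*Choices* use beta-mixed per-fly preferences: p_i ~ Beta(a, b) with the
species' marginal mean and concentration a+b = 10, choices i.i.d.
Bernoulli(p_i) given p_i. This induces exactly the exchangeable correlation
the GEE assumes, with closed form α = 1/(a+b+1) ≈ 0.091 — deliberately, so
the working-correlation estimate has an oracle value. Defaults mirror the
larger published experiment: 47 and 20 flies, orange-choice preferences
0.91 and 0.20 (i.e., an 80% white preference), geometric sequence lengths
with median 5 truncated at 20 choices, soils assigned 50:50 per choice. Not
emulated: order effects within a sequence (the correlation is exchangeable
by construction), nectar depletion, or soil-dependent detectability of the
flowers — first-choice counts in synthetic data are null by construction.

All generators are pure functions of (params, seed) via NumPy's
`default_rng`, so outputs are identical across runs and platforms.

## Numerical conventions and limitations

- Integration: trapezoid on the common grid; no adaptive quadrature.
- Boundary conventions: detectability uses ≥ (a distance exactly at
  threshold is `detectable`); quadrant boundary tolerance 1e−12.
- Degenerate inputs: all-0/all-1 responses, empty clouds, empty region
  lists, single-phase conditioning data, and mixed-color sites all raise
  typed errors rather than returning defaults.
- Problem sizes in the test suite and acceptance script (5 images per
  species×soil, 54 sites, 200–500 simulation replicates at 60 clusters) were
  chosen to estimate the relevant rates stably while keeping a full run in
  tens of seconds.
- The receptor λmax defaults and the excitation transform are the two
  modeling choices a user should challenge first when porting to another
  fly taxon; both are single config switches.
- The package does not model receptor noise (RNL), achromatic channels,
  inter-ommatidial opponency, bee color spaces, spatial autocorrelation of
  landscapes, or conditional (random-effects) choice models — the choice
  inference is marginal by design.
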