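# flymosaic

Tools for asking whether landscape-scale flower-color structure in annual
daisy communities can be explained by a geographic mosaic of fly pollinators
with divergent color preferences. The package is aimed at pollination
ecologists who have (or want to prototype with) three kinds of data:

1. **Reflectance spectra** of daisy ray florets and soil backgrounds, to ask
   whether orange and white flowers are *detectable* and *distinguishable* in
   fly vision;
2. **Site surveys** of fly densities, to ask whether the dominant flower
   color of a site is predicted by pollinator availability;
3. **Arena choice experiments** with sequential, within-fly-correlated flower
   choices, to ask whether the flies have divergent (and conditionable)
   color preferences.

Because such field data are rarely deposited, a seeded synthetic-data
generator (`flymosaic.synth`) produces spectra, landscapes, and choice
sequences with the statistical structure the analyses assume, so the whole
pipeline runs and is tested end to end without any downloads.

## The models

**Fly vision.** For receptor *r* with spectral sensitivity *S_r(λ)*, stimulus
reflectance *R(λ)* and illuminant *I(λ)* (CIE D65 in photon units by
default), the quantum catch is

    Q_r = ∫ R(λ) I(λ) S_r(λ) dλ        (trapezoid, 300–700 nm, 1 nm)

Catches are adapted to the background (von Kries): *q_r = Q_r / Q_r(bg)*,
transformed to excitations *e_r = q_r / (q_r + 1)*, and combined into two
opponent coordinates

    x = e_R7p − e_R8p,    y = e_R7y − e_R8y

so the adapting background sits exactly at the origin. The four quadrants of
the (x, y) plane act as discrete color categories; distance from the origin
measures detectability against the background (compared with behavioral
discrimination thresholds of 0.021 in the p−y− quadrant and 0.059 in p+y−),
and distance between species centroids measures discriminability. Welch's
*t*-tests compare detectability across soils.

**Pollinator mosaic.** Site fly density is Σ (flies per flowerhead ×
flowerheads per m²) over plant species. Binary site color (orange = 1) is
regressed on density by ordinary logistic MLE and by Firth's bias-reduced
logistic regression, which maximizes ℓ(β) + ½ log det I(β) and stays finite
under the complete separation that a qualitative pollinator mosaic produces;
inference for the Firth fit uses penalized likelihood-ratio tests.

**Choice experiments.** Flower-color choice (orange = 1) is modeled with a
binomial-logit GEE with exchangeable working correlation across each fly's
choices, variance by an approximate (one-step) leave-one-cluster-out
jackknife, Wald tests per term, and estimated marginal means with 95% CIs on
the probability scale. First-choice soil counts get a 1-df chi-square
(*χ²* = (a−b)²/(a+b)), and conditioning experiments are tested as a phase
contrast in the GEE.

## Worked example

```sh
flymosaic --seed 1 --out demo vision --plot
flymosaic --seed 1 --out demo mosaic
flymosaic --seed 1 --out demo choice
```

The vision stage writes `demo/vision/points.csv` (one row per modeled
image):

```
image_id             species      soil   x         y         quadrant  dist_origin  verdict
D_pluvialis_pale_01  D_pluvialis  pale  -0.530371 -0.486679  p-y-      0.719827     detectable
```

and a per-soil centroid-distance matrix. With the default synthetic spectra,
white species land in the p−y− quadrant and orange species in p+y+; the
white–orange centroid separations (≈ 0.97–1.08) are more than an order of
magnitude above the 0.021/0.059 thresholds, while the two white species are
nearly coincident (≈ 0.002–0.006) — so a fly should distinguish orange from
white easily but not one white species from the other.

`demo/mosaic/mosaic_report.json` reports both fits for each model; with the
default landscape (54 sites, logistic slope 3.0 linking density to color)
the MLE slope test gives z ≈ 3.01. On a separation-mode landscape the MLE is
flagged `separated` while the Firth slope stays finite.

`demo/choice/choice_report.json` shows the recovered preferences: the
orange-community fly chooses orange with estimated marginal probability
0.899 (CI 0.848–0.934), the white-community fly 0.209 (CI 0.130–0.319), a
species Wald of 81.1 (p < 0.001), soil and interaction terms
non-significant, and working correlation α ≈ 0.083 — close to the
generator's beta-mixing value 1/11.

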