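# Methods

## Overview

`hexaflora` models how a trichromatic hymenopteran pollinator (the honeybee
is the reference visual system) perceives flower reflectance spectra, and
relates the resulting visual signals — chromatic *colour contrast* and
achromatic *green contrast* — to flower size and elevation in a
phylogenetically informed regression framework. The pipeline was designed
for community-scale studies in which several hundred species are measured
with a field spectrophotometer, assigned to elevational zones, and analysed
per zone with phylogenetic generalized least squares (PGLS) and single-trait
phylogenetic-signal tests.

## Colorimetric model

A reflectance spectrum R(λ) on the common 300–700 nm grid (1 nm steps,
linear interpolation onto the grid) is viewed against a green-foliage
adaptation background B(λ) under a daylight-like illuminant I(λ). For each
receptor class i ∈ {UV, blue, green} with sensitivity S_i(λ):

* quantum catch, trapezoid rule:
  `P_i = ∫ R I S_i dλ / ∫ B I S_i dλ` — the denominator is the von Kries
  adaptation term, so the background yields P = 1 in every receptor and any
  positive rescaling of the illuminant cancels exactly;
* transduction: `E_i = P_i / (P_i + 1)`, so the background sits at E = 0.5;
* hexagon coordinates: `x = (√3/2)(E_g − E_uv)`, `y = E_b − (E_uv + E_g)/2`;
* colour contrast `cc = √(x² + y²)` (distance from the achromatic centre);
* green contrast `gc = |0.5 − E_g|` (the achromatic detection signal).

The background therefore maps exactly to cc = gc = 0, cc ≤ 1 and gc ≤ 0.5
for excitations in [0, 1], and loci are invariant to illuminant intensity.
These closed-form anchors are what the geometry tests assert.

Loci are labelled with one of six 60° hexagon sectors (UV, UV-blue, blue,
blue-green, green, UV-green; the pure-UV direction points at the UV vertex)
and flagged as achromatic when cc falls below a configurable radius,
default 0.11 hexagon units — a commonly used behavioural discrimination
threshold; the radius is a display/classification device and enters no
statistic.

### Standard curves

All standard curves are computed from closed forms rather than shipped as
tables:

* **Receptor sensitivities** — Govardovskii A1 visual-pigment nomogram
  (alpha band four-exponential template plus the Gaussian beta band) with
  peak wavelengths 344, 436 and 544 nm, the classic honeybee UV/blue/green
  values, each normalised to a maximum of 1. The beta band pulls the
  realised UV peak ≈2 nm short of the template λmax; this is a property of
  the template, not an error.
* **Illuminant** — a 6500 K blackbody expressed as photon flux (quantum
  units), normalised at 500 nm. Because of von Kries adaptation only the
  *shape* of the illuminant matters, and any smooth daylight-like curve
  gives nearly identical loci.
* **Background** — a parametric green-leaf reflectance: 5 % base, a
  chlorophyll bump to ~15 % at 550 nm, and the start of the red edge just
  below 700 nm.

Replicate flowers (typically 3–5 per species) are averaged *as spectra*
before modelling by default; averaging hexagon loci instead is available as
a configuration switch (`average_spectra_first: false`) and differs only
marginally for low replicate noise because the whole chain is smooth.

Negative reflectance readings (instrument noise near the dark reference)
are clipped to 0 with a logged count; values slightly above 1 are retained
because glossy petals can exceed a diffuse white standard.

## Phylogenetic statistics

The among-species covariance is the shared-branch-length matrix C of a
rooted tree with branch lengths: C[i,i] is the root-to-tip depth and C[i,j]
the depth of the most recent common ancestor. Polytomies are handled
natively by this definition; trees are never randomly resolved. Pruning
keeps path lengths and collapses unifurcations.

Pagel's λ rescales the off-diagonal part: C(λ) = λC + (1−λ)diag(C). The
largest admissible λ (`lambda_max`, the positive-definiteness boundary) is
computed from the minimum eigenvalue of the off-diagonal correlation
matrix; on ultrametric trees it slightly exceeds 1, which is why
single-trait λ estimates marginally above 1 can legitimately occur.

### PGLS

For fixed λ the GLS estimate is β̂ = (XᵀC(λ)⁻¹X)⁻¹XᵀC(λ)⁻¹y. λ is estimated
by maximising the ML profile log-likelihood

    lnL(λ) = −½[n·ln(2π σ̂²_ML) + n + ln|C(λ)|],  σ̂²_ML = eᵀC(λ)⁻¹e/n

with a 33-point grid pre-scan followed by bounded Brent refinement
(tolerance 1e-6 in λ) — the grid guards against local optima in the
profile. The search interval is [0, 1] for regression (the convention of
the standard comparative-methods regression implementations) and
[0, lambda_max] for single-trait signal estimation (the convention of
`phylosig`-style tools). ML rather than REML is used in both, matching the
defaults of the reference implementations this package was validated
against (ape/nlme `corPagel` and phytools `phylosig`; agreement to ≥6
decimals on a 20-taxon fixture with polytomies is frozen into the tests).

Every likelihood evaluation reuses a single symmetric eigendecomposition of
the correlation-scaled covariance (cached on the covariance object), so a
full ML fit costs O(n²) after an O(n³) setup; hundreds of fits on 300-taxon
trees take seconds.

Standard errors use the unbiased σ̂² = eᵀC(λ)⁻¹e/(n−p); t statistics have
n−p degrees of freedom with two-sided p-values. The 95 % CI for λ is the
profile-likelihood interval at the χ²₁ cutoff. AIC = 2k − 2lnL with k
counting the β's plus σ² and λ. The GLS R² compares the model's weighted
residual sum of squares with that of the intercept-only model at the same
λ, and is reported in adjusted form. When λ is estimated near its upper
boundary C(λ) approaches singularity and the intercept-only weighted RSS
can grow without bound, inflating R²; interpret R² cautiously for boundary
fits.

### Model set and selection

For each elevational zone the response is green contrast and the candidate
predictor forms for colour contrast are linear (Y = β0 + β1·X), quadratic
(Y = β0 + β1·X² + β2·X) and logarithmic (Y = β0 + β1·ln X, natural log;
a zero-valued predictor under the log model is an error, never silently
offset). Flower size enters a separate linear model. Candidates are ranked
by AIC; models within ΔAIC < 2 of the best are treated as ties and broken
by higher adjusted R² (equal values: first listed wins).

### Phylogenetic signal

Single-trait λ is the ML estimate under an intercept-only Brownian model on
the λ-transformed tree, searched on [0, lambda_max]. The test against λ = 0
is a likelihood-ratio test on χ²₁. Because λ = 0 lies on the boundary of
the parameter space this reference distribution is conservative; simulated
type-I error at the 5 % level is well below nominal (asserted ≤10 % in the
validation suite).

## Elevational zones and summaries

Zones are half-open bins of the species' mean elevation (mean of the
reported range): Foothills [0, 500), Submontane [500, 1500), Montane
[1500, 2500), Upper-montane [2500, 3000), Alpine [3000, ∞) m a.s.l. The
published zone definitions leave the interval just below 3000 m ambiguous;
the package closes it at 3000 m so every elevation belongs to exactly one
zone. Species are assigned to exactly one zone.

Per-zone summaries report, for gc, cc and size: the mode of the continuous
sample — Gaussian KDE with Silverman bandwidth, argmax over 512 grid points
spanning the data range (at least 3 values required) — and the mean with a
t-based 95 % CI.

## Synthetic-data generator

The generator produces data with the structure the analysis assumes, so
every stage is testable without downloads:

* **Tree** — Yule (pure birth) tree conditioned on n tips; the clock runs
  an extra Exp(n·birth-rate) time past the nth birth so pendant edges are
  positive; scaled to unit height; 20 % of internal nodes (default) are
  collapsed into polytomies preserving tip depths, so the tree stays
  ultrametric.
* **Colour contrast** — latent Brownian motion with a λ transform (default
  λ = 0.5, unit rate on the unit-height tree) squashed logistically into
  (0, 0.65). The ceiling is deliberately below the hexagon's theoretical
  maximum of 1: loci with cc near 1 are not attainable by physical
  reflectance spectra viewed against green foliage, and the spectra
  inverse-design stage must be able to realise every target.
* **Green contrast** — gc = β0 + β1·cc (+ β2·cc²) plus phylogenetically
  structured noise (same λ-transformed covariance), clipped to [0, 0.5];
  defaults β0 = 0.15, β1 = 0.25, β2 = 0, noise sd 0.05 keep clipping rare.
  All values clipped at a bound is a configuration error.
* **Zones and sizes** — species are apportioned to the five zones by
  largest remainder with the observed community proportions
  (183/258/170/67/36 of 714); elevation is uniform within the zone bin
  (alpine capped at 3300 m, the highest sampling elevation); flower size is
  log-normal with log-location declining linearly in elevation
  (14.5 mm at sea level, slope 8×10⁻⁵ per metre, log-sd 0.45), matching the
  observed decline from ~14 mm (foothills) to ~11 mm (alpine).
* **Spectra** — each species' curve is a brightness-scaled blend of the
  foliage background (the achromatic direction: a scaled background has
  cc = 0 at any brightness) and a random smooth flower profile (sigmoid
  step plus Gaussian band). The two free parameters (blend, brightness) are
  solved by bounded least squares so the resulting hexagon locus hits the
  species' target cc *and* target green-receptor excitation (gc = |0.5−E_g|
  admits a bright and a dark solution; both are tried). Species whose best
  design still misses cc by more than 0.05 are flagged. Replicates (3–5)
  add smooth perturbations (Gaussian control points every 50 nm,
  interpolated; sd 0.005) mimicking between-flower variation rather than
  white instrument noise.

What the generator does **not** emulate: instrument artefacts (dark-current
drift, stray light), pigment-level constraints linking cc and gc beyond the
regression, spatial/temporal sampling structure, and measurement error in
size or elevation. Passing round-trip tests therefore demonstrate that the
statistical machinery recovers known structure through the full spectral
chain — not that any particular field dataset satisfies the model.

## Problem sizes used in validation

The validation suite and the acceptance script use: 100 replicates per true
λ ∈ {0, 0.5, 1} on 300-tip trees (10 trees × 10 traits) for λ recovery; 100
replicates at n = 200 for quadratic model selection; one 300-species
synthetic community for the end-to-end round trip, whose pooled PGLS slope
must sit within twice its standard error of the generating β. The
eigendecomposition reuse makes these sizes run in seconds to minutes on one
CPU.

## Known limitations

* λ estimates at the search boundary make the profile CI one-sided and the
  GLS R² unstable (see above).
* The hexagon model assumes honeybee-like trichromacy; receptor-noise
  limited or tetrachromatic (bird) spaces are out of scope.
* The inverse spectral design spans a two-parameter family; real floral
  spectra with sharp multi-band structure can realise loci the family
  cannot, which only matters for the generator, never for analysing
  measured spectra.
* Reported λ values per regression are estimated per fitted model; when a
  zone's candidate models disagree in λ̂ the selected model's value is the
  one to quote.
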