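# Methods

`islandtone` re-creates, on synthetic data with known ground truth, the
computational chain used to study convergent plumage darkening ("island
melanism") in songbirds: spectral summarisation, multivariate trajectory
statistics, binary-trait phylogenetic signal, receptor-noise camouflage
modelling, and a biophysical heat-flux model. This note records the models,
their assumptions, the defaults that matter, and the places where the design
was genuinely open.

## Solar-weighted reflectance (`spectra`)

Reflectance spectra live on a 1-nm grid from 350 to 2500 nm. The scalar
summary is the irradiance-weighted band mean

    R_sw = ∫ R(λ) I(λ) dλ / ∫ I(λ) dλ          (trapezoidal, per band)

with bands UV 350–400, VIS 400–700, NIR 700–2500, FULL 350–2500. Because
only ratios of I enter, the packaged solar curve is relative: a 5778 K
Planck envelope with Gaussian telluric water-vapour dips (a synthetic
stand-in shaped like standard dry-air reference spectra; see
`synthetic.gen_solar_spectrum`). R_sw is invariant to rescaling I, and the
FULL value decomposes exactly into the irradiance-weighted combination of
the UV/VIS/NIR values because the bands share grid nodes.

Per-wavelength "solar-corrected" matrices use r(λ)·I(λ)/mean(I); dividing
by the mean irradiance keeps values on the reflectance scale. A `mode="raw"`
switch passes spectra through untouched for analyses that want uncorrected
values. Divergence between cohorts is (island − mainland)/island × 100 per
100-nm bin (positive = island reflects more), tested with Welch t-tests and
a Holm–Bonferroni correction across bins. The final 2450–2500 half-bin is
kept and flagged. Raw reflectance above 1.05 is rejected as a calibration
failure; values in (1, 1.05] are clipped with a warning.

## Trajectory analysis (`trajectory`)

Each taxon's divergence vector runs from the mainland centroid to the
island centroid in wavelength space. Length is the Euclidean norm; pairwise
orientation is reported both as the vector correlation (cosine) and the
angle, which satisfy r = cos(θ) identically. Disparity is the mean squared
distance of taxon centroids from their pooled centroid, computed separately
for island and mainland taxon sets; lower island disparity indicates
convergence sensu stricto. (The centroid-level definition was an open
choice; specimen-level variance would weight cohort sizes, which is
undesirable when sample sizes differ sixfold across taxa.)

Permutation tests shuffle mainland/island labels within each taxon,
excluding the observed labelling from the draw (the p-value's +1 term
counts it): p = (#{null ≥ obs} + 1)/(n_perm + 1). Length differences are
tested two-sided on |L_i − L_j|; orientations one-sided toward convergence
(null angle ≤ observed). PCA is covariance-based (the variables share
units) and loadings are returned so the sign conventions behind "PC1 =
achromatic brightness" interpretations are auditable.

## Fritz–Purvis D (`phylosignal`)

The statistic d sums, over internal nodes, the absolute difference of
daughter nodal values, where nodal values are equal-weight averages
propagated from the tips (the original estimation scheme; branch lengths do
not enter d). D scales d_obs between the means of two nulls:

    D = (d_obs − mean d_Brownian) / (mean d_random − mean d_Brownian)

d_random comes from shuffling tip states; d_Brownian from variance-1
Brownian simulations thresholded per simulation at the observed prevalence
(top-k tips get state 1). p_random is the fraction of random-null d values
≤ d_obs (small = more clumped than chance); p_brownian the fraction of
Brownian d values ≥ d_obs. Trees are flattened to index arrays so one
bottom-up pass scores a whole matrix of trait vectors; the 1000-permutation
default is cheap. Calibration (acceptance suite): across 200 fifty-tip Yule
trees the mean D is within 0.1 of 1 for shuffled traits and within 0.1 of 0
for Brownian-threshold traits.

## Receptor-noise visual model (`vision`)

Quantum catches are Q_i = ∫ R I S_i dλ with sensitivities from the
Govardovskii A1 template (alpha plus beta band, unit peak). Signals are
log-linear, f_i = ln Q_i (appropriate for large contrasts), von
Kries-normalised to the background, making ΔS and ΔL exactly invariant to
illuminant intensity. Chromatic contrast uses the n-receptor
noise-limited formula

    ΔS² = Σ_{i<j} (Π_{k≠i,j} e_k²)(Δf_i − Δf_j)² / Σ_i Π_{k≠i} e_k²

with e_i = ω √(η_max/η_i); achromatic contrast is ΔL = |Δf_D|/ω_D through
the double cone. The dichromat closed form |Δf₁ − Δf₂|/√(e₁²+e₂²) is used
as an independent check of the general formula.

None of the receptor parameters are measured here. Presets follow common
practice for the two raptor-relevant viewer classes: violet-sensitive
(peafowl-like peaks 424/477/537/605 nm, densities 1:1.9:2.2:2.1) and
ultraviolet-sensitive (blue-tit-like 371/448/503/563 nm, densities
1:1.78:2.21:1.96), ω = ω_D = 0.1 on the most abundant cone. Every value is
overridable, and results should always be reported with the parameter set
used. Contrast thresholds of 2.0 (standard) and 1.0 (favourable
conditions) are exposed as constants. Group comparisons average each
specimen's contrast over all background samples, then report group means
with percentile bootstrap 95% CIs (default 2000 replicates) and a
two-group OLS p-value for the mainland−island difference.

## Smoothest-reflectance reconstruction (`srgb2spec`)

Soil backgrounds arrive as 8-bit sRGB triples. The reconstruction solves

    min Σ_i (R_{i+1} − R_i)²   s.t.   A R = linear-RGB target

on a 380–730 nm, 10-nm grid, as a single KKT linear system. A maps spectra
through observer colour-matching functions, the colorimetric illuminant
(D65) and the XYZ→sRGB matrix, and is row-normalised so a perfect reflector
maps exactly to linear (1,1,1); greys therefore reconstruct to flat spectra
and round trips are exact to machine precision for in-gamut colours. The
colour-matching functions are the Wyman–Sloan–Shirley multi-lobe Gaussian
fit of the CIE 1931 2° observer — an analytic approximation accurate to
about a percent, which is irrelevant here because every consumer of these
spectra (visual modelling) sees the same system the round-trip checks use.
Colours whose exact solution leaves [0, 1] (saturated primaries; never
desaturated soils) are flagged, clipped, and returned with the achieved
colorimetric error rather than re-solved with inequality constraints.
Visible-grid reconstructions are extended to the pipeline grid by constant
extrapolation of the terminal values (soil UV/NIR is unmeasured in the
source colours), flagged via `patch="extrapolated"`.

## Heat-flux model (`heatflux`)

The bird is a feathered sphere: an isothermal core at T_b = 41 °C, a
plumage slab of conductance K_p = k_p·A_skin/depth in series with a
boundary conductance K_b = (h_conv + h_rad)·A_outer, where h_conv follows
the sphere correlation Nu = 2 + 0.6 Re^½ Pr^⅓ and h_rad = 4εσT³. Solar
radiation absorbed at the plumage surface (dorsal absorptance α_d = 1 −
R_sw weights direct and diffuse; ventral absorptance weights the
ground-reflected component; all intercepted over the silhouette area)
raises the operative temperature

    T_e = T_a + S_surface/K_b + S_skin/K_e,

where S_skin is the direct beam transmitted through the plumage
(τ = τ₀ e^{−depth/d₀}) and deposited at the skin — folding it into T_e keeps
the steady-state identity exact. The balance is then

    Q = M − E = K_e (T_b − T_e),   K_e = (1/K_p + 1/K_b)⁻¹.

Metabolic production is M = max(BMR, Q); evaporation balances the books
(E = M − Q), so conservation holds to machine precision at every hour.
Heating cost is max(0, Q − BMR)/BMR × 100 (basal heat is assumed fully
available against the sensible load — an open partitioning choice exposed
in config); cooling converts max(0, −Q) to water via the latent heat
2.41 J/mg and is reported as % body mass per hour. An optional
heterothermy band lets T_b sag toward T_e before costs accrue. Daylight is
solar zenith < 90°.

Morphology comes from mass allometries with every coefficient in
`HeatFluxConfig`: sphere-equivalent diameter at body density 1000 kg/m³,
plumage depth 0.023·m_kg^⅓ (≈6 mm at 20 g), BMR = 0.04·m_g^0.669 W
(passerine-scale). The plumage conductivity default, 0.05 W m⁻¹ K⁻¹, is an
*effective* value: still air conducts ≈0.026, and radiative transfer plus
wind penetration through the coat roughly double it; with it, small birds
in the cool island climate incur heating costs through ~95% of daylight
hours, the physiologically expected regime. The transmittance scale and
this conductivity are documented approximations — the coefficients are
deliberately config-versioned so a more detailed parameterisation can be
slotted in without touching the solver.

The NIR counterfactual builds a chimeric spectrum (island values below
700 nm, mainland values above), recomputes solar absorptance, and compares
evaporative water loss against the unmodified island phenotype — the
question being whether elevated distant-NIR reflectance in the darkest
island taxa buys meaningful water savings. Under the packaged island
climate, cooling loads are rare and the savings are orders of magnitude
below physiological relevance.

## Synthetic data (`synthetic`)

The generators define the study conditions; they are first-class, tested
code. Cohort sizes mirror the museum sample (scrub-jay 33/35, horned lark
30/19, house finch 30/15, orange-crowned warbler 29/20, spotted towhee
30/20, rufous-crowned sparrow 10/23). Each taxon's mainland curve is a
common smooth base (logistic VIS-to-NIR ramps) times a taxon brightness
tint; the island curve multiplies it by a piecewise-flat curve: exactly the
VIS multiplier below 700 nm, a smoothstep transition to the NIR multiplier
by the changepoint (default 900 nm), exactly the NIR multiplier beyond.
Flat levels make the true VIS divergence closed-form,
(1 − 1/vis_mult)·100. Defaults: three strongly melanic taxa with elevated
distant-NIR (vis multipliers 0.52–0.68, NIR 1.12–1.18), two mildly melanic,
and the rufous-crowned sparrow as a weak opposite-direction outlier.
Brightness tints vary on the mainland while island VIS levels cluster near
a common dark value, so island disparity comes out below mainland disparity
— the convergence signature the trajectory module is built to detect.
Specimen noise is a lognormal whole-spectrum scale (σ = 0.08) plus
wavelength-autocorrelated perturbations (white noise smoothed with a 50-nm
moving average, σ = 0.01), clipped to [0, 1].

What the generator does *not* emulate: pigment-specific spectral shapes
(carotenoid/melanin absorption bands), within-specimen patch heterogeneity,
measurement-angle artefacts, or sexual dichromatism. Passing tests
therefore demonstrate the statistical machinery recovers known effects
under realistic noise, not that real museum spectra would yield these
particular numbers.

Climate is a sinusoidal annual + diel temperature cycle with standard
declination/hour-angle solar geometry and a clearness index splitting
global radiation into direct and diffuse; the island preset is cooler,
windier and foggier than the mainland preset and carries the darker island
soil albedo (0.163 vs 0.246). Trees are Yule (pure birth); the binary
trait is placed by random shuffle, Brownian thresholding, or maximal
clumping at exact prevalence, with the default fixture mirroring the
13-taxon, 10-melanic island community. Scene soils are drawn around dark
(island) and light (mainland) brown sRGB anchors; the leaf curve has the
usual green peak, red edge and NIR plateau; the fog illuminant is the
clear curve attenuated and flattened. All generators are
seed-deterministic.

## Numerical choices and limitations

* Trapezoidal integration everywhere on the native grid; linear
  interpolation for resampling, with extrapolation an error (except the
  flagged constant extension of reconstructed soil spectra).
* Permutation and bootstrap p-values use count formulas that include the
  observed arrangement; permutation draws exclude the observed labelling.
* Welch (unequal-variance) t-tests; Holm adjustment via statsmodels.
* PCA signs are arbitrary; only reconstructions and explained variance are
  contract.
* Problem sizes in the test and acceptance runs — 500 null datasets at
  n_perm = 199 for permutation calibration, 200 trees at n_perm = 300 per D
  estimate, one 8760-hour year per phenotype pair — were chosen so each
  Monte Carlo standard error sits well inside the tolerance it is checked
  against.
* The heat-flux model is a deliberately compact two-conductor abstraction:
  no posture, no shade-seeking, no wind-direction effects, no transient
  body-temperature dynamics beyond the heterothermy band. Its role is the
  *difference* between phenotypes under identical conditions, which is far
  less sensitive to the shared coefficients than absolute costs are.
* Receptor-noise contrasts do not satisfy the triangle inequality and are
  not asserted to; symmetry and illuminant invariance are.
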