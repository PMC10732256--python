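# Methods

`paoxsim` is an in-silico study of how epidermal melanin biases
photoacoustic imaging (PAI) and oximetry. It builds melanin-graded layered
skin models, validates them against in-vivo skin colorimetry via
adding-doubling radiative transfer, simulates multispectral photoacoustic
initial-pressure images by voxel Monte-Carlo photon transport, estimates
blood oxygenation (sO2) by linear spectral unmixing and by learned spectral
decoloring, and quantifies the melanin dependence of the estimates
statistically. This note records the models, the parameter choices, the
numerical decisions and the limits of what the synthetic studies show.

## Tissue optics

Absorption is a volume-fraction-weighted sum of pure chromophore spectra
bundled as CSV tables on 400–1000 nm (linear interpolation, no
extrapolation): melanosome, oxy-/deoxy-hemoglobin, water and lipid. Blood
is carried as *whole blood* at 150 g/L hemoglobin, so the stated volume
fractions (e.g. 0.2 % dermal blood) multiply the whole-blood absorption
directly; the tables are converted from molar extinction via
mu_a = ln(10)·ε·150/64500.

The melanosome spectrum is the standard power law
mu_a = C·(λ/500 nm)^−3.5 with C = 519.2 cm⁻¹, calibrated so that a 2 % v/v
melanosome epidermis absorbs 3.45 cm⁻¹ at 685 nm. This single constant
reproduces the whole six-value epidermal absorption series (2–40 % v/v,
log-spaced; 3.45–68.98 cm⁻¹) to better than 1 %.

Reduced scattering follows the Rayleigh + Mie mixture
mu_s' = a₅₀₀·[f_ray (λ/500)⁻⁴ + (1−f_ray)(λ/500)^(−b_mie)] with anisotropy
g = 0.9 (0.89 for the phantom material). Per-region defaults (epidermis
66.7/0.29/0.689; dermis 45.3/0.41/0.562) are the compilation skin entries.
The sub-dermal "generic tissue" background reuses the dermal entry: the
forearm volume below the dermis is dominated by dermal-like connective
tissue, and this choice reproduces the published in-vivo reflectance range
(0.20–0.72 at 685 nm) where the soft-tissue-average entry falls ~0.05
short. All scattering defaults live in `spectra.REGION_SCATTERING` and are
overridable per composition.

## Scenes

All scenes are piecewise homogeneous, so a voxel label map plus per-region
spectral tables represent them losslessly and compactly. The surface is
z = 0, depth increases with z, the imaging plane is x–z, and embedded
cylinders run along y. Vessel depth is measured surface → cylinder
*center* (asserted by a test so the convention is visible).

* layer model: 60 µm epidermis (melanosomes only), 1 mm dermis (0.2 %
  blood at 70 % sO2, 65 % water, 20 % lipid), semi-infinite background
  (2.5 % blood at 70 %, 65 % water, 20 % lipid);
* vessel model: layer model + whole-blood cylinder, r = 1.25 mm, center
  2.5 mm deep, oxygenation 0–1;
* realistic model: artery (r = 1.25 mm, sO2 = 1.0) and vein (r = 0.625 mm,
  sO2 = 0.7) at 2.5 mm;
* phantom twin: concentric cylinders in a 22 mm cube at 100 µm voxels
  (220³) — central blood tube r = 0.75 mm, water/intralipid body, 1 mm
  melanin shell whose melanosome fraction is set from a requested
  mu_a(700 nm);
* training volumes: 19.2 mm cubes at 0.3 mm voxels (64³) with a one-voxel
  epidermis layer (melanosome fraction ~ U[0.1 %, 5 %]), a 1 % v/v blood
  background at 70 % sO2, and 0–9 whole-blood cylinders with radius
  ~ U[0.3, 3] mm (clipped to fit) and sO2 ~ U[0, 1]. All randomness
  derives from one integer seed.

Voxelization samples the composition at voxel centers (no anti-aliasing);
a convergence test quantifies the discretization error (vessel volume
changes < 1 % from 60 to 30 µm voxels).

## Adding-doubling radiative transfer

Reflection/transmission operators are discretized over quadrature cosines
(Gauss below the critical angle, Radau above it so µ = 1 is always a node),
initialized from an infinitesimal single-scattering layer (Δτ = 10⁻⁸) and
grown by repeated doubling; layers compose by the adding equations with the
interreflection series summed by matrix inversion. The Henyey–Greenstein
phase function is delta-M scaled with the truncation order capped at 16 so
that refining the quadrature refines the angular integration of a fixed
scaled problem. Boundaries are specular Fresnel interfaces evaluated at the
internal angles (total internal reflection included); skin uses n = 1.4
against air, the phantom material n = 1.34.

Two illumination conventions are exposed: collimated normal incidence
(UR1, the quantity a pencil-beam Monte-Carlo run estimates) and diffuse
hemispherical incidence (URU, the d/8-style reflectance factor used in
colorimetry). The skin reflectance spectra and Table-series validation use
URU; solver cross-checks use UR1 with consistent Fresnel settings, where
Monte Carlo and adding-doubling agree to ~0.1 % on homogeneous half-spaces
and ≤ 2 % on the layered models.

At 16 quadrature nodes the darkest model's reflectance is within 0.5 % of
the 32-node value (the thin, strongly absorbing epidermis dominates the
angular error); by 32 nodes the result is converged to 0.1 %.

The inverse problem (mu_a, mu_s' from measured total R and T at fixed
g = 0.89, n = 1.34) runs a coarse log-grid presearch followed by
Levenberg–Marquardt in log-parameters with a 10⁻⁴ finite-difference step —
large enough to step over the doubling quantization noise — and flags
convergence at squared residual < 10⁻⁶. Round trips recover (mu_a, mu_s')
to well under 2 %.

## Colorimetry

Tristimulus integration uses bundled CIE 1964 10° observer and illuminant
D65 tables at 10 nm; the integrals are normalized so a perfect reflector is
exactly the white point, and the bundled tables reproduce the standard
D65/10° white (94.811, 100, 107.304) to 0.03 %. ITA =
arctan((L*−50)/b*)·180/π with the two-argument arctangent restricted to
(−90°, 90°] so b* = 0 is well defined. sRGB rendering maps the observer
white onto the sRGB reference white before the standard matrix and gamma,
with out-of-gamut clipping.

The reflectance fed to colorimetry is evaluated on 400–900 nm in 20 nm
steps — the full observer support — rather than constant-extrapolating a
450 nm-limited spectrum: the model reflectance falls steeply in the violet
(melanin power law, hemoglobin Soret bands), and constant extrapolation
there overstates blue reflectance enough to bias b* low and ITA high by
~5°. With full-support spectra the six-model series reproduces the
published ITA values (67° … −47°) within ~1.5° and the published hex
swatches within a few counts per channel.

Fitzpatrick types are assigned from ITA bands with cut points
60/48/30/10/−30° (configurable), which map both the published and the
computed ITA series one model per type I–VI.

## Monte-Carlo photon transport

Photons perform weighted random walks through the voxel grid
(Henyey–Greenstein scattering, per-region mu_a/mu_s/g). Absorption is
continuous along each voxel segment (track-length estimator): the weight
decays as exp(−mu_a·l) and the integral is deposited as fluence, so the
energy identity reflected + transmitted + absorbed = launched + net
roulette weight closes to ~10⁻¹² per run (roulette injections and
destructions are tallied separately because roulette conserves energy only
in expectation). Russian roulette triggers below weight 10⁻⁴ with survival
probability 0.1. Every photon owns a counter-based splitmix64 stream
derived from (seed, photon index), so results are bit-reproducible and
independent of execution order; multispectral runs derive per-wavelength
seeds as seed ⊕ wavelength index.

The tissue surface at z = 0 is index-matched by default — the convention
of the standard voxel MC frameworks for photoacoustic forward modelling,
and the one that reproduces the published epidermis (≥10×) and vessel
(≈1.7×) signal ratios; an n = 1.4 Fresnel surface with specular entry
refraction and total internal reflection is available
(`fresnel_top=True`) and is used when cross-validating against the
boundary-including adding-doubling solver. Lateral and bottom faces are
absorbing.

The clinical illumination is a single fiber 43.2 mm above the probe with
8.66° divergence half-angle (uniform in solid angle), tilted 22.4° out of
the imaging plane, its central ray crossing the imaging plane 2.8 mm in
front of the probe face — read so the surface spot is centered over the
imaging plane. The phantom geometry uses ten fiber bundles on a ring,
aimed at the sample, water-coupled. Initial pressure is p0 = mu_a·Φ with
the Grüneisen parameter set to 1 (arbitrary units).

## Oximetry

Linear unmixing solves per-pixel least squares against the literature
whole-blood HbO2/Hb endmembers via the matrix pseudo-inverse
(unconstrained, exactly as in standard practice); sO2^EST =
c_HbO2/(c_HbO2+c_Hb). Pixels with a negative coefficient are invalid (a
relative 10⁻⁹ epsilon keeps pure endmembers from being invalidated by
rounding); region estimates are median(c_HbO2)/median(THb) over valid
pixels. Voxels never visited by a photon (all-zero spectra) are excluded
before unmixing.

Learned spectral decoloring trains a histogram-based gradient-boosted
regression tree (max depth 16, otherwise library defaults, recorded in the
model metadata) on mean-normalized per-voxel p0 spectra of *vessel* voxels
from the randomized training volumes, labelled with their true sO2.
Background voxels are excluded: their fixed 70 % label would dominate the
corpus and collapse the regressor onto a constant. Mean-normalization
removes the unknown fluence scale; predictions are clipped to [0, 1].

The Severinghaus dissociation curve sO2 = 1/(23400/(pO2³ + 150·pO2) + 1)
converts reference pO2 to sO2, with the pO2 = 0 limit handled explicitly
(P50 ≈ 26.9 mmHg).

## Statistics

Melanin dependence is quantified by ordinary least squares with classical
95 % confidence intervals and p-values, a Shapiro–Wilk normality check on
the residuals reported with every fit, and an optional log transformation
of the response. The in-vivo-style comparison uses an additive two-factor
linear model (strain + pigmentation, no interaction) with
first-appearance factor coding. No multiple-testing correction is applied
(raw p-values are reported). Repeat scans are treated as independent
observations.

## Problem sizes and what the synthetic studies show

Desk-scale runs use a 12×12×7.2 mm volume at 60 µm voxels for the forearm
scenes and the following budgets, chosen once and used identically in the
test suite and the acceptance script:

* single-wavelength signal-ratio runs: 10⁶ photons (script), 10⁵ (suite);
* six-model multispectral runs: 21 wavelengths × 10⁵ photons;
* learned-decoloring corpus: 12 training volumes × 21 wavelengths × 10⁴
  photons (the published study used 500 volumes; the reduced corpus is
  enough for the slope-reduction result, see below).

At these budgets the measured quantities and their published counterparts
are: epidermal signal ratio ≈ 11 (published > 10), vessel signal ratio
≈ 1.68 (published 1.7), linear-unmixing sO2 slope vs melanosome fraction
≈ 0.20 (published 0.218 ± 0.018), learned slope ≈ 0.04 (published 0.150).

Known limitations:

* The absolute sO2^EST level for a fully oxygenated vessel sits at
  ~0.7–0.77 here, dominated by spectral self-shadowing inside the
  whole-blood cylinder; the published work reports only the slope of the
  melanin bias, which is reproduced. Any comparison of absolute levels
  would need the (unpublished) details of the original ROI placement.
* The learned regressor flattens the melanin bias *more* than the
  published one (slope ≈ 0.04 vs 0.150). The residual-slope value depends
  on unpublished details of the original training pipeline; the robust,
  reproducible findings are that learning shrinks the bias well below the
  linear slope and below the published band's upper edge. Scaling the
  corpus up drives the learned predictions closer to truth and the slope
  further down, not towards the published value.
* Idealized p0 images contain no acoustic propagation, reconstruction
  artifacts or noise, so negative-pixel handling is exercised on
  constructed fixtures rather than arising naturally.
* Training volumes illuminate with a full-surface disc beam rather than
  the clinical fiber; the learned model is therefore tested under a
  deliberate illumination domain shift, as in the original study design.
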