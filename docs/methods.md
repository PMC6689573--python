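# Methods

This note documents the models implemented in iridoscan, the parameters
that matter, the numerical choices made where conventions were open, and
what the synthetic-data generators do and do not emulate.

## Reflectance colorimetry

Spectra are relative reflectance (%) against a white diffuse standard on an
ascending wavelength grid, restricted to 300–700 nm on reading (instrument
exports are often binned at ~0.37 nm; any uniform grid is accepted).
Processing applies degree-1 local regression (loess family) with the span
interpreted as the fraction of points in each tricube-weighted
neighbourhood, followed by clamping negative reflectance to exactly zero —
in that order, so the clamp acts on the smoothed curve. The smoother is
statsmodels' `lowess` with zero robustness iterations, which reproduces
constants and linear ramps exactly and matches the R convention for
span-parameterised local regression. Default span 0.3.

Summaries: B1 = ΣR (a plain sum over grid samples, so B1 is only comparable
within one grid — recorded in output metadata); H1 = wavelength of maximum
reflectance with ties broken toward the lowest wavelength (deterministic
argmax-first convention); chroma S1.X = band sum / B1 with both band
endpoints inclusive. The UV/blue/green/red bands tile 300–700 nm, so their
S1 values sum to 1 up to the three double-counted boundary samples at 400,
510 and 605 nm; the yellow band (550–625 nm) deliberately overlaps green
and red and is excluded from that sum rule. Whether band endpoints should
be inclusive is not fixed by convention; inclusive was chosen and is what
the sum-rule tests encode. An all-zero spectrum yields B1 = 0 with H1 and
S1 reported as missing.

Melanistic individuals (which lose the bright pattern) are excluded via a
`melanistic` flag column in the sample sheet rather than hard-coded ids.

## Redundancy analysis and permutation tests

RDA is computed from first principles: Y (rows = spectra, columns =
standardized summary variables) is centered; the constraint design X (and
optional conditioning design Z) are centered and, under conditioning, both
Y and X are residualized on Z's column space. Fitted values Ŷ = H·Y use an
orthonormal (QR) basis of X; constrained eigenvalues are the singular
values of Ŷ squared over (n−1), residual eigenvalues those of Y−Ŷ, and
proportions are taken against the total (conditioned) variance, so
constrained + residual variance equals total variance to machine precision.
Categorical predictors are dummy-coded dropping one level; a rank-deficient
constraint design is an error.

The ANOVA-like pseudo-F is (SS_constrained/q) / (SS_residual/(n−q−p_Z−1))
with q constraint columns and p_Z conditioning columns. The permutation
test permutes rows of the conditioned responses and re-residualizes on Z
(reduced-model permutation, the standard scheme for partial constrained
ordination; with no conditioning this is a plain row permutation), with
p = (1 + #{F* ≥ F}) / (1 + n_perm) and 9999 permutations by default. The
smallest attainable p is therefore 1/(n_perm+1); note that with grouped
designs, permutations that reproduce the same group partition tie with the
observed statistic, so the practical floor for a two-group factor is the
partition-preserving fraction of permutations, not 1/(n_perm+1). The
permutation seed is an explicit argument recorded in outputs.

Adjusted R² uses the Ezekiel correction 1 − (1−R²)(n−1)/(n−m−1) with m the
rank of the constraint set. Variance partitioning for two predictor sets
derives unique and shared fractions from the three adjusted R² values
(unique(X1) = adjR²(X1,X2) − adjR²(X2), shared by inclusion–exclusion,
residual = 1 − adjR²(X1,X2)); overlapping combined designs are handled by
rank, and slightly negative adjusted fractions are reported as computed.
Per-variable ANOVAs with Holm correction are a thin wrapper applying the
same permutation engine column-wise.

## Platelet morphometry and angular organisation

Micrographs are contrast-stretched to full range and thresholded with
Otsu's criterion; polarity (bright platelets vs dark) is a switch since
intact platelets and empty holes can have either contrast after staining.
Components touching the image border (partial platelets) are discarded, as
are regions under 20 px (configurable). Each region is reduced to its
moment-equivalent ellipse via scikit-image regionprops; axis lengths are
converted to nm by the image scale and the major-axis angle is expressed
against the x-axis, y up, in (−90°, 90°]. Circles report 0° by convention;
one-pixel regions are skipped with a log entry.

The angle density is a histogram on (−90°, 90°] with 5° bins (configurable)
normalized to integrate to 1 — a histogram rather than a kernel estimate,
the simplest choice consistent with fitting a parametric peak. The model
y0 + A·exp(−(θ−c)²/2σ²) is fitted by bounded nonlinear least squares
(A, y0 ≥ 0, σ bounded below so FWHM cannot collapse under one bin width).
Because the support is periodic with period 180°, the histogram is
circularly recentred on its modal bin before fitting and the centre mapped
back, which makes the fit well-behaved for predominant orientations near
±90°. A/y0 is reported as infinite (flagged) when the background term hits
zero, which includes the degenerate all-one-bin spike where FWHM is
reported at its floor, the bin width. At least ~20 angle measurements are
recommended (a warning is emitted below that).

Thin-film prediction: the quarter-wave single-layer condition λ = 4·n·d
with platelet refractive index n = 1.83 (guanine). The exact single-layer
formula in the source literature could include cytoplasm-gap or
viewing-angle terms; the quarter-wave form reproduces the right order of
magnitude for ~86–145 nm platelets (λ ≈ 630–1060 nm) and the formula mode
is a config switch so an alternative can be dropped in. The population
prediction is the mode of a Gaussian kernel density (Silverman bandwidth)
over per-platelet wavelengths, evaluated on a 1 nm grid.

## Collagen Fourier analysis

The analysed square is 800×800 px by default (centre crop, manual offset
available), contrast-stretched, and binarized by Otsu's threshold into
refractive indices 1.42 (dark, collagen) and 1.35 (light,
mucopolysaccharide matrix); a constant crop is treated as all-fibre. The
mean is removed before the FFT (otherwise the DC bin dominates the
normalization); no window is applied by default, matching the classic
image-Fourier workflow for biological nanostructure, with an optional Hann
window flag because spectral leakage affects the lowest-frequency bins.
Power is |FFT|²/N_pixels so total power equals field variance × N_pixels
(Parseval).

Radial averaging uses annuli one frequency step Δf = 1/(N·scale) wide,
centred on integer multiples of Δf (the zero bin then contains only the DC
pixel, which is zero after mean removal); the profile is normalized to unit
total power. The radial profile is exactly invariant under 90° rotation of
the input.

Frequency maps to wavelength as λ = 2·n̄/f with n̄ = (1.42+1.35)/2 = 1.385 —
the frequency→wavelength inversion of coherent scattering (the "inverse
value" of the spatial frequency; inverting the power itself would be
dimensionally meaningless). Power at each frequency is assigned wholly to
the nearest of 51 wavelength bins centred at 300, 310, …, 800 nm (10 nm
spacing, no interpolation — simple and mass-conserving); power mapping
below 300 nm or above 800 nm (including the DC bin, λ = ∞) is reported
separately so total mass is conserved exactly. Visible-light coherent
scattering corresponds to 0.0034–0.0092 nm⁻¹. Composites over micrographs
are per-bin means, loess-smoothed with span 0.3.

Wavelength resolution is set by the physical field of view L = N·scale:
Δλ ≈ λ²/(2n̄L) at wavelength λ, i.e. ~8 nm at 550 nm for L ≈ 14.4 µm. Peak
positions at long wavelengths are correspondingly quantized on small
fields of view.

## Synthetic data

Generators are deterministic under (seed, parameters) and return truth
tables consistent with their images.

*Spectra* are baseline + UV Gaussian (centre 330–370 nm) + primary Gaussian
(500–600 nm) + white noise — the two-peaked shape of bright yellow skin
regions — with group effects on hue (peak shift), brightness (scale) and UV
amplitude. Defaults: baseline 2%, UV peak (350, 25, 4%), primary peak
(540, 40, 15%), noise sd 0.5% — magnitudes representative of bright stripe
spectra with a modest instrument noise floor.

*Platelet images* draw non-overlapping bright platelet cross-sections on a
dark ground; thicknesses ~Normal(90, 30) nm and widths ~Normal(395, 120) nm
match the magnitudes reported for emydid turtle iridophores. A fraction of
angles is Normal(0°, 25°), the rest uniform — an aligned population over a
random background. Platelets are drawn as filled ellipses by default: the
moment-equivalent ellipse of an ellipse recovers its axes exactly, so truth
tables compare directly with measurements; rectangle mode exists but its
equivalent-ellipse axes are 2/√3 ≈ 1.155× the side lengths, a shape
convention rather than a measurement property. Overlap is disallowed
(rejection sampling) so segmentation ground truth is unambiguous — real
micrographs do contain touching platelets, which thresholding merges; that
failure mode is deliberately absent from the recovery suites.

*Collagen textures* place dark disks on a jittered **square** lattice with
target nearest-neighbour spacing s. A square lattice is used rather than a
hexagonal one because its first Fourier ring lies exactly at 1/s, keeping
the identity λ_peak = 2·n̄·s between generator spacing and predicted
reflectivity; a hexagonal lattice's first ring sits at the lattice-plane
spacing (√3/2)·s, which silently breaks spacing-based recovery checks.
Default scale is 18 nm/px on an 800 px square (field of view 14.4 µm) so
the wavelength quantization at 550 nm (~8 nm) is finer than the 10 nm
output bins. Jitter sd is spacing_cv × s per coordinate; note that jitter
biases the *realized* mean nearest-neighbour distance below the lattice
constant (the minimum over neighbours), while the Fourier ring stays at the
lattice frequency — truth tables record both the target and the realized
spacing.

What the generators do not emulate: staining artefacts, section folds and
TEM shot noise structure; touching/overlapping platelets; non-Gaussian
spectral shapes (e.g. the flat dark-region spectra); melanistic-pattern
spectra. Passing recovery suites therefore demonstrates correctness of the
measurement chain on clean, known-truth inputs, not robustness to every
preparation artefact of real material.

## Pipeline

The `iridoscan run` pipeline executes stages in dependency order from one
YAML config whose defaults mirror the analysis defaults above (span 0.3,
9999 permutations, n = 1.83/1.42/1.35, 800 px square, 51 bins). Each stage
hashes its parameters and input files into a run manifest; unchanged stages
are skipped on rerun. Fixed seeds plus fixed inputs give byte-identical
outputs.

## Problem sizes used in the test and acceptance suites

Recovery suites run at sizes chosen to make the statistics stable while
keeping the whole suite fast on one CPU: 200 platelets on a 1600 px
micrograph for thickness recovery, 2000–4000 sampled angles for angular
statistics, one 800 px collagen square per seed (10 seeds for the
composite), 200 null datasets × 199 permutations for type-I calibration,
and exhaustive enumeration at n = 5 against 10⁴ Monte-Carlo permutations
for the permutation-test cross-check.

## Known limitations

- B1 depends on grid spacing; only within-grid comparisons are meaningful.
- The exact form of the cited single-layer interference equation is not
  recoverable from the text implemented against; the quarter-wave form is a
  documented choice behind a switch.
- Chroma boundary samples are double-counted under inclusive endpoints
  (bounded by 3·max(R)/B1).
- The angular fit assumes a single predominant orientation; bimodal
  platelet populations would need a mixture extension.
- Wavelength re-binning assigns each frequency bin wholly to one 10 nm bin;
  no sub-bin interpolation is attempted.
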