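# iridoscan

Quantitative analysis of animal structural and pigmentary coloration, built
for the kind of study that combines reflectance spectrophotometry with
transmission electron microscopy of the skin: colorimetric summaries of
reflectance spectra with constrained-ordination tests of species and sex
effects, morphometry of iridophore reflecting platelets with a thin-film
interference prediction, and 2-D Fourier analysis of dermal collagen
nanostructure yielding predicted-reflectivity curves.

## Who it is for

Researchers measuring how skin colour is produced — e.g. in turtles,
lizards or amphibians whose bright stripes combine pigment cells
(xanthophores), reflecting cells (iridophores) and structured dermal
collagen. The package turns raw spectra and micrographs into the standard
quantities of that literature and tests hypotheses about them, and it ships
synthetic-data generators with known ground truth so every stage can be
validated without access to the original specimens.

## What it computes

**Colorimetry** (`iridoscan.colorimetry`). Reflectance spectra on a
300–700 nm grid are smoothed by degree-1 local regression (span = 0.3 as a
fraction of points) and negative values clamped to zero, then summarised as

- B1 = Σ R(λ) — total brightness (grid-dependent by definition),
- H1 = argmax R(λ) — hue, the wavelength of maximum reflectance,
- S1.X = Σ<sub>λ∈X</sub> R(λ) / B1 — chroma of band X, for
  UV 300–400, blue 400–510, green 510–605, yellow 550–625 and
  red 605–700 nm (endpoints inclusive).

**Ordination** (`iridoscan.ordination`). Redundancy analysis (RDA) from
first principles: Y (standardized colour summaries) is regressed on a
constraint design X (e.g. species), optionally after partialling out Z
(e.g. sex); constrained axes are the principal axes of the fitted values.
Significance uses the ANOVA-like permutation pseudo-F,
F = (SS<sub>constrained</sub>/q) / (SS<sub>residual</sub>/(n−q−p<sub>Z</sub>−1)),
with p = (1 + #{F\* ≥ F}) / (1 + n<sub>perm</sub>) and 9999 permutations by
default (reduced-model permutation under conditioning). Variance is
partitioned between predictor sets with Ezekiel-adjusted R². A
sklearn-style estimator class `RDA` wraps the module functions.

**Platelets** (`iridoscan.platelets`). Reflecting platelets (or the empty
holes they leave after embedding) are segmented by Otsu thresholding of the
contrast-stretched micrograph; each region's moment-equivalent ellipse
gives thickness (minor axis, nm), width (major axis, nm) and orientation in
(−90°, 90°]. The angle density is fitted with
y0 + A·exp(−(θ−c)²/2σ²): A/y0 measures the share of platelets aligned with
the skin surface and FWHM = 2√(2 ln 2)·σ its spread. Thickness d maps to a
predicted reflected wavelength by the quarter-wave thin-film condition
λ = 4·n·d (guanine n = 1.83), and the population prediction is the mode of
a Gaussian kernel density over per-platelet wavelengths.

**Collagen Fourier analysis** (`iridoscan.collagen_fourier`). A
standardized square (800 px) is binarized into a refractive-index field
(collagen 1.42, matrix 1.35); the mean-removed 2-D FFT power spectrum is
radially averaged into annuli one frequency step wide and normalized to
total power. Each spatial frequency f maps to λ = 2·n̄/f (n̄ = 1.385), and
power is re-binned into 51 bins of 10 nm spanning 300–800 nm; composites
over micrographs are loess-smoothed (span = 0.3). Frequencies of
0.0034–0.0092 nm⁻¹ correspond to coherent scattering of visible light.

**Synthetic data** (`iridoscan.synthetic_data`) and a staged pipeline with
config, caching and a reproducibility manifest (`iridoscan.pipeline`,
CLI `iridoscan`).

## Worked example

```python
import numpy as np
from iridoscan import synthetic_data as sd, colorimetry as cm, ordination as ord_
from iridoscan import platelets as pl, collagen_fourier as cf

# two-species reflectance study with a 20 nm hue shift in species B
groups = {
    "A_f": sd.GroupEffect(taxon="A", sex="f"),
    "B_f": sd.GroupEffect(taxon="B", sex="f", hue_shift_nm=20.0),
}
spectra, truth = sd.gen_spectra(10, groups, noise_sd=0.5, seed=42)
table = cm.summarize_table(spectra)
print(table.groupby("taxon")[["B1", "H1", "S1_green"]].mean().round(2))

Y = ord_.standardize(table[cm.SUMMARY_COLUMNS])
X = ord_.design_matrix(table, ["taxon"])
model = ord_.RDA(n_permutations=999, random_state=0).fit(Y, X)
print(f"pseudo-F = {model.pseudo_F_:.2f}, p = {model.p_value_:.3f}, "
      f"RDA1 explains {100*model.prop_variance_[0]:.0f}% of variance")

# iridophore platelet morphometry on a synthetic micrograph (5 nm/px)
img, _ = sd.gen_platelet_image(n_platelets=200, thickness_nm=(90, 30),
                               seed=21, image_px=1600)
pset = pl.measure_micrograph(img, scale_nm_per_px=5.0)
org = pl.angular_organization(pset)
print(f"platelets: {len(pset)}, mean thickness {pset.minor_nm.mean():.1f} nm, "
      f"A/y0 = {org.A_over_y0:.2f}, FWHM = {org.fwhm_deg:.1f} deg")
print(f"thin-film peak: {pl.predicted_wavelength_peak(pset):.0f} nm")

# collagen texture tuned to reflect at 550 nm (spacing = 550 / 2*1.385)
cimg, _ = sd.gen_collagen_image(mean_spacing_nm=198.6, spacing_cv=0.1, seed=4)
profile, refl = cf.analyze_micrograph(cimg, scale_nm_per_px=18.0)
print(f"collagen ring at {profile.peak_frequency():.4f} nm^-1 -> "
      f"predicted reflectivity peak {refl.peak_wavelength():.0f} nm")
```

Output:

```
            B1     H1  S1_green
taxon
A      2534.36  540.0      0.47
B      2528.10  560.0      0.49
pseudo-F = 46.18, p = 0.002, RDA1 explains 72% of variance
platelets: 200, mean thickness 87.6 nm, A/y0 = 9.31, FWHM = 55.9 deg
thin-film peak: 648 nm
collagen ring at 0.0051 nm^-1 -> predicted reflectivity peak 550 nm
```

The species hue shift (H1: 540 → 560 nm) drives a significant RDA;
segmentation recovers the 200 drawn platelets and their ~90 nm mean
thickness; and the collagen texture built with 198.6 nm fibre spacing
produces its predicted reflectivity peak at 2 × 1.385 × 198.6 ≈ 550 nm, in
the correct 10 nm bin.

The same stages are scriptable from the shell, e.g.:

```
iridoscan simulate spectra --seed 3 --out demo/
iridoscan spectra summarize --in demo/spectra.csv --samples demo/samples.csv --out demo/summary.csv
iridoscan rda --summary demo/summary.csv --samples demo/samples.csv --constrain taxon --nperm 9999 --seed 42
iridoscan run --config pipeline.yaml --out runs/
```

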