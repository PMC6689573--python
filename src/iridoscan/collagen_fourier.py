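"""2-D Fourier analysis of dermal collagen arrays and predicted reflectivity.

Quasi-ordered arrays of dermal collagen fibres can produce colour by
coherent scattering when the spatial periodicity of the refractive-index
field matches visible wavelengths.  The analysis follows the standard
image-Fourier workflow for biological nanostructure:

1. a standardized square (default 800 px) is cropped from the micrograph,
   contrast-stretched and thresholded; dark (fibre) pixels are assigned
   refractive index 1.42 and light (mucopolysaccharide matrix) pixels 1.35;
2. the mean is removed and the 2-D FFT power spectrum computed, with axes
   in physical spatial frequency (nm^-1);
3. power is averaged over concentric annuli of one frequency-step width and
   normalized to total power (the radial average);
4. each spatial frequency f maps to a predicted reflected wavelength
   lambda = 2 * n_avg / f, and the normalized power is re-binned into 51
   bins of 10 nm spanning 300-800 nm to give a predicted-reflectivity
   curve; composites over several micrographs are loess-smoothed
   (span = 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._smoothing import loess_smooth

__all__ = [
    "FourierConfig",
    "RadialPowerProfile",
    "PredictedReflectivity",
    "prepare_square",
    "power_spectrum_2d",
    "radial_average",
    "frequency_for_wavelength",
    "wavelength_for_frequency",
    "predicted_reflectivity",
    "composite_reflectivity",
    "analyze_micrograph",
]


@dataclass
class FourierConfig:
    """Parameters of the collagen Fourier analysis."""

    square_px: int = 800
    n_collagen: float = 1.42
    n_matrix: float = 1.35
    n_bins: int = 51
    lambda_range_nm: tuple[float, float] = (300.0, 800.0)
    window: Literal["none", "hann"] = "none"

    def __post_init__(self) -> None:
        if not self.n_collagen > self.n_matrix > 1:
            raise ValueError("need n_collagen > n_matrix > 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        lo, hi = self.lambda_range_nm
        if not 0 < lo < hi:
            raise ValueError("lambda range must be positive and increasing")

    @property
    def n_avg(self) -> float:
        return 0.5 * (self.n_collagen + self.n_matrix)

    @property
    def bin_width_nm(self) -> float:
        # 51 bins spanning 300-800 nm are centred at 300, 310, ..., 800
        lo, hi = self.lambda_range_nm
        return (hi - lo) / (self.n_bins - 1)

    @property
    def wavelength_bin_centers_nm(self) -> np.ndarray:
        lo, hi = self.lambda_range_nm
        return np.linspace(lo, hi, self.n_bins)


@dataclass
class RadialPowerProfile:
    """Normalized Fourier power per spatial-frequency bin for one image."""

    freq_per_nm: np.ndarray
    power: np.ndarray
    scale_nm_per_px: float
    image_id: str = ""

    def __post_init__(self) -> None:
        self.freq_per_nm = np.asarray(self.freq_per_nm, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.freq_per_nm < 0) or np.any(np.diff(self.freq_per_nm) <= 0):
            raise ValueError("frequencies must be nonnegative and ascending")

    def peak_frequency(self) -> float:
        """Frequency bin centre with maximal power (DC bin excluded)."""
        p = self.power.copy()
        p[0] = -np.inf
        return float(self.freq_per_nm[int(np.argmax(p))])


@dataclass
class PredictedReflectivity:
    """Relative predicted reflectivity per wavelength bin (300-800 nm)."""

    wavelength_nm: np.ndarray
    reflectivity: np.ndarray
    sub_range_mass: float = 0.0  # power mapping below the wavelength range
    above_range_mass: float = 0.0  # power mapping above it (incl. near-DC)
    image_id: str = ""
    smoothed: np.ndarray | None = None

    def peak_wavelength(self) -> float:
        curve = self.smoothed if self.smoothed is not None else self.reflectivity
        return float(self.wavelength_nm[int(np.argmax(curve))])


# ---------------------------------------------------------------------------

def prepare_square(
    image: np.ndarray,
    scale_nm_per_px: float,
    cfg: FourierConfig | None = None,
    *,
    offset: tuple[int, int] | None = None,
) -> np.ndarray:
    """Crop, contrast-standardize and binarize into a refractive-index field.

    The square of side ``cfg.square_px`` is taken from the image centre
    unless ``offset`` gives the top-left corner (row, col).  Pixels darker
    than the Otsu threshold of the contrast-stretched crop become
    ``n_collagen`` (fibre), lighter ones ``n_matrix``.  A constant crop is
    treated as all-fibre.
    """
    from skimage.filters import threshold_otsu

    cfg = cfg or FourierConfig()
    if scale_nm_per_px <= 0:
        raise ValueError("scale_nm_per_px must be positive")
    img = np.asarray(image, dtype=float)
    s = cfg.square_px
    if img.shape[0] < s or img.shape[1] < s:
        raise ValueError(f"image {img.shape} is smaller than the {s} px analysis square")
    if offset is None:
        r0 = (img.shape[0] - s) // 2
        c0 = (img.shape[1] - s) // 2
    else:
        r0, c0 = offset
        if r0 < 0 or c0 < 0 or r0 + s > img.shape[0] or c0 + s > img.shape[1]:
            raise ValueError("offset square falls outside the image")
    crop = img[r0:r0 + s, c0:c0 + s]

    lo, hi = crop.min(), crop.max()
    if hi == lo:
        return np.full(crop.shape, cfg.n_collagen)
    stretched = (crop - lo) / (hi - lo)
    t = threshold_otsu(stretched)
    return np.where(stretched < t, cfg.n_collagen, cfg.n_matrix)


def power_spectrum_2d(
    field: np.ndarray,
    scale_nm_per_px: float,
    *,
    window: Literal["none", "hann"] = "none",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centred 2-D Fourier power spectrum with physical frequency axes.

    The mean (DC) is removed first.  Power is ``|FFT|^2 / N_pixels`` so
    that total power equals field variance times N_pixels (Parseval).
    Returns ``(power, fy, fx)`` with frequencies in nm^-1.
    """
    f = np.asarray(field, dtype=float)
    if f.ndim != 2 or f.shape[0] != f.shape[1]:
        raise ValueError("field must be a square 2-D array")
    f = f - f.mean()
    if window == "hann":
        w = np.hanning(f.shape[0])
        f = f * np.outer(w, w)
    F = np.fft.fftshift(np.fft.fft2(f))
    power = np.abs(F) ** 2 / f.size
    fy = np.fft.fftshift(np.fft.fftfreq(f.shape[0], d=scale_nm_per_px))
    fx = np.fft.fftshift(np.fft.fftfreq(f.shape[1], d=scale_nm_per_px))
    return power, fy, fx


def radial_average(
    power: np.ndarray,
    fy: np.ndarray,
    fx: np.ndarray,
    *,
    image_id: str = "",
    scale_nm_per_px: float | None = None,
) -> RadialPowerProfile:
    """Mean power in concentric annuli of one frequency-step width.

    The annulus width is the frequency step 1/(N * scale); the resulting
    profile is normalized to unit total power.
    """
    df = float(fy[1] - fy[0])
    if scale_nm_per_px is None:
        scale_nm_per_px = 1.0 / (df * power.shape[0])
    r = np.hypot(fy[:, None], fx[None, :])
    idx = np.floor(r / df + 0.5).astype(int)  # annuli centred on multiples of df
    nbins = int(idx.max()) + 1
    sums = np.bincount(idx.ravel(), weights=power.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    means = sums / np.maximum(counts, 1)
    total = means.sum()
    if total > 0:
        means = means / total
    freqs = np.arange(nbins) * df
    return RadialPowerProfile(
        freq_per_nm=freqs, power=means,
        scale_nm_per_px=float(scale_nm_per_px), image_id=image_id,
    )


def wavelength_for_frequency(freq_per_nm, n_avg: float = 1.385):
    """lambda = 2 * n_avg / f — the coherent-scattering wavelength of f."""
    f = np.asarray(freq_per_nm, dtype=float)
    with np.errstate(divide="ignore"):
        lam = 2.0 * n_avg / f
    return float(lam) if np.isscalar(freq_per_nm) else lam


def frequency_for_wavelength(wavelength_nm, n_avg: float = 1.385):
    """Inverse mapping: f = 2 * n_avg / lambda."""
    return wavelength_for_frequency(wavelength_nm, n_avg)


def predicted_reflectivity(
    profile: RadialPowerProfile,
    cfg: FourierConfig | None = None,
) -> PredictedReflectivity:
    """Re-bin normalized radial power onto the wavelength axis.

    Each frequency bin's power is assigned wholly to the wavelength bin
    containing lambda = 2*n_avg/f.  The zero-frequency bin (infinite
    wavelength) and power mapping beyond the range are reported as
    above/sub-range mass so total mass is conserved.
    """
    cfg = cfg or FourierConfig()
    lo, hi = cfg.lambda_range_nm
    bw = cfg.bin_width_nm
    refl = np.zeros(cfg.n_bins)
    sub = 0.0
    above = 0.0
    for f, p in zip(profile.freq_per_nm, profile.power):
        if f <= 0:
            above += p  # DC: infinite wavelength
            continue
        lam = 2.0 * cfg.n_avg / f
        j = int(round((lam - lo) / bw))  # nearest bin centre
        if j < 0:
            sub += p
        elif j >= cfg.n_bins:
            above += p
        else:
            refl[j] += p
    return PredictedReflectivity(
        wavelength_nm=cfg.wavelength_bin_centers_nm,
        reflectivity=refl,
        sub_range_mass=float(sub),
        above_range_mass=float(above),
        image_id=profile.image_id,
    )


def composite_reflectivity(
    profiles: Sequence[PredictedReflectivity],
    span: float = 0.3,
) -> PredictedReflectivity:
    """Per-bin mean over images plus a loess-smoothed composite curve."""
    if not profiles:
        raise ValueError("need at least one reflectivity profile")
    wl = profiles[0].wavelength_nm
    for p in profiles[1:]:
        if not np.array_equal(p.wavelength_nm, wl):
            raise ValueError("profiles are on mismatched wavelength bins")
    mean = np.mean([p.reflectivity for p in profiles], axis=0)
    smoothed = loess_smooth(wl, mean, span=span)
    return PredictedReflectivity(
        wavelength_nm=wl.copy(),
        reflectivity=mean,
        sub_range_mass=float(np.mean([p.sub_range_mass for p in profiles])),
        above_range_mass=float(np.mean([p.above_range_mass for p in profiles])),
        image_id="composite",
        smoothed=smoothed,
    )


def analyze_micrograph(
    image: np.ndarray,
    scale_nm_per_px: float,
    cfg: FourierConfig | None = None,
    *,
    image_id: str = "",
    offset: tuple[int, int] | None = None,
) -> tuple[RadialPowerProfile, PredictedReflectivity]:
    """Full single-image pipeline: square -> FFT power -> radial -> reflectivity."""
    cfg = cfg or FourierConfig()
    field = prepare_square(image, scale_nm_per_px, cfg, offset=offset)
    power, fy, fx = power_spectrum_2d(field, scale_nm_per_px, window=cfg.window)
    profile = radial_average(power, fy, fx, image_id=image_id,
                             scale_nm_per_px=scale_nm_per_px)
    return profile, predicted_reflectivity(profile, cfg)
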