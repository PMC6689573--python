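"""Iridophore reflecting-platelet morphometry and thin-film predictions.

Reflecting platelets (guanine crystals inside iridophores) are measured
from transmission electron micrographs either as intact platelets or as
the empty holes they leave after dissolving during embedding.  Each
platelet is reduced to the moment-equivalent ellipse of its segmented
region: minor axis (thickness, nm), major axis (width, nm) and the angle
of the major axis to the image x-axis in (-90, 90] degrees.

The angular organisation of a platelet population is summarised by
fitting density(theta) = y0 + A*exp(-(theta-c)^2 / (2 sigma^2)) to the
angle density: ``A`` is the aligned peak above the background ``y0`` of
randomly oriented platelets, and A/y0 measures how strongly platelets are
aligned with the skin surface.  FWHM = 2*sqrt(2 ln 2)*sigma.

Platelet thickness d maps to a predicted constructively-reflected
wavelength with a quarter-wave single-layer interference model,
lambda = 4 * n * d (guanine platelet refractive index n = 1.83 by
default); the reported prediction of a population is the mode of a
Gaussian kernel density of the per-platelet wavelengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde
from skimage import exposure, measure, segmentation
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

PLATELET_COLUMNS = ["image_id", "mode", "minor_nm", "major_nm", "angle_deg"]


@dataclass
class PlateletSet:
    """Per-platelet measurements from one or more micrographs.

    ``records`` has columns image_id, mode (intact | empty_hole),
    minor_nm, major_nm, angle_deg.
    """

    records: pd.DataFrame
    scale_nm_per_px: float

    def __post_init__(self) -> None:
        if self.scale_nm_per_px <= 0:
            raise ValueError("scale_nm_per_px must be positive")
        missing = [c for c in PLATELET_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"platelet records missing columns: {missing}")
        if len(self.records):
            bad = self.records["minor_nm"] > self.records["major_nm"] + 1e-9
            if bad.any():
                raise ValueError("minor axis exceeds major axis in some records")
            a = self.records["angle_deg"]
            if ((a <= -90) | (a > 90)).any():
                raise ValueError("angles must lie in (-90, 90]")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def angles_deg(self) -> np.ndarray:
        return self.records["angle_deg"].to_numpy(float)

    @property
    def minor_nm(self) -> np.ndarray:
        return self.records["minor_nm"].to_numpy(float)


@dataclass
class AngularOrganization:
    """Gaussian-plus-background fit of the platelet angle density."""

    A: float
    y0: float
    center_deg: float
    fwhm_deg: float
    y0_clamped: bool = False

    @property
    def A_over_y0(self) -> float:
        return self.A / self.y0 if self.y0 > 0 else float("inf")

    def as_dict(self) -> dict:
        return {
            "A": self.A,
            "y0": self.y0,
            "center_deg": self.center_deg,
            "fwhm_deg": self.fwhm_deg,
            "A_over_y0": self.A_over_y0,
            "y0_clamped": self.y0_clamped,
        }


@dataclass
class ThinFilmModel:
    """Single-layer thin-film interference model for platelet reflection."""

    n_platelet: float = 1.83
    mode: Literal["quarter_wave"] = "quarter_wave"

    def __post_init__(self) -> None:
        if self.n_platelet <= 1:
            raise ValueError("refractive index must exceed 1")
        if self.mode != "quarter_wave":
            raise ValueError(f"unknown thin-film formula mode: {self.mode}")


# ---------------------------------------------------------------------------
# segmentation and measurement

def segment_platelets(
    image: np.ndarray,
    scale_nm_per_px: float,
    mode: Literal["intact", "empty_hole"] = "intact",
    *,
    polarity: Literal["bright", "dark"] = "bright",
    min_area_px: int = 20,
) -> np.ndarray:
    """Threshold and label platelet (or empty-hole) regions.

    The micrograph is contrast-stretched, thresholded with Otsu's
    criterion (``polarity`` selects whether platelets are the bright or
    dark phase), and connected components touching the border or smaller
    than ``min_area_px`` are discarded.  Returns a labelled image.
    """
    if scale_nm_per_px <= 0:
        raise ValueError("scale_nm_per_px must be positive")
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = exposure.rescale_intensity(img, in_range=(lo, hi), out_range=(0.0, 1.0))
        t = threshold_otsu(img)
        mask = img > t if polarity == "bright" else img < t
    else:
        mask = np.zeros(img.shape, dtype=bool)
    mask = segmentation.clear_border(mask)
    labels = measure.label(mask)
    if labels.max() > 0:
        areas = np.bincount(labels.ravel())
        small = np.where(areas < min_area_px)[0]
        if small.size:
            mask &= ~np.isin(labels, small)
            labels = measure.label(mask)
    if labels.max() == 0:
        warnings.warn("segmentation produced no platelet regions", stacklevel=2)
    return labels


def fit_ellipses(
    labels: np.ndarray,
    scale_nm_per_px: float,
    *,
    image_id: str = "",
    mode: str = "intact",
) -> PlateletSet:
    """Moment-equivalent ellipse of each labelled region, in nm and degrees.

    The angle is that of the major axis against the image x-axis with y
    pointing up (mathematical convention), mapped to (-90, 90]; circles
    report 0 by convention.  One-pixel (degenerate) regions are skipped.
    """
    rows = []
    for p in measure.regionprops(labels):
        if p.area < 2 or p.axis_major_length == 0:
            logger.info("skipping degenerate region of area %d", p.area)
            continue
        minor = p.axis_minor_length * scale_nm_per_px
        major = p.axis_major_length * scale_nm_per_px
        if major > 0 and (major - minor) / major < 1e-3:
            angle = 0.0  # circle: orientation undefined, report 0
        else:
            # regionprops orientation is measured from the row axis;
            # convert to x-axis/y-up convention in (-90, 90]
            angle = np.rad2deg(p.orientation) - 90.0
            angle = ((angle + 90.0) % 180.0) - 90.0
            if angle == -90.0:
                angle = 90.0
        rows.append(
            {"image_id": image_id, "mode": mode, "minor_nm": minor,
             "major_nm": major, "angle_deg": angle}
        )
    return PlateletSet(
        records=pd.DataFrame(rows, columns=PLATELET_COLUMNS),
        scale_nm_per_px=scale_nm_per_px,
    )


def measure_micrograph(
    image: np.ndarray,
    scale_nm_per_px: float,
    mode: Literal["intact", "empty_hole"] = "intact",
    **segment_kwargs,
) -> PlateletSet:
    """Segment a micrograph and fit ellipses in one step."""
    labels = segment_platelets(image, scale_nm_per_px, mode, **segment_kwargs)
    return fit_ellipses(labels, scale_nm_per_px, mode=mode)


# ---------------------------------------------------------------------------
# angular organisation

def _gauss_bg(theta, y0, a, c, sigma):
    return y0 + a * np.exp(-((theta - c) ** 2) / (2.0 * sigma**2))


def angular_organization(
    platelets: PlateletSet | np.ndarray,
    bin_deg: float = 5.0,
) -> AngularOrganization:
    """Fit a Gaussian-plus-background model to the platelet angle density.

    Angles are histogrammed on (-90, 90] with ``bin_deg``-wide bins
    (density normalised to integrate to 1).  The histogram is circularly
    recentred on its modal bin before fitting so that peaks near +-90 are
    handled correctly, and the fitted centre is mapped back to (-90, 90].
    """
    angles = platelets.angles_deg if isinstance(platelets, PlateletSet) else np.asarray(platelets, float)
    n = angles.size
    if n == 0:
        raise ValueError("no angles to fit")
    if n < 20:
        warnings.warn(f"only {n} angle measurements; angular fit may be unstable", stacklevel=2)

    nbins = max(int(round(180.0 / bin_deg)), 3)
    edges = np.linspace(-90.0, 90.0, nbins + 1)
    dens, _ = np.histogram(angles, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    mode_idx = int(np.argmax(dens))
    # circular shift so the modal bin sits in the middle of the support
    shift = nbins // 2 - mode_idx
    dens_s = np.roll(dens, shift)
    mode_angle = centers[mode_idx]

    nonzero = np.count_nonzero(dens_s)
    if nonzero <= 1:
        # degenerate spike: all mass in one bin; centre on the data
        return AngularOrganization(
            A=float(dens_s.max()), y0=0.0, center_deg=float(np.median(angles)),
            fwhm_deg=float(bin_deg), y0_clamped=True,
        )

    y0_guess = float(np.median(dens_s))
    a_guess = max(float(dens_s.max() - y0_guess), 1e-6)
    p0 = [y0_guess, a_guess, float(centers[nbins // 2]), max(bin_deg, 10.0)]
    bounds = ([0.0, 0.0, -90.0, bin_deg / FWHM_PER_SIGMA],
              [np.inf, np.inf, 90.0, 360.0])
    try:
        popt, _ = curve_fit(_gauss_bg, centers, dens_s, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"angular Gaussian fit did not converge (n={n}, bins={nbins}): {err}"
        ) from err
    y0, a, c_shifted, sigma = popt

    center = c_shifted + (mode_angle - centers[nbins // 2])
    center = ((center + 90.0) % 180.0) - 90.0
    if center == -90.0:
        center = 90.0

    y0_clamped = y0 < 1e-12
    fwhm = max(FWHM_PER_SIGMA * sigma, bin_deg)
    return AngularOrganization(
        A=float(a), y0=float(max(y0, 0.0)), center_deg=float(center),
        fwhm_deg=float(fwhm), y0_clamped=bool(y0_clamped),
    )


# ---------------------------------------------------------------------------
# thin-film interference

def thin_film_wavelength(
    minor_axis_nm: float | np.ndarray,
    model: ThinFilmModel | None = None,
) -> float | np.ndarray:
    """Predicted reflected wavelength(s) for platelet thickness d.

    Quarter-wave single-layer condition: lambda = 4 * n * d.
    """
    model = model or ThinFilmModel()
    d = np.asarray(minor_axis_nm, dtype=float)
    if np.any(d < 0):
        raise ValueError("platelet thickness must be nonnegative")
    lam = 4.0 * model.n_platelet * d
    return float(lam) if np.isscalar(minor_axis_nm) else lam


def predicted_wavelength_peak(
    platelets: PlateletSet | np.ndarray,
    model: ThinFilmModel | None = None,
    *,
    grid_step_nm: float = 1.0,
) -> float:
    """Density peak of the per-platelet predicted-wavelength distribution.

    The mode of a Gaussian kernel density (Silverman bandwidth) over the
    individual thin-film predictions.
    """
    d = platelets.minor_nm if isinstance(platelets, PlateletSet) else np.asarray(platelets, float)
    lam = np.asarray(thin_film_wavelength(d, model))
    if lam.size == 0:
        raise ValueError("no platelets to predict from")
    if lam.size == 1 or np.ptp(lam) == 0:
        return float(lam[0])
    kde = gaussian_kde(lam, bw_method="silverman")
    grid = np.arange(lam.min(), lam.max() + grid_step_nm, grid_step_nm)
    return float(grid[int(np.argmax(kde(grid)))])
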