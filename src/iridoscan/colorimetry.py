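"""Reflectance colorimetry: spectra I/O, processing and summary variables.

A reflectance spectrum is relative reflectance (%) on an ascending
wavelength grid restricted to 300–700 nm.  Spectra are processed by
loess-family smoothing (span as a fraction of points) followed by clamping
negative reflectance to zero, and then summarised into the standard
avian/reptile colorimetric variables:

* B1 — total brightness, the sum of reflectance over the grid;
* H1 — hue, the wavelength of maximum reflectance;
* S1.X — chroma, the fraction of total brightness inside a named band:
  UV 300–400, blue 400–510, green 510–605, yellow 550–625, red 605–700 nm
  (endpoints inclusive; yellow overlaps green and red).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._smoothing import loess_smooth

WAVELENGTH_MIN_NM = 300.0
WAVELENGTH_MAX_NM = 700.0

#: Chroma band bounds (nm), both endpoints inclusive.
CHROMA_BANDS: dict[str, tuple[float, float]] = {
    "S1_UV": (300.0, 400.0),
    "S1_blue": (400.0, 510.0),
    "S1_green": (510.0, 605.0),
    "S1_yellow": (550.0, 625.0),
    "S1_red": (605.0, 700.0),
}

REGION_CODES = ("CBC", "DHC", "FLBS", "PM", "ZP")


@dataclass
class ReflectanceSpectrum:
    """One specimen-region reflectance spectrum.

    Attributes
    ----------
    wavelength_nm:
        Strictly increasing wavelength grid (nm), within [300, 700] after
        restriction.
    reflectance_pct:
        Relative reflectance (%); nonnegative once ``processed``.
    meta:
        Specimen metadata (``id``, ``taxon``, ``sex``, ``region`` ...).
    processed:
        Whether smoothing and negative-clamping have been applied.
    """

    wavelength_nm: np.ndarray
    reflectance_pct: np.ndarray
    meta: dict = field(default_factory=dict)
    processed: bool = False

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.reflectance_pct = np.asarray(self.reflectance_pct, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.shape != self.reflectance_pct.shape:
            raise ValueError("wavelength and reflectance must be 1-D arrays of equal length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def grid_step_nm(self) -> float:
        """Median grid spacing in nm."""
        return float(np.median(np.diff(self.wavelength_nm)))

    def restrict(
        self, lo: float = WAVELENGTH_MIN_NM, hi: float = WAVELENGTH_MAX_NM
    ) -> "ReflectanceSpectrum":
        """Return a copy restricted to wavelengths in [lo, hi]."""
        keep = (self.wavelength_nm >= lo) & (self.wavelength_nm <= hi)
        return replace(
            self,
            wavelength_nm=self.wavelength_nm[keep],
            reflectance_pct=self.reflectance_pct[keep],
            meta=dict(self.meta),
        )


@dataclass
class ColourSummary:
    """Brightness/hue/chroma summary of one processed spectrum.

    ``B1`` is grid-dependent (a plain sum over samples); comparisons are
    only meaningful among spectra on the same grid.  For an all-zero
    spectrum B1 = 0 and H1/S1 are NaN.
    """

    B1: float
    H1: float
    S1_UV: float
    S1_blue: float
    S1_green: float
    S1_yellow: float
    S1_red: float
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("B1", "H1", "S1_UV", "S1_blue", "S1_green", "S1_yellow", "S1_red")}
        d.update(self.meta)
        return d


SUMMARY_COLUMNS = ["B1", "H1", "S1_UV", "S1_blue", "S1_green", "S1_yellow", "S1_red"]


# ---------------------------------------------------------------------------
# I/O

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV with columns id, taxon, sex, region."""
    sheet = pd.read_csv(path, dtype=str)
    required = {"id", "taxon", "sex", "region"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    return sheet


def filter_melanistic(sheet: pd.DataFrame) -> pd.DataFrame:
    """Drop rows flagged melanistic (column ``melanistic`` truthy), if present.

    Melanistic individuals lose their bright colour pattern and are excluded
    from colour analyses via this sample-sheet flag rather than hard-coded
    ids.
    """
    if "melanistic" not in sheet.columns:
        return sheet
    flag = sheet["melanistic"].astype(str).str.lower().isin({"1", "true", "yes", "y"})
    return sheet.loc[~flag].reset_index(drop=True)


def read_spectra(
    path: str | Path,
    sample_sheet: str | Path | pd.DataFrame,
    *,
    exclude_melanistic: bool = False,
) -> list[ReflectanceSpectrum]:
    """Read spectra from a CSV table and join specimen metadata.

    Accepts a wide table (``wavelength`` plus one column per spectrum id) or
    a long table (columns ``wavelength``, ``reflectance``, ``specimen``).
    Each spectrum is restricted to [300, 700] nm.  Every spectrum id must
    have a matching row in the sample sheet.
    """
    df = pd.read_csv(path)
    if isinstance(sample_sheet, (str, Path)):
        sheet = read_sample_sheet(sample_sheet)
    else:
        sheet = sample_sheet
    excluded: set[str] = set()
    if exclude_melanistic:
        kept = filter_melanistic(sheet)
        excluded = set(sheet["id"]) - set(kept["id"])
        sheet = kept
    sheet = sheet.set_index("id")

    cols = {c.lower(): c for c in df.columns}
    if "wavelength" not in cols:
        raise ValueError("spectra table must have a 'wavelength' column")
    wl_col = cols["wavelength"]

    spectra: list[ReflectanceSpectrum] = []
    if {"reflectance", "specimen"} <= set(cols):
        # long format
        for sid, sub in df.groupby(cols["specimen"], sort=False):
            if str(sid) in excluded:
                continue
            spectra.append(
                _make_spectrum(
                    sub[wl_col].to_numpy(float),
                    sub[cols["reflectance"]].to_numpy(float),
                    str(sid),
                    sheet,
                )
            )
    else:
        wl = df[wl_col].to_numpy(float)
        for col in df.columns:
            if col == wl_col or str(col) in excluded:
                continue
            spectra.append(_make_spectrum(wl, df[col].to_numpy(float), str(col), sheet))
    return spectra


def _make_spectrum(
    wl: np.ndarray, refl: np.ndarray, sid: str, sheet: pd.DataFrame
) -> ReflectanceSpectrum:
    if sid not in sheet.index:
        raise KeyError(f"spectrum '{sid}' has no row in the sample sheet (column 'id')")
    meta = {"id": sid, **sheet.loc[sid].dropna().to_dict()}
    s = ReflectanceSpectrum(wl, refl, meta=meta)
    return s.restrict()


def write_spectra_wide(spectra: Sequence[ReflectanceSpectrum], path: str | Path) -> None:
    """Write spectra sharing one grid as a wide CSV (wavelength + id columns)."""
    wl = spectra[0].wavelength_nm
    for s in spectra[1:]:
        if not np.array_equal(s.wavelength_nm, wl):
            raise ValueError("all spectra must share one wavelength grid")
    out = pd.DataFrame({"wavelength": wl})
    for s in spectra:
        out[str(s.meta.get("id"))] = s.reflectance_pct
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Processing and summaries

def process_spectrum(s: ReflectanceSpectrum, span: float = 0.3) -> ReflectanceSpectrum:
    """Smooth (local linear regression, neighbourhood = ``span`` of points)
    then clamp negative reflectance to exactly zero."""
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    smoothed = loess_smooth(s.wavelength_nm, s.reflectance_pct, span=span)
    smoothed = np.maximum(smoothed, 0.0)
    return replace(s, reflectance_pct=smoothed, meta=dict(s.meta), processed=True)


def summarize(s: ReflectanceSpectrum) -> ColourSummary:
    """Compute B1, H1 and the five chroma segments of a processed spectrum."""
    wl = s.wavelength_nm
    r = s.reflectance_pct
    b1 = float(np.sum(r))
    if b1 == 0.0:
        vals = {k: float("nan") for k in CHROMA_BANDS}
        return ColourSummary(B1=0.0, H1=float("nan"), meta=dict(s.meta), **vals)
    h1 = float(wl[int(np.argmax(r))])  # argmax takes the lowest wavelength on ties
    seg = {}
    for name, (lo, hi) in CHROMA_BANDS.items():
        mask = (wl >= lo) & (wl <= hi)
        seg[name] = float(np.sum(r[mask]) / b1)
    return ColourSummary(B1=b1, H1=h1, meta=dict(s.meta), **seg)


def summarize_table(
    spectra: Iterable[ReflectanceSpectrum],
    *,
    span: float | None = 0.3,
) -> pd.DataFrame:
    """Process (unless ``span`` is None) and summarise spectra into a table.

    Returns one row per spectrum with the summary variables followed by
    metadata columns.
    """
    rows = []
    for s in spectra:
        if span is not None and not s.processed:
            s = process_spectrum(s, span=span)
        rows.append(summarize(s).as_dict())
    return pd.DataFrame(rows)


def write_summary(
    table: pd.DataFrame,
    path: str | Path,
    *,
    params: Mapping | None = None,
) -> None:
    """Write the summary table as CSV with a JSON sidecar of parameters."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(dict(params or {}), fh, indent=2, sort_keys=True)
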