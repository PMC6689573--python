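"""Colorimetry: spectra I/O, loess processing and B1/H1/S1 summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iridoscan import colorimetry as cm
from iridoscan import synthetic_data as sd
from iridoscan.colorimetry import ReflectanceSpectrum


def make_sheet(ids, region="FLBS"):
    return pd.DataFrame(
        {"id": ids, "taxon": ["A"] * len(ids), "sex": ["f"] * len(ids),
         "region": [region] * len(ids)}
    )


# ---------------------------------------------------------------------------
# reading

def test_read_wide_preserves_count_and_clips_grid(tmp_path):
    wl = np.arange(250.0, 751.0)
    df = pd.DataFrame({"wavelength": wl})
    for sid in ["s1", "s2", "s3"]:
        df[sid] = 5.0
    df.to_csv(tmp_path / "spec.csv", index=False)
    make_sheet(["s1", "s2", "s3"]).to_csv(tmp_path / "sheet.csv", index=False)

    spectra = cm.read_spectra(tmp_path / "spec.csv", tmp_path / "sheet.csv")
    assert len(spectra) == 3
    for s in spectra:
        assert s.wavelength_nm[0] == 300.0 and s.wavelength_nm[-1] == 700.0
        assert s.meta["taxon"] == "A" and s.meta["region"] == "FLBS"


def test_read_long_format(tmp_path):
    wl = np.arange(300.0, 701.0)
    long = pd.concat([
        pd.DataFrame({"wavelength": wl, "reflectance": 1.0 + i, "specimen": f"s{i}"})
        for i in range(2)
    ])
    long.to_csv(tmp_path / "long.csv", index=False)
    spectra = cm.read_spectra(tmp_path / "long.csv", make_sheet(["s0", "s1"]))
    assert len(spectra) == 2
    assert spectra[1].reflectance_pct[0] == 2.0


def test_read_missing_metadata_names_spectrum(tmp_path):
    df = pd.DataFrame({"wavelength": np.arange(300.0, 701.0), "sX": 1.0})
    df.to_csv(tmp_path / "spec.csv", index=False)
    make_sheet(["other"]).to_csv(tmp_path / "sheet.csv", index=False)
    with pytest.raises(KeyError, match="sX"):
        cm.read_spectra(tmp_path / "spec.csv", tmp_path / "sheet.csv")


def test_non_monotone_wavelengths_rejected():
    with pytest.raises(ValueError, match="increasing"):
        ReflectanceSpectrum(np.array([300.0, 302.0, 301.0]), np.zeros(3))


def test_synthetic_roundtrip_identical(tmp_path):
    spectra, truth = sd.gen_spectra(3, {"A": sd.GroupEffect()}, noise_sd=0.3, seed=5)
    sp_path, sheet_path = sd.write_spectra_files(spectra, truth, tmp_path)
    back = cm.read_spectra(sp_path, sheet_path)
    assert len(back) == len(spectra)
    for a, b in zip(spectra, back):
        np.testing.assert_allclose(b.reflectance_pct, a.reflectance_pct, rtol=0, atol=1e-9)
        assert b.meta["id"] == a.meta["id"]


def test_melanistic_filter(tmp_path):
    wl = np.arange(300.0, 701.0)
    df = pd.DataFrame({"wavelength": wl, "s1": 1.0, "s2": 2.0})
    df.to_csv(tmp_path / "spec.csv", index=False)
    sheet = make_sheet(["s1", "s2"])
    sheet["melanistic"] = ["false", "true"]
    sheet.to_csv(tmp_path / "sheet.csv", index=False)
    spectra = cm.read_spectra(tmp_path / "spec.csv", tmp_path / "sheet.csv",
                              exclude_melanistic=True)
    assert [s.meta["id"] for s in spectra] == ["s1"]


# ---------------------------------------------------------------------------
# processing

def grid():
    return np.arange(300.0, 701.0)


def test_process_constant_spectrum_unchanged():
    s = ReflectanceSpectrum(grid(), np.full(401, 5.0))
    out = cm.process_spectrum(s)
    np.testing.assert_allclose(out.reflectance_pct, 5.0, atol=1e-9)
    assert out.processed


def test_process_clamps_negative_values():
    r = np.full(401, -0.01)
    out = cm.process_spectrum(ReflectanceSpectrum(grid(), r))
    assert np.all(out.reflectance_pct == 0.0)


def test_process_rejects_bad_span():
    s = ReflectanceSpectrum(grid(), np.ones(401))
    for span in (0.0, -0.2, 1.5):
        with pytest.raises(ValueError):
            cm.process_spectrum(s, span=span)


def _reference_local_linear(y, x, frac):
    """Independent degree-1 local regression with tricube weights."""
    n = len(x)
    k = int(frac * n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[k - 1]
        w = (1 - np.clip(d / h, 0, 1) ** 3) ** 3
        X = np.column_stack([np.ones(n), x - x[i]])
        wx = X * w[:, None]
        beta = np.linalg.solve(wx.T @ X, wx.T @ y)
        out[i] = beta[0]
    return out


def test_smoothing_matches_local_linear_reference():
    rng = np.random.default_rng(1)
    wl = grid()
    r = 10.0 + rng.normal(0.0, 1.0, wl.size)
    out = cm.process_spectrum(ReflectanceSpectrum(wl, r), span=0.3)
    ref = np.maximum(_reference_local_linear(r, wl, 0.3), 0.0)
    np.testing.assert_allclose(out.reflectance_pct, ref, atol=1e-6)
    assert out.reflectance_pct.var() < r.var()


def test_smoother_reproduces_linear_ramp():
    wl = grid()
    ramp = 0.02 * (wl - 300.0) + 1.0
    out = cm.process_spectrum(ReflectanceSpectrum(wl, ramp))
    np.testing.assert_allclose(out.reflectance_pct, ramp, atol=1e-8)


# ---------------------------------------------------------------------------
# summaries

def test_flat_spectrum_segment_fractions():
    s = ReflectanceSpectrum(grid(), np.full(401, 3.0), processed=True)
    cs = cm.summarize(s)
    assert cs.H1 == 300.0
    np.testing.assert_allclose(
        [cs.S1_UV, cs.S1_blue, cs.S1_green, cs.S1_yellow, cs.S1_red],
        [101 / 401, 111 / 401, 96 / 401, 76 / 401, 96 / 401],
    )


def test_single_support_spectrum():
    r = np.zeros(401)
    r[np.where(grid() == 550.0)[0][0]] = 10.0
    cs = cm.summarize(ReflectanceSpectrum(grid(), r, processed=True))
    assert cs.H1 == 550.0
    assert cs.S1_green == 1.0 and cs.S1_yellow == 1.0
    assert cs.S1_UV == cs.S1_blue == cs.S1_red == 0.0


def test_gaussian_summary_matches_bruteforce():
    wl = grid()
    r = 20.0 * np.exp(-((wl - 520.0) ** 2) / (2 * 30.0**2))
    cs = cm.summarize(ReflectanceSpectrum(wl, r, processed=True))
    # brute-force python loop, independent of the vectorized path
    b1 = sum(float(v) for v in r)
    seg = {name: 0.0 for name in cm.CHROMA_BANDS}
    for w, v in zip(wl, r):
        for name, (lo, hi) in cm.CHROMA_BANDS.items():
            if lo <= w <= hi:
                seg[name] += float(v)
    assert cs.B1 == pytest.approx(b1, rel=1e-12)
    for name in seg:
        assert getattr(cs, name) == pytest.approx(seg[name] / b1, rel=1e-12)
    assert cs.H1 == 520.0


def test_all_zero_spectrum_gives_missing_summaries():
    cs = cm.summarize(ReflectanceSpectrum(grid(), np.zeros(401), processed=True))
    assert cs.B1 == 0.0
    assert np.isnan(cs.H1) and np.isnan(cs.S1_green)


def test_h1_tie_break_lowest_wavelength():
    r = np.zeros(401)
    r[10] = r[200] = 5.0
    cs = cm.summarize(ReflectanceSpectrum(grid(), r, processed=True))
    assert cs.H1 == 310.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(k=st.floats(0.01, 100.0), seed=st.integers(0, 10_000))
def test_scale_equivariance(k, seed):
    r = np.random.default_rng(seed).uniform(0.0, 30.0, 401)
    base = cm.summarize(ReflectanceSpectrum(grid(), r, processed=True))
    scaled = cm.summarize(ReflectanceSpectrum(grid(), k * r, processed=True))
    assert scaled.B1 == pytest.approx(k * base.B1, rel=1e-9)
    assert scaled.H1 == base.H1
    for name in cm.CHROMA_BANDS:
        assert getattr(scaled, name) == pytest.approx(getattr(base, name), rel=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_sum_rule_tiling_segments(seed):
    r = np.random.default_rng(seed).uniform(0.0, 30.0, 401)
    cs = cm.summarize(ReflectanceSpectrum(grid(), r, processed=True))
    total = cs.S1_UV + cs.S1_blue + cs.S1_green + cs.S1_red
    # boundary samples 400, 510, 605 are double counted (inclusive endpoints)
    assert 1.0 - 1e-12 <= total <= 1.0 + 3 * r.max() / cs.B1 + 1e-12


def test_moving_mass_from_red_to_uv_increases_uv_chroma():
    wl = grid()
    r = np.full(401, 1.0)
    red_idx = np.where(wl == 650.0)[0][0]
    uv_idx = np.where(wl == 350.0)[0][0]
    r_red = r.copy(); r_red[red_idx] += 10.0
    r_uv = r.copy(); r_uv[uv_idx] += 10.0
    c_red = cm.summarize(ReflectanceSpectrum(wl, r_red, processed=True))
    c_uv = cm.summarize(ReflectanceSpectrum(wl, r_uv, processed=True))
    assert c_uv.S1_UV > c_red.S1_UV
    assert c_uv.S1_red < c_red.S1_red


def test_summary_table_and_sidecar(tmp_path):
    spectra, truth = sd.gen_spectra(2, {"A": sd.GroupEffect()}, noise_sd=0.0, seed=1)
    table = cm.summarize_table(spectra)
    assert list(table.columns[:7]) == cm.SUMMARY_COLUMNS
    assert len(table) == 2
    cm.write_summary(table, tmp_path / "summary.csv", params={"span": 0.3})
    assert (tmp_path / "summary.csv").exists()
    assert (tmp_path / "summary.csv.json").exists()
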