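"""Fourier analysis of collagen textures: power spectra, radial averages,
frequency-to-wavelength mapping and composite reflectivity."""

import numpy as np
import pytest

from iridoscan import collagen_fourier as cf
from iridoscan import synthetic_data as sd

N_AVG = 1.385


# ---------------------------------------------------------------------------
# prepare_square

def test_all_dark_square_maps_to_collagen_index():
    cfg = cf.FourierConfig(square_px=64)
    field = cf.prepare_square(np.zeros((64, 64)), 10.0, cfg)
    assert np.all(field == 1.42)


def test_binary_image_maps_to_two_indices():
    img = np.zeros((64, 64))
    img[:, 32:] = 255.0
    field = cf.prepare_square(img, 10.0, cf.FourierConfig(square_px=64))
    assert set(np.unique(field)) == {1.35, 1.42}
    assert np.all(field[:, :32] == 1.42)  # dark half = fibre


def test_prepare_square_rejects_small_image():
    with pytest.raises(ValueError, match="smaller"):
        cf.prepare_square(np.zeros((100, 100)), 10.0, cf.FourierConfig(square_px=256))


def test_fibre_area_fraction_recovered():
    img, truth = sd.gen_collagen_image(seed=2, size_px=400)
    field = cf.prepare_square(img, 18.0, cf.FourierConfig(square_px=400))
    frac = float(np.mean(field == 1.42))
    assert frac == pytest.approx(truth.table["fibre_area_fraction"].iloc[0], abs=0.05)


def test_fourier_config_validation():
    with pytest.raises(ValueError):
        cf.FourierConfig(n_collagen=1.3, n_matrix=1.35)
    with pytest.raises(ValueError):
        cf.FourierConfig(n_bins=1)
    assert cf.FourierConfig().n_avg == pytest.approx(N_AVG)
    assert cf.FourierConfig().bin_width_nm == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# power spectrum

def test_constant_field_has_zero_power():
    power, _, _ = cf.power_spectrum_2d(np.full((32, 32), 7.0), 10.0)
    assert np.all(power == 0.0)


def test_sinusoid_gives_two_symmetric_peaks():
    n, period, scale = 200, 20, 5.0
    x = np.arange(n)
    field = np.sin(2 * np.pi * x / period)[None, :] * np.ones((n, 1))
    power, fy, fx = cf.power_spectrum_2d(field, scale)
    hot = np.argwhere(power > power.max() * 0.5)
    assert len(hot) == 2
    freqs = sorted(fx[c] for _, c in hot)
    assert freqs[0] == pytest.approx(-1.0 / (period * scale))
    assert freqs[1] == pytest.approx(+1.0 / (period * scale))
    assert all(fy[r] == 0.0 for r, _ in hot)


def test_parseval_total_power_equals_variance_times_npix():
    rng = np.random.default_rng(9)
    field = rng.integers(0, 2, size=(128, 128)).astype(float)
    power, _, _ = cf.power_spectrum_2d(field, 4.0)
    expected = field.var() * field.size
    assert power.sum() == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------------------
# radial average

def naive_radial_average(power, fy, fx):
    """Independent per-pixel annulus accumulation."""
    df = fy[1] - fy[0]
    sums, counts = {}, {}
    for i in range(power.shape[0]):
        for j in range(power.shape[1]):
            r = np.hypot(fy[i], fx[j])
            b = int(np.floor(r / df + 0.5))
            sums[b] = sums.get(b, 0.0) + power[i, j]
            counts[b] = counts.get(b, 0) + 1
    nb = max(sums) + 1
    means = np.array([sums.get(b, 0.0) / counts.get(b, 1) for b in range(nb)])
    return means / means.sum()


def test_radial_average_matches_naive_accumulation():
    rng = np.random.default_rng(9)
    field = rng.normal(size=(48, 48))
    power, fy, fx = cf.power_spectrum_2d(field, 3.0)
    prof = cf.radial_average(power, fy, fx)
    oracle = naive_radial_average(power, fy, fx)
    np.testing.assert_allclose(prof.power, oracle, atol=1e-9)
    assert prof.power.sum() == pytest.approx(1.0, abs=1e-9)


def ring_field(n, period_px, laminar=False):
    yy, xx = np.mgrid[0:n, 0:n] - n // 2
    if laminar:
        return np.cos(2 * np.pi * xx / period_px)
    r = np.hypot(yy, xx)
    return np.cos(2 * np.pi * r / period_px)


def test_isotropic_ring_localized_in_radial_bin():
    n, period, scale = 256, 16, 4.0
    power, fy, fx = cf.power_spectrum_2d(ring_field(n, period), scale)
    prof = cf.radial_average(power, fy, fx)
    f0 = 1.0 / (period * scale)
    df = prof.freq_per_nm[1] - prof.freq_per_nm[0]
    assert abs(prof.peak_frequency() - f0) <= df


def test_laminar_and_isotropic_share_radial_peak_bin():
    n, period, scale = 256, 16, 4.0
    peaks = []
    for laminar in (False, True):
        power, fy, fx = cf.power_spectrum_2d(ring_field(n, period, laminar), scale)
        peaks.append(cf.radial_average(power, fy, fx).peak_frequency())
    assert peaks[0] == pytest.approx(peaks[1], abs=1e-12)


def test_radial_profile_rotation_invariant():
    rng = np.random.default_rng(3)
    field = rng.normal(size=(128, 128))
    power, fy, fx = cf.power_spectrum_2d(field, 5.0)
    p_rot, fy2, fx2 = cf.power_spectrum_2d(np.rot90(field), 5.0)
    a = cf.radial_average(power, fy, fx).power
    b = cf.radial_average(p_rot, fy2, fx2).power
    np.testing.assert_allclose(a, b, atol=1e-9)


# ---------------------------------------------------------------------------
# wavelength mapping and reflectivity

def test_frequency_wavelength_arithmetic():
    assert cf.wavelength_for_frequency(0.00923) == pytest.approx(300.1, abs=0.05)
    assert round(cf.frequency_for_wavelength(300.0), 4) == 0.0092


def test_reflectivity_has_51_bins_of_10nm():
    profile = cf.RadialPowerProfile(
        freq_per_nm=np.linspace(0, 0.02, 100), power=np.full(100, 0.01),
        scale_nm_per_px=10.0,
    )
    refl = cf.predicted_reflectivity(profile)
    assert len(refl.wavelength_nm) == 51
    steps = np.diff(refl.wavelength_nm)
    np.testing.assert_allclose(steps, 10.0)
    assert refl.wavelength_nm[0] == 300.0 and refl.wavelength_nm[-1] == 800.0


def test_reflectivity_mass_conservation():
    rng = np.random.default_rng(8)
    p = rng.random(80)
    profile = cf.RadialPowerProfile(
        freq_per_nm=np.linspace(0, 0.05, 80), power=p / p.sum(), scale_nm_per_px=5.0,
    )
    refl = cf.predicted_reflectivity(profile)
    total = refl.reflectivity.sum() + refl.sub_range_mass + refl.above_range_mass
    assert total == pytest.approx(1.0, abs=1e-9)


def test_spike_at_550nm_frequency_lands_in_550_bin():
    f0 = 2 * N_AVG / 550.0
    freqs = np.linspace(0, 0.02, 400)
    power = np.zeros(400)
    power[np.argmin(np.abs(freqs - f0))] = 1.0
    profile = cf.RadialPowerProfile(freq_per_nm=freqs, power=power, scale_nm_per_px=5.0)
    refl = cf.predicted_reflectivity(profile)
    assert abs(refl.peak_wavelength() - 550.0) <= 5.0


def test_scale_covariance_doubles_wavelength():
    img, _ = sd.gen_collagen_image(seed=6, size_px=400)
    cfg = cf.FourierConfig(square_px=400)
    prof1, _ = cf.analyze_micrograph(img, 18.0, cfg)
    prof2, _ = cf.analyze_micrograph(img, 36.0, cfg)
    np.testing.assert_allclose(prof2.freq_per_nm, prof1.freq_per_nm / 2.0)
    np.testing.assert_allclose(prof2.power, prof1.power, atol=1e-12)
    assert prof2.peak_frequency() == pytest.approx(prof1.peak_frequency() / 2.0)


def test_end_to_end_spacing_recovery():
    spacing = 550.0 / (2 * N_AVG)
    img, _ = sd.gen_collagen_image(mean_spacing_nm=spacing, spacing_cv=0.05, seed=12)
    prof, refl = cf.analyze_micrograph(img, 18.0)
    assert prof.peak_frequency() == pytest.approx(1.0 / spacing, rel=0.10)
    assert refl.peak_wavelength() == pytest.approx(2 * N_AVG * spacing, rel=0.10)


# ---------------------------------------------------------------------------
# composites

def fake_reflectivity(values):
    cfg = cf.FourierConfig()
    return cf.PredictedReflectivity(
        wavelength_nm=cfg.wavelength_bin_centers_nm, reflectivity=np.asarray(values, float)
    )


def test_composite_single_profile_is_identity():
    r = fake_reflectivity(np.linspace(0, 1, 51))
    comp = cf.composite_reflectivity([r])
    np.testing.assert_allclose(comp.reflectivity, r.reflectivity)


def test_composite_two_profiles_is_mean():
    a = fake_reflectivity(np.linspace(0, 1, 51))
    b = fake_reflectivity(np.linspace(1, 0, 51))
    comp = cf.composite_reflectivity([a, b])
    np.testing.assert_allclose(comp.reflectivity, 0.5 * (a.reflectivity + b.reflectivity))


def test_composite_rejects_mismatched_grids():
    a = fake_reflectivity(np.zeros(51))
    b = fake_reflectivity(np.zeros(51))
    b.wavelength_nm = b.wavelength_nm + 1.0
    with pytest.raises(ValueError, match="mismatch"):
        cf.composite_reflectivity([a, b])


def test_composite_smoothed_peak_within_one_bin():
    spacing = 550.0 / (2 * N_AVG)
    refls = []
    for seed in range(1, 11):
        img, _ = sd.gen_collagen_image(mean_spacing_nm=spacing, spacing_cv=0.1, seed=seed)
        _, refl = cf.analyze_micrograph(img, 18.0)
        refls.append(refl)
    comp = cf.composite_reflectivity(refls)
    assert abs(comp.peak_wavelength() - 550.0) <= 10.0
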