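"""Spectral processing chain: apodization/zero-fill/FFT, phasing,
baseline correction, ppm calibration, and matrix assembly."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from nmrmwas import (
    Acquisition,
    CalibrationError,
    FID,
    ProcessingParams,
    apodize_zero_fill_fft,
    assemble_spectrum_set,
    auto_phase,
    baseline_correct,
    calibrate_ppm,
    generate_fid,
    process_fid,
)
from nmrmwas.processing import read_fid_tsv, write_fid_tsv
from nmrmwas.templates import MetaboliteTemplate, Multiplet


ACQ = Acquisition(dwell_time=1 / 6000, n_points=8192,
                  spectrometer_frequency=600.0, carrier_ppm=4.7)


def single_line_fid(t2=0.3, ppm=5.0, acq=ACQ):
    tmpl = MetaboliteTemplate("x", peaks=(Multiplet(ppm, (0.0,), (1.0,), t2),))
    return generate_fid({"x": 1.0}, [tmpl], acq)


def measure_fwhm(y, x):
    """Full width at half maximum with linear interpolation of the
    half-height crossings."""
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = np.where(y[:i] < half)[0][-1]
    right = i + np.where(y[i:] < half)[0][0]
    xl = x[left] + (x[left + 1] - x[left]) * (half - y[left]) / (y[left + 1] - y[left])
    xr = x[right - 1] + (x[right] - x[right - 1]) * (half - y[right - 1]) / (y[right] - y[right - 1])
    return xr - xl


def test_zero_fill_factor_two_doubles_points():
    """A 65,536-point FID zero-filled by two gives 131,072 (128K)
    frequency-domain points."""
    fid = FID(np.zeros(65536, dtype=complex) + 1.0, 1 / 12000, 600.0)
    spec, hz = apodize_zero_fill_fft(fid, ProcessingParams(zero_fill_factor=2))
    assert spec.size == 131072 == 128 * 1024
    assert hz.size == 131072


def test_lorentzian_fwhm_no_broadening():
    """A decaying sinusoid with relaxation time T2 gives a Lorentzian of
    width 1/(pi*T2) Hz."""
    t2 = 0.3
    spec, hz = apodize_zero_fill_fft(single_line_fid(t2),
                                     ProcessingParams(line_broadening_hz=0.0))
    real = auto_phase(spec)
    step = hz[1] - hz[0]
    assert abs(measure_fwhm(real, hz) - 1 / (math.pi * t2)) < step


def test_line_broadening_adds_to_fwhm():
    """Exponential apodization by lb Hz convolves with a Lorentzian of that
    width: FWHM = 1/(pi*T2) + lb."""
    t2, lb = 0.3, 0.8
    spec, hz = apodize_zero_fill_fft(single_line_fid(t2),
                                     ProcessingParams(line_broadening_hz=lb))
    real = auto_phase(spec)
    step = hz[1] - hz[0]
    assert abs(measure_fwhm(real, hz) - (1 / (math.pi * t2) + lb)) < step


def test_fft_energy_scales_with_zero_filling():
    """Zero filling pads with zeros: total spectral power is unchanged
    (Parseval, time-domain energy fixed) while points double."""
    fid = single_line_fid()
    p = ProcessingParams(line_broadening_hz=0.0)
    s1, _ = apodize_zero_fill_fft(fid, ProcessingParams(line_broadening_hz=0.0, zero_fill_factor=1))
    s2, _ = apodize_zero_fill_fft(fid, p)
    # Parseval: sum|S|^2 = N * sum|s|^2; N doubles under zero filling
    assert np.abs(s2).__pow__(2).sum() / np.abs(s1).__pow__(2).sum() == pytest.approx(2.0, rel=1e-9)


def test_apodization_rejects_empty_fid():
    with pytest.raises(ValueError):
        FID(np.array([], dtype=complex), 1 / 6000, 600.0)


# ---------------------------------------------------------------------
# phasing


def test_autophase_identity_on_absorption_spectrum():
    spec, _ = apodize_zero_fill_fft(single_line_fid())
    real = auto_phase(spec)
    real2 = auto_phase(real.astype(complex))
    np.testing.assert_allclose(real2, real, atol=1e-6 * real.max())


def test_autophase_recovers_known_rotation():
    spec, _ = apodize_zero_fill_fft(single_line_fid())
    ref = auto_phase(spec)
    for deg in (30.0, 90.0, -120.0):
        rotated = (ref.astype(complex)) * np.exp(1j * math.radians(deg))
        rec = auto_phase(rotated)
        np.testing.assert_allclose(rec, ref, atol=1e-4 * ref.max())


def test_autophase_pure_noise_is_total():
    rng = np.random.default_rng(0)
    noise = rng.standard_normal(512) + 1j * rng.standard_normal(512)
    out = auto_phase(noise)
    assert out.dtype.kind == "f" and np.all(np.isfinite(out))


def test_autophase_all_zero_warns_and_passes_through():
    with pytest.warns(UserWarning, match="all-zero"):
        out = auto_phase(np.zeros(32, dtype=complex))
    assert not np.any(out)


# ---------------------------------------------------------------------
# baseline


def peaks_fixture(n=2000):
    x = np.linspace(0, 1, n)
    y = np.zeros(n)
    for c in (0.3, 0.6):
        y += 0.002 ** 2 / ((x - c) ** 2 + 0.002 ** 2)
    return x, y


def test_baseline_removes_constant_offset():
    _, y = peaks_fixture()
    out = baseline_correct(y + 5.0)
    off_peak = np.abs(out[:400])
    assert np.median(off_peak) < 0.05
    assert abs(out.max() - y.max()) / y.max() < 0.05


def test_baseline_removes_linear_ramp():
    x, y = peaks_fixture()
    out = baseline_correct(y + 2.0 + 3.0 * x)
    assert np.argmax(out) == np.argmax(y)  # peak position unchanged
    assert abs(np.median(out[np.abs(y) < 1e-3])) < 0.05
    assert abs(out.max() - y.max()) / y.max() < 0.05


def test_baseline_zero_spectrum_is_zero():
    np.testing.assert_allclose(baseline_correct(np.zeros(100)), 0.0, atol=1e-12)


def test_baseline_rejects_short_input():
    with pytest.raises(ValueError):
        baseline_correct(np.ones(5))


# ---------------------------------------------------------------------
# calibration


def glucose_spectrum(shift_ppm=0.0):
    acq = ACQ
    tmpl = MetaboliteTemplate(
        "glucose", peaks=(Multiplet(5.233 + shift_ppm, (0.0,), (1.0,), 0.3),))
    fid = generate_fid({"glucose": 1.0}, [tmpl], acq)
    spec, hz = apodize_zero_fill_fft(fid)
    return auto_phase(spec), hz


def test_calibration_zero_shift_when_peak_on_reference():
    y, hz = glucose_spectrum(0.0)
    _, ppm, ok = calibrate_ppm(y, hz, 600.0)
    assert ok
    assert abs(ppm[np.argmax(y)] - 5.233) < 1e-9


def test_calibration_corrects_displaced_reference():
    y, hz = glucose_spectrum(+0.01)
    _, ppm_raw, _ = calibrate_ppm(y, hz, 600.0, strict=False,
                                  params=ProcessingParams(reference_search_window=1e-9))
    _, ppm, ok = calibrate_ppm(y, hz, 600.0)
    assert ok
    # axis shifted by -0.01 ppm: the displaced peak lands on 5.233
    assert abs(ppm[np.argmax(y)] - 5.233) < 1e-9
    step_ppm = (hz[1] - hz[0]) / 600.0
    np.testing.assert_allclose(ppm_raw - ppm, 0.01, atol=step_ppm)


def test_calibration_failure_flags_sample():
    y = np.zeros(1000)
    hz = np.linspace(-3000, 3000, 1000)
    with pytest.raises(CalibrationError):
        calibrate_ppm(y, hz, 600.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, ppm, ok = calibrate_ppm(y, hz, 600.0, strict=False)
    assert not ok
    np.testing.assert_allclose(ppm, hz / 600.0 + 4.7)


def test_calibration_idempotent(grid):
    y, hz = glucose_spectrum(+0.005)
    _, ppm1, _ = calibrate_ppm(y, hz, 600.0)
    # calibrating an already-calibrated spectrum is a no-op
    p = ProcessingParams()
    lo = 5.233 - p.reference_search_window
    inside = (ppm1 >= lo) & (ppm1 <= 5.233 + p.reference_search_window)
    peak = np.argmax(np.where(inside, y, -np.inf))
    assert abs(ppm1[peak] - 5.233) < 1e-9


# ---------------------------------------------------------------------
# assembly


def test_assemble_identity_on_grid():
    ppm = np.linspace(0, 10, 50)
    y = np.sin(ppm)
    meta = pd.DataFrame({"sample_id": ["a"]})
    sset = assemble_spectrum_set([(y, ppm)], ppm, meta)
    np.testing.assert_allclose(sset.intensities[0], y)


def test_assemble_two_identical_spectra():
    ppm = np.linspace(0, 10, 50)
    y = np.cos(ppm)
    meta = pd.DataFrame({"sample_id": ["a", "b"]})
    sset = assemble_spectrum_set([(y, ppm), (y, ppm)], ppm, meta)
    np.testing.assert_allclose(sset.intensities[0], sset.intensities[1])


def test_assemble_linear_interpolation_closed_form():
    # hand-computed: fine grid [0,1,2,3,4] values [0,2,4,6,8] onto [0.5,...]
    fine = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    vals = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
    coarse = np.array([0.5, 1.5, 2.5, 3.5])
    meta = pd.DataFrame({"sample_id": ["a"]})
    sset = assemble_spectrum_set([(vals, fine)], coarse, meta)
    np.testing.assert_allclose(sset.intensities[0], [1.0, 3.0, 5.0, 7.0])


def test_assemble_accepts_descending_axis():
    ppm = np.linspace(0, 10, 50)
    y = np.sin(ppm)
    meta = pd.DataFrame({"sample_id": ["a"]})
    sset = assemble_spectrum_set([(y[::-1], ppm[::-1])], ppm, meta)
    np.testing.assert_allclose(sset.intensities[0], y)


def test_assemble_mismatched_metadata_errors():
    ppm = np.linspace(0, 10, 20)
    meta = pd.DataFrame({"sample_id": ["a", "b"]})
    with pytest.raises(ValueError):
        assemble_spectrum_set([(np.zeros(20), ppm)], ppm, meta)


def test_processing_is_order_independent():
    """Permuting sample order permutes output rows identically."""
    fids = [single_line_fid(t2=0.2 + 0.05 * k) for k in range(3)]
    processed = [process_fid(f) for f in fids]
    ppm = processed[0][1]
    meta = pd.DataFrame({"sample_id": ["a", "b", "c"]})
    s1 = assemble_spectrum_set([(y, p) for y, p, _ in processed], ppm, meta)
    order = [2, 0, 1]
    meta2 = pd.DataFrame({"sample_id": [meta["sample_id"][i] for i in order]})
    s2 = assemble_spectrum_set([(processed[i][0], processed[i][1]) for i in order],
                               ppm, meta2)
    for new_row, old in enumerate(order):
        np.testing.assert_allclose(s2.intensities[new_row], s1.intensities[old])


def test_fid_tsv_round_trip(tmp_path):
    fid = single_line_fid()
    path = tmp_path / "fid.tsv"
    write_fid_tsv(fid, path)
    back = read_fid_tsv(path)
    np.testing.assert_allclose(back.complex_points, fid.complex_points)
    assert back.dwell_time == fid.dwell_time
    assert back.spectrometer_frequency == fid.spectrometer_frequency
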