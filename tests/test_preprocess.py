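"""Cleaning chain: bandpass, Welch PSD, PSD-score, peak detection, validity
verdicts and the cropped-PSD / spectrogram features."""

import numpy as np
import pytest
from scipy import signal as sps

from wingbeatid import (CleaningConfig, WingbeatRecord, bandpass, crop_psd_db,
                        detect_psd_peaks, l2_normalize, psd_score,
                        simulate_false_trigger, spectrogram, validate,
                        welch_psd)
from conftest import pure_tone_record


def _filter_response_db(freq, config=CleaningConfig(), fs=8000):
    """Analytic two-pass Butterworth attenuation at one frequency, in dB."""
    sos = sps.butter(config.filter_order, [config.band_low, config.band_high],
                     btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return 2 * 20 * np.log10(np.abs(h[0]))  # filtfilt applies |H|^2


def test_bandpass_zero_in_zero_out():
    rec = WingbeatRecord(samples=np.zeros(5000), fs=8000)
    np.testing.assert_array_equal(bandpass(rec).samples, 0.0)


def test_bandpass_attenuates_50hz_at_least_20db():
    rec = pure_tone_record(50.0)
    out = bandpass(rec)
    measured = 20 * np.log10(np.std(out.samples) / np.std(rec.samples))
    assert measured <= -20.0
    assert _filter_response_db(50.0) <= -20.0  # oracle agrees the band stops 50 Hz


def test_bandpass_passes_250hz_within_1db():
    rec = pure_tone_record(250.0)
    out = bandpass(rec)
    measured = 20 * np.log10(np.std(out.samples) / np.std(rec.samples))
    assert abs(measured) <= 1.0
    assert abs(_filter_response_db(250.0)) <= 1.0


def test_bandpass_rejects_too_low_sampling_rate():
    rec = WingbeatRecord(samples=np.zeros(5000), fs=2000)
    with pytest.raises(ValueError):
        bandpass(rec)


def test_welch_psd_has_4097_bins_spanning_nyquist():
    psd = welch_psd(pure_tone_record(250.0))
    assert psd.values.size == 4097
    assert psd.freqs[0] == 0.0
    assert psd.freqs[-1] == 4000.0
    assert np.all(np.diff(psd.freqs) > 0)
    assert np.all(psd.values >= 0)


def test_welch_psd_zero_signal_is_all_zero():
    psd = welch_psd(WingbeatRecord(samples=np.zeros(5000), fs=8000))
    np.testing.assert_array_equal(psd.values, 0.0)


def test_welch_psd_peak_at_nearest_bin_to_tone():
    psd = welch_psd(pure_tone_record(250.0))
    expected_bin = int(round(250.0 / (8000 / 8192)))
    assert psd.values.argmax() == expected_bin


def test_welch_equals_single_hann_periodogram():
    """For one 5,000-sample segment, Welch reduces to a single Hann-windowed
    zero-padded periodogram (rel. tol. 1e-9)."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(5000)
    psd = welch_psd(WingbeatRecord(samples=x, fs=8000))
    w = sps.get_window("hann", 5000)
    spec = np.abs(np.fft.rfft(x * w, n=8192)) ** 2 / (8000 * np.sum(w ** 2))
    spec[1:-1] *= 2  # one-sided density
    np.testing.assert_allclose(psd.values, spec, rtol=1e-9)


def test_welch_rejects_short_records():
    with pytest.raises(ValueError):
        welch_psd(WingbeatRecord(samples=np.zeros(100), fs=8000))


def test_l2_normalize_properties():
    v = np.abs(np.random.default_rng(1).standard_normal(4097))
    out = l2_normalize(v)
    assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(l2_normalize(10 * v), out, rtol=1e-12)
    one_hot = np.zeros(10)
    one_hot[3] = 1.0
    np.testing.assert_array_equal(l2_normalize(one_hot), one_hot)
    with pytest.raises(ValueError):
        l2_normalize(np.zeros(10))


def test_psd_score_closed_forms_and_bounds():
    one_hot = np.zeros(4097)
    one_hot[100] = 0.5
    assert psd_score(one_hot) == pytest.approx(1.0, abs=1e-12)
    flat = np.full(4097, 0.25)
    assert psd_score(flat) == pytest.approx(np.sqrt(4097), rel=1e-12)
    rng = np.random.default_rng(2)
    for _ in range(20):
        v = np.abs(rng.standard_normal(4097)) + 1e-9
        s = psd_score(v)
        assert 1.0 <= s <= np.sqrt(4097) + 1e-9


def test_reference_fixture_has_exactly_five_peaks(reference_record):
    nz = l2_normalize(welch_psd(bandpass(reference_record)).values)
    peaks = detect_psd_peaks(nz)
    assert len(peaks) == 5
    # peaks sit on the fundamental and its four overtones
    freqs = peaks * 8000 / 8192
    np.testing.assert_allclose(freqs, [220, 440, 660, 880, 1100], atol=3.0)


def test_constant_vector_has_no_peaks():
    assert len(detect_psd_peaks(np.full(1000, 0.1))) == 0


def test_peak_distance_rule_merges_close_spikes():
    """Two equal spikes 3 bins apart: the 5-bin separation rule keeps one.

    Oracle: exhaustive application of the distance rule to the local-maxima
    list (greedy, higher peaks first).
    """
    v = np.zeros(100)
    v[[50, 53]] = 0.5
    got = detect_psd_peaks(v)

    maxima = [i for i in range(1, 99) if v[i] > v[i - 1] and v[i] >= v[i + 1]
              and v[i] >= 0.04]
    keep = []
    for i in sorted(maxima, key=lambda i: -v[i]):
        if all(abs(i - j) >= 5 for j in keep):
            keep.append(i)
    assert len(got) == len(keep) == 1


def test_validate_accepts_reference_and_reports_score(reference_record):
    report = validate(reference_record)
    assert report.valid
    assert report.reasons == []
    assert 3.5 <= report.psd_score <= 12.0
    assert report.n_peaks == 5


def test_validate_rejects_white_noise_as_flat_spectrum(sim_config):
    rec = simulate_false_trigger(sim_config, np.random.default_rng(3),
                                 noise_sd=0.3)
    report = validate(rec)
    assert not report.valid
    assert "psd_score above maximum" in report.reasons
    assert report.psd_score > 12.0


def test_validate_rejects_single_peak_record():
    report = validate(pure_tone_record(250.0))
    assert not report.valid
    assert "too few peaks" in report.reasons


def test_validate_is_deterministic(reference_record):
    a = validate(reference_record)
    b = validate(reference_record)
    assert (a.psd_score, a.n_peaks, a.valid, a.reasons) == \
           (b.psd_score, b.n_peaks, b.valid, b.reasons)


def test_validate_rejects_wrong_length_and_zero_records():
    with pytest.raises(ValueError):
        validate(WingbeatRecord(samples=np.zeros(4000), fs=8000))
    report = validate(WingbeatRecord(samples=np.zeros(5000), fs=8000))
    assert not report.valid and report.reasons == ["zero signal"]


def test_crop_psd_db_emits_1360_values(reference_record):
    psd = welch_psd(bandpass(reference_record))
    cropped = crop_psd_db(psd)
    assert cropped.values.size == 1360
    assert 135.0 <= cropped.freq_low <= 140.0
    assert 1460.0 <= cropped.freq_high <= 1500.0


def test_crop_psd_db_scaling_shifts_by_20db():
    from wingbeatid import PSDFeature
    rng = np.random.default_rng(8)
    freqs = np.linspace(0, 4000, 4097)
    values = rng.random(4097) + 0.5  # well above the dB epsilon floor
    a = crop_psd_db(PSDFeature(freqs=freqs, values=values)).values
    b = crop_psd_db(PSDFeature(freqs=freqs, values=100 * values)).values
    np.testing.assert_allclose(b - a, 20.0, atol=1e-6)


def test_crop_psd_db_preserves_value_order(reference_record):
    psd = welch_psd(bandpass(reference_record))
    cropped = crop_psd_db(psd)
    raw = psd.values[140:1500]
    assert np.array_equal(np.argsort(cropped.values), np.argsort(raw))


def test_spectrogram_shape_is_295_by_400(reference_record):
    spec = spectrogram(reference_record)
    assert spec.values.shape == (295, 400)


def test_spectrogram_of_silence_is_constant_floor():
    spec = spectrogram(WingbeatRecord(samples=np.zeros(5000), fs=8000))
    assert np.ptp(spec.values) < 1e-6


def test_spectrogram_tone_row_consistent_across_columns():
    """A 400 Hz tone keeps the max-energy row fixed over >= 95% of columns,
    matching the per-column argmax of a directly computed short-time FFT."""
    spec = spectrogram(pure_tone_record(400.0))
    rows = spec.values.argmax(axis=0)
    dominant = np.bincount(rows).argmax()
    assert np.mean(rows == dominant) >= 0.95

    w = sps.get_window("hann", 600)
    _, _, sxx = sps.spectrogram(pure_tone_record(400.0).samples, fs=8000,
                                window=w, nperseg=600, noverlap=595,
                                nfft=8192, detrend=False, mode="psd")
    direct_rows = sxx[140:1500].argmax(axis=0)
    scale = 295 / 1360
    assert abs(np.median(direct_rows) * scale - dominant) <= 2


def test_spectrogram_rejects_wrong_length():
    with pytest.raises(ValueError):
        spectrogram(WingbeatRecord(samples=np.zeros(4096), fs=8000))
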