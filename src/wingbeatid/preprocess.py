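"""Signal cleaning and featurization for wingbeat records.

The cleaning chain is: 140–1500 Hz band-pass (4th-order Butterworth applied
forward-backward, so zero phase), Welch power spectral density with a Hann
window (FFT size 8,192, segment length 5,000, overlap 2,500 — a single
segment for standard 5,000-sample records), then two validity statistics on
the L2-normalized PSD:

* the PSD-score, the plain sum of the unit-norm PSD vector — close to 1 for
  a spectrally concentrated signal, close to sqrt(N) for flat noise;
* the number of spectral peaks (``scipy.signal.find_peaks`` with prominence
  0.001, height 0.04, width 1, distance 5).

A record is valid when the score lies in [3.5, 12] and the peak count in
[2, 14]. A clean wingbeat ideally shows five peaks: the fundamental plus
four overtones.

Model inputs are the band-passed waveform, the dB-scaled PSD cropped to the
pass band (1,360 values), and a dB spectrogram resized to 295 × 400.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage.transform import resize as _resize

from .sensor_sim import WingbeatRecord


@dataclass(frozen=True)
class CleaningConfig:
    band_low: float = 140.0
    band_high: float = 1500.0
    psd_score_min: float = 3.5
    psd_score_max: float = 12.0
    peaks_min: int = 2
    peaks_max: int = 14
    peak_prominence: float = 0.001
    peak_height: float = 0.04
    peak_width: float = 1.0
    peak_distance: int = 5
    fft_size: int = 8192
    segment_len: int = 5000
    segment_overlap: int = 2500
    filter_order: int = 4
    spec_window_len: int = 600
    spec_hop: int = 5
    spec_shape: tuple[int, int] = (295, 400)
    db_eps: float = 1e-12

    def __post_init__(self):
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be below band_high")
        if not self.psd_score_min < self.psd_score_max:
            raise ValueError("psd_score_min must be below psd_score_max")
        if self.peaks_min > self.peaks_max:
            raise ValueError("peaks_min must not exceed peaks_max")


@dataclass
class PSDFeature:
    """Welch power spectral density: fft_size/2 + 1 bins over [0, fs/2]."""
    freqs: np.ndarray
    values: np.ndarray


@dataclass
class ValidityReport:
    record_id: str
    psd_score: float
    n_peaks: int
    valid: bool
    reasons: list[str]


@dataclass
class CroppedPSD:
    """dB-scaled PSD restricted to the pass band: exactly 1,360 values."""
    values: np.ndarray
    freq_low: float
    freq_high: float


@dataclass
class SpectrogramFeature:
    """dB time-frequency image, frequency rows × time columns (295 × 400)."""
    values: np.ndarray


def bandpass(record: WingbeatRecord, config: CleaningConfig | None = None
             ) -> WingbeatRecord:
    """Zero-phase Butterworth band-pass; length and envelope timing preserved."""
    config = config or CleaningConfig()
    if record.fs <= 2 * config.band_high:
        raise ValueError(
            f"sampling rate {record.fs} Hz too low for a {config.band_high} Hz "
            "high cutoff")
    sos = sps.butter(config.filter_order, [config.band_low, config.band_high],
                     btype="bandpass", fs=record.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, record.samples)
    return replace_samples(record, filtered)


def replace_samples(record: WingbeatRecord, samples: np.ndarray) -> WingbeatRecord:
    return WingbeatRecord(samples=samples, fs=record.fs, species=record.species,
                          population=record.population, record_id=record.record_id,
                          timestamp=record.timestamp, true_f0=record.true_f0)


def welch_psd(record: WingbeatRecord, config: CleaningConfig | None = None
              ) -> PSDFeature:
    """Hann-window Welch PSD, zero-padded to the configured FFT size.

    For the standard 5,000-sample record there is exactly one segment, which
    makes this identical to a single Hann-windowed zero-padded periodogram
    (the overlap setting is inert). No detrending is applied.
    """
    config = config or CleaningConfig()
    if record.samples.size < config.segment_len:
        raise ValueError(
            f"record length {record.samples.size} below segment length "
            f"{config.segment_len}")
    freqs, values = sps.welch(record.samples, fs=record.fs, window="hann",
                              nperseg=config.segment_len,
                              noverlap=config.segment_overlap,
                              nfft=config.fft_size, detrend=False)
    return PSDFeature(freqs=freqs, values=values)


def l2_normalize(values: np.ndarray) -> np.ndarray:
    """Scale a PSD vector to unit Euclidean norm."""
    values = np.asarray(values, dtype=np.float64)
    norm = np.linalg.norm(values)
    if norm == 0:
        raise ValueError("cannot normalize an all-zero PSD (empty record?)")
    return values / norm


def psd_score(psd: PSDFeature | np.ndarray) -> float:
    """Sum of the L2-normalized PSD: in [1, sqrt(N)] for any nonzero PSD."""
    values = psd.values if isinstance(psd, PSDFeature) else psd
    return float(np.sum(l2_normalize(values)))


def detect_psd_peaks(normalized_psd: np.ndarray,
                     config: CleaningConfig | None = None) -> np.ndarray:
    """Peak indices of the unit-norm PSD under the validity-filter settings.

    The height threshold (0.04) only has meaning on a unit-norm vector, so
    callers must pass the L2-normalized PSD.
    """
    config = config or CleaningConfig()
    peaks, _ = sps.find_peaks(normalized_psd,
                              prominence=config.peak_prominence,
                              height=config.peak_height,
                              width=config.peak_width,
                              distance=config.peak_distance)
    return peaks


def validate(record: WingbeatRecord, config: CleaningConfig | None = None
             ) -> ValidityReport:
    """Full validity check: bandpass → Welch → normalize → score + peaks.

    The verdict is valid iff score in [psd_score_min, psd_score_max]
    (inclusive) and peak count in [peaks_min, peaks_max]; ``reasons`` lists
    every violated rule.
    """
    config = config or CleaningConfig()
    if record.samples.size != config.segment_len:
        raise ValueError(
            f"expected a {config.segment_len}-sample record, got "
            f"{record.samples.size}")
    filtered = bandpass(record, config)
    psd = welch_psd(filtered, config)
    reasons: list[str] = []
    if not np.any(psd.values):
        return ValidityReport(record_id=record.record_id, psd_score=float("nan"),
                              n_peaks=0, valid=False, reasons=["zero signal"])
    normalized = l2_normalize(psd.values)
    score = float(np.sum(normalized))
    n_peaks = len(detect_psd_peaks(normalized, config))
    if score < config.psd_score_min:
        reasons.append("psd_score below minimum")
    if score > config.psd_score_max:
        reasons.append("psd_score above maximum")
    if n_peaks < config.peaks_min:
        reasons.append("too few peaks")
    if n_peaks > config.peaks_max:
        reasons.append("too many peaks")
    return ValidityReport(record_id=record.record_id, psd_score=score,
                          n_peaks=n_peaks, valid=not reasons, reasons=reasons)


def crop_psd_db(psd: PSDFeature, config: CleaningConfig | None = None
                ) -> CroppedPSD:
    """dB-scale the PSD and keep the pass-band slice: exactly 1,360 values.

    At 8 kHz with an 8,192-point FFT the bin spacing is ~0.977 Hz, so the
    cropper adopts the bin-index slice 140..1499 (a one-bin-per-hertz
    convention spanning ≈137–1464 Hz) to emit the canonical 1,360-dim
    feature for the 140–1500 Hz band.
    """
    config = config or CleaningConfig()
    n_bins = config.fft_size // 2 + 1
    if psd.values.size != n_bins:
        raise ValueError(f"expected a {n_bins}-bin PSD, got {psd.values.size}")
    lo, hi = int(config.band_low), int(config.band_high)
    values = 10.0 * np.log10(psd.values[lo:hi] + config.db_eps)
    return CroppedPSD(values=values, freq_low=float(psd.freqs[lo]),
                      freq_high=float(psd.freqs[hi - 1]))


def spectrogram(record: WingbeatRecord, config: CleaningConfig | None = None
                ) -> SpectrogramFeature:
    """dB spectrogram (window 600, hop 5, FFT 8,192) resized to 295 × 400.

    The frequency axis is cropped to the pass band with the same bin-index
    convention as :func:`crop_psd_db`, then the image is downscaled with
    bilinear interpolation. Rows are frequency (low to high), columns time.
    """
    config = config or CleaningConfig()
    if record.samples.size != config.segment_len:
        raise ValueError(
            f"expected a {config.segment_len}-sample record, got "
            f"{record.samples.size}")
    win = sps.get_window("hann", config.spec_window_len)
    _, _, sxx = sps.spectrogram(record.samples, fs=record.fs, window=win,
                                nperseg=config.spec_window_len,
                                noverlap=config.spec_window_len - config.spec_hop,
                                nfft=config.fft_size, detrend=False, mode="psd")
    lo, hi = int(config.band_low), int(config.band_high)
    db = 10.0 * np.log10(sxx[lo:hi, :] + config.db_eps)
    out = _resize(db, config.spec_shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    return SpectrogramFeature(values=out)


# ---------------------------------------------------------------------------
# Model-input featurization
# ---------------------------------------------------------------------------

def featurize_waveform(record: WingbeatRecord,
                       config: CleaningConfig | None = None,
                       standardize: bool = True) -> np.ndarray:
    """Band-passed waveform as a model input (5,000 values).

    Per-record standardization (zero mean, unit variance) removes the
    arbitrary light-intensity scale, which carries no species information.
    """
    filtered = bandpass(record, config)
    x = filtered.samples
    if standardize:
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
    return x


def featurize_psd(record: WingbeatRecord,
                  config: CleaningConfig | None = None,
                  standardize: bool = True) -> np.ndarray:
    """Cropped dB PSD of the band-passed record (1,360 values)."""
    config = config or CleaningConfig()
    cropped = crop_psd_db(welch_psd(bandpass(record, config), config), config)
    x = cropped.values
    if standardize:
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
    return x


def featurize_spectrogram(record: WingbeatRecord,
                          config: CleaningConfig | None = None,
                          standardize: bool = True) -> np.ndarray:
    """dB spectrogram image of the band-passed record (295 × 400)."""
    config = config or CleaningConfig()
    spec = spectrogram(bandpass(record, config), config)
    x = spec.values
    if standardize:
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
    return x
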