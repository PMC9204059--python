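"""Inspect the three model-input representations of one clean record.

Uses the deterministic reference record (fundamental 220 Hz plus four
overtones) and prints the geometry and peak structure the models consume.
"""

from wingbeatid import (bandpass, crop_psd_db, detect_psd_peaks, l2_normalize,
                        psd_score, reference_clean_record, spectrogram,
                        welch_psd)

record = reference_clean_record()
print(f"record: {record.samples.size} samples at {record.fs} Hz "
      f"({record.samples.size / record.fs:.3f} s), f0 = {record.true_f0} Hz")

filtered = bandpass(record)
psd = welch_psd(filtered)
normalized = l2_normalize(psd.values)
peaks = detect_psd_peaks(normalized)
print(f"Welch PSD: {psd.values.size} bins, PSD-score {psd_score(psd):.2f}")
print("peaks at", ", ".join(f"{psd.freqs[p]:.0f} Hz" for p in peaks),
      "- the fundamental and its four overtones")

cropped = crop_psd_db(psd)
print(f"cropped dB PSD: {cropped.values.size} values spanning "
      f"{cropped.freq_low:.0f}-{cropped.freq_high:.0f} Hz")

spec = spectrogram(record)
print(f"spectrogram: {spec.values.shape[0]} frequency rows x "
      f"{spec.values.shape[1]} time columns (dB)")
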