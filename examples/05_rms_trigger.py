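"""Emulate the sensor's RMS event trigger on a continuous stream.

Builds a 10-second silent stream with two embedded wingbeat transits and
scans it with a windowed RMS threshold, as the sensor's microelectronics
do: each detection claims one fixed 5,000-sample record.
"""

import numpy as np

from wingbeatid import SimConfig, default_profiles, rms_trigger, simulate_wingbeat

fs = 8000
rng = np.random.default_rng(1)
stream = rng.normal(0, 0.01, 10 * fs)  # sensor noise floor

config = SimConfig()
for start_s in (2.0, 6.5):
    rec = simulate_wingbeat(default_profiles()[0], config, rng)
    i = int(start_s * fs)
    stream[i:i + rec.samples.size] += rec.samples

events = rms_trigger(stream, fs=fs, window_len=256, threshold=0.05)
print(f"stream: {stream.size / fs:.1f} s, {len(events)} events detected")
for start, segment in events:
    print(f"  event at t = {start / fs:.3f} s, {segment.size} samples, "
          f"RMS {np.sqrt(np.mean(segment ** 2)):.3f}")
# Each event is exactly one record length (0.625 s); detections cannot
# overlap because scanning resumes after the claimed segment.
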