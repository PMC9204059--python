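"""Simulate a small wingbeat dataset and run the validity filter.

Generates 2 species x 2 populations x 50 records plus 10% noise-only
false triggers, then applies the PSD-score validity filter. The printed
rates show the filter separating clean wingbeats from false triggers.
"""

import numpy as np

from wingbeatid import SimConfig, default_profiles, simulate_dataset, validate

config = SimConfig(n_records=50, false_trigger_fraction=0.1, rng_seed=42)
records, manifest = simulate_dataset(config, default_profiles())
print(f"simulated {len(records)} records "
      f"({(manifest['species'] != 'unknown').sum()} wingbeats, "
      f"{(manifest['species'] == 'unknown').sum()} false triggers)")

reports = {rec.record_id: validate(rec) for rec in records}
for kind, ids in [("wingbeat", manifest.loc[manifest.species != 'unknown',
                                            'record_id']),
                  ("false trigger", manifest.loc[manifest.species == 'unknown',
                                                 'record_id'])]:
    subset = [reports[rid] for rid in ids]
    rate = np.mean([r.valid for r in subset])
    scores = [r.psd_score for r in subset]
    print(f"{kind:>14}: {100 * rate:5.1f}% valid, PSD-score "
          f"{min(scores):.2f}-{max(scores):.2f} (validity window 3.5-12)")

# A spectrally concentrated wingbeat has a low PSD-score; flat white noise
# scores near sqrt(4097) ~ 64 and is rejected together with peak-count
# violations.
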