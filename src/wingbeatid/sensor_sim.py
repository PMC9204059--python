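"""Synthetic wingbeat-sensor signals for *Drosophila* species discrimination.

An optical wingbeat sensor records the light-intensity trace produced while
an insect flies through a light beam: the wings superimpose a quasi-periodic
occlusion pattern (fundamental wing-stroke frequency plus overtones) on a
slow body-occlusion baseline, enveloped by the transit through the beam.
Real recordings of this kind are 5,000 samples long at 8 kHz (0.625 s).

This module generates records with that statistical structure:

* per-species fundamental-frequency (f0) distributions, truncated normal and
  deliberately overlapping between species;
* species-specific overtone amplitude profiles (the wing-morphology cue that
  makes the classes separable even where the f0 histograms overlap);
* a Hann-shaped transit envelope with randomized onset/offset, slow
  frequency modulation of the wing stroke, a sub-140 Hz body-occlusion
  baseline, and additive white sensor noise;
* noise-only "false trigger" records, which the validity filter is meant to
  reject;
* an RMS event trigger emulating the sensor's microelectronics.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SpeciesProfile:
    """Statistical description of one species' wingbeat signals.

    Parameters
    ----------
    name
        Species tag, conventionally ``"DM"`` or ``"SWD"``.
    f0_mean, f0_sd
        Mean and standard deviation (Hz) of the fundamental wingbeat
        frequency distribution.
    f0_bounds
        Truncation interval for f0 in Hz; the upper bound must stay below
        300 Hz (fruit-fly wing strokes live below that).
    harmonic_amps
        Relative amplitude of each overtone, ``a_1 = 1`` being the
        fundamental. The overtone balance is a wing-morphology signature
        and is what distinguishes species with overlapping f0.
    envelope_family
        ``(lo, hi)`` range the random onset/offset fractions of the transit
        envelope are drawn from.
    baseline_amp
        Amplitude of the slow (< 140 Hz) body-occlusion component.
    noise_sd
        Standard deviation of additive white sensor noise, in the same
        (arbitrary) light-intensity units as a unit-amplitude fundamental.
    fm_depth
        Relative depth of the slow frequency modulation of the wing stroke
        (insects do not beat their wings at a perfectly constant rate);
        broadens the spectral lines the way real recordings are broadened.
    """

    name: str
    f0_mean: float
    f0_sd: float
    f0_bounds: tuple[float, float] = (140.0, 299.0)
    harmonic_amps: tuple[float, ...] = (1.0, 0.7, 0.55, 0.45, 0.35)
    envelope_family: tuple[float, float] = (0.15, 0.45)
    baseline_amp: float = 0.5
    noise_sd: float = 0.03
    fm_depth: float = 0.012

    def __post_init__(self):
        if not self.f0_bounds[1] < 300.0:
            raise ValueError("f0 upper bound must be < 300 Hz")
        if not self.f0_bounds[0] < self.f0_bounds[1]:
            raise ValueError("f0_bounds must be an increasing interval")
        if self.f0_sd <= 0:
            raise ValueError("f0_sd must be positive")
        if len(self.harmonic_amps) < 1:
            raise ValueError("at least one harmonic amplitude is required")
        if self.harmonic_amps[0] not in (0.0, 1.0) or (
                self.harmonic_amps[0] == 0.0 and any(self.harmonic_amps)):
            # a_1 = 1 is the reference; the all-zero profile is the one
            # permitted degenerate case (a silent record).
            raise ValueError("the fundamental amplitude a_1 must be 1 (reference)")
        if any(a < 0 for a in self.harmonic_amps):
            raise ValueError("harmonic amplitudes must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Simulation run configuration.

    ``populations`` maps a population suffix to an f0 mean shift in Hz that
    is applied to every species (population ids become ``"<species>_<key>"``);
    distinct populations of one species differ slightly in mean wingbeat
    frequency, which is what makes population-wise splits meaningful.
    """

    fs: int = 8000
    duration_s: float = 0.625
    n_records: int = 100
    populations: dict[str, float] = field(
        default_factory=lambda: {"A": 5.0, "B": -5.0})
    false_trigger_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        n = self.fs * self.duration_s
        if self.fs <= 0 or self.duration_s <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration_s must be a positive integer")
        if not 0 <= self.false_trigger_fraction < 1:
            raise ValueError("false_trigger_fraction must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class WingbeatRecord:
    """One triggered sensor event: a fixed-length light-intensity series."""

    samples: np.ndarray
    fs: int
    species: str = "unknown"
    population: str = ""
    record_id: str = ""
    timestamp: str = ""
    true_f0: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


def default_profiles() -> list[SpeciesProfile]:
    """The two default species profiles the study conditions use.

    The f0 distributions overlap substantially (means 20 Hz apart at 18 Hz
    spread) so the frequency histograms of the two species look alike; the
    overtone balance differs (DM overtone energy decays monotonically, SWD
    puts relatively more energy into the odd overtones), which is the cue a
    waveform classifier can exploit.
    """
    return [
        SpeciesProfile(name="DM", f0_mean=210.0, f0_sd=18.0,
                       harmonic_amps=(1.0, 0.72, 0.50, 0.38, 0.28)),
        SpeciesProfile(name="SWD", f0_mean=190.0, f0_sd=18.0,
                       harmonic_amps=(1.0, 0.45, 0.62, 0.30, 0.42)),
    ]


def _transit_envelope(n: int, onset_frac: float, offset_frac: float) -> np.ndarray:
    env = np.ones(n)
    n_on = int(round(onset_frac * n))
    n_off = int(round(offset_frac * n))
    if n_on > 0:
        env[:n_on] = 0.5 * (1 - np.cos(np.pi * np.arange(n_on) / n_on))
    if n_off > 0:
        env[n - n_off:] = 0.5 * (1 - np.cos(np.pi * np.arange(n_off)[::-1] / n_off))
    return env


def simulate_wingbeat(profile: SpeciesProfile, config: SimConfig,
                      rng: np.random.Generator, f0_shift: float = 0.0,
                      f0: float | None = None) -> WingbeatRecord:
    """Draw one synthetic wingbeat record.

    The signal model is ``envelope(t) * sum_k a_k sin(k*phase(t) + phi_k)
    + baseline(t) + noise``, with f0 drawn from the profile's truncated
    normal (optionally shifted per population, or forced via ``f0``), random
    uniform phases per overtone, slow sinusoidal frequency modulation of the
    stroke rate, and a transit-shaped sub-140 Hz baseline.
    """
    n = config.n_samples
    fs = config.fs
    lo, hi = profile.f0_bounds
    if f0 is None:
        mean = profile.f0_mean + f0_shift
        a, b = (lo - mean) / profile.f0_sd, (hi - mean) / profile.f0_sd
        f0 = float(stats.truncnorm.rvs(a, b, loc=mean, scale=profile.f0_sd,
                                       random_state=rng))
    t = np.arange(n) / fs

    onset = rng.uniform(*profile.envelope_family)
    offset = rng.uniform(*profile.envelope_family)
    env = _transit_envelope(n, onset, offset)

    # Slow two-tone FM of the stroke rate; modulation index stays below ~0.9
    # so the fundamental's spectral peak remains on the carrier bin.
    fm1 = rng.uniform(2.5, 4.0)
    fm2 = rng.uniform(5.0, 9.0)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    f_inst = f0 * (1.0 + profile.fm_depth * (0.6 * np.sin(2 * np.pi * fm1 * t + ph1)
                                             + 0.4 * np.sin(2 * np.pi * fm2 * t + ph2)))
    phase = 2 * np.pi * np.cumsum(f_inst) / fs

    harmonic_phases = rng.uniform(0, 2 * np.pi, size=len(profile.harmonic_amps))
    wave = np.zeros(n)
    for k, (a_k, phi_k) in enumerate(zip(profile.harmonic_amps, harmonic_phases), start=1):
        if a_k > 0:
            wave += a_k * np.sin(k * phase + phi_k)

    scale = rng.uniform(0.6, 1.4)  # transit depth varies per flight
    samples = scale * (env * wave + profile.baseline_amp * env)
    if profile.noise_sd > 0:
        samples = samples + rng.normal(0.0, profile.noise_sd, size=n)

    return WingbeatRecord(samples=samples, fs=fs, species=profile.name,
                          true_f0=f0)


def simulate_false_trigger(config: SimConfig, rng: np.random.Generator,
                           noise_sd: float | None = None) -> WingbeatRecord:
    """A noise-only record, as produced when the sensor triggers spuriously."""
    n = config.n_samples
    if noise_sd is None:
        noise_sd = rng.uniform(0.05, 0.5)
    samples = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    return WingbeatRecord(samples=samples, fs=config.fs, species="unknown")


def reference_clean_record(config: SimConfig | None = None) -> WingbeatRecord:
    """The deterministic reference clean fixture.

    f0 = 220 Hz with five overtone amplitudes (1, 0.7, 0.55, 0.45, 0.35),
    no sensor noise and no baseline: its normalized power spectrum carries
    exactly five peaks (fundamental + four overtones), all clearing the
    0.04 height threshold of the validity filter.
    """
    config = config or SimConfig()
    profile = SpeciesProfile(name="reference", f0_mean=220.0, f0_sd=1.0,
                             harmonic_amps=(1.0, 0.7, 0.55, 0.45, 0.35),
                             envelope_family=(0.5, 0.5), baseline_amp=0.0,
                             noise_sd=0.0, fm_depth=0.004)
    rng = np.random.default_rng(20220603)
    return simulate_wingbeat(profile, config, rng, f0=220.0)


def rms_trigger(stream: np.ndarray, fs: int, window_len: int,
                threshold: float, event_len: int = 5000
                ) -> list[tuple[int, np.ndarray]]:
    """Emulate the sensor's RMS event trigger on a continuous stream.

    The windowed RMS is scanned left to right; an event starts at the first
    index whose window RMS reaches ``threshold`` and claims the next
    ``event_len`` samples (zero-padded past the stream end). Scanning
    resumes after the event, so events never overlap.
    """
    stream = np.asarray(stream, dtype=np.float64)
    if stream.size == 0:
        raise ValueError("empty stream")
    if stream.size < event_len:
        raise ValueError(f"stream shorter than one event ({event_len} samples)")
    if window_len < 1:
        raise ValueError("window_len must be >= 1")

    sq = np.concatenate([[0.0], np.cumsum(stream ** 2)])
    n_windows = stream.size - window_len + 1
    rms = np.sqrt((sq[window_len:window_len + n_windows] - sq[:n_windows]) / window_len)

    events: list[tuple[int, np.ndarray]] = []
    i = 0
    while i < n_windows:
        hits = np.flatnonzero(rms[i:] >= threshold)
        if hits.size == 0:
            break
        start = i + int(hits[0])
        segment = stream[start:start + event_len]
        if segment.size < event_len:
            segment = np.pad(segment, (0, event_len - segment.size))
        events.append((start, segment))
        i = start + event_len
    return events


def simulate_dataset(config: SimConfig,
                     profiles: list[SpeciesProfile] | None = None
                     ) -> tuple[list[WingbeatRecord], pd.DataFrame]:
    """Generate a labeled multi-population dataset plus its manifest.

    ``config.n_records`` records are drawn per (species, population), each
    population's f0 mean shifted per ``config.populations``; noise-only
    false triggers are appended so that they make up
    ``config.false_trigger_fraction`` of the final dataset. Fully
    reproducible from ``config.rng_seed``.
    """
    profiles = profiles if profiles is not None else default_profiles()
    rng = np.random.default_rng(config.rng_seed)
    records: list[WingbeatRecord] = []

    base_ts = pd.Timestamp("2021-06-01T00:00:00")
    idx = 0
    for profile in profiles:
        for pop_key, shift in config.populations.items():
            population = f"{profile.name}_{pop_key}"
            for i in range(config.n_records):
                rec = simulate_wingbeat(profile, config, rng, f0_shift=shift)
                rec.population = population
                rec.record_id = f"{population}_{i:05d}"
                rec.timestamp = (base_ts + pd.Timedelta(minutes=idx)).isoformat()
                records.append(rec)
                idx += 1

    n_signal = len(records)
    frac = config.false_trigger_fraction
    n_false = int(round(frac * n_signal / (1.0 - frac))) if frac > 0 else 0
    for i in range(n_false):
        rec = simulate_false_trigger(config, rng)
        rec.population = "noise"
        rec.record_id = f"FT_{i:05d}"
        rec.timestamp = (base_ts + pd.Timedelta(minutes=idx)).isoformat()
        records.append(rec)
        idx += 1

    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in simulated dataset")

    manifest = pd.DataFrame({
        "record_id": ids,
        "path": ["" for _ in records],
        "species": [r.species for r in records],
        "population": [r.population for r in records],
        "timestamp": [r.timestamp for r in records],
        "true_f0": [r.true_f0 if r.true_f0 is not None else np.nan for r in records],
    })
    return records, manifest
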