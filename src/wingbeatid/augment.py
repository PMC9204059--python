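"""Stochastic waveform augmentations for training.

Three operations, each applied independently with 50% probability during
training (never at evaluation time): a circular time shift ("random roll"),
time reversal ("random flip"), and Gaussian noise confined to one random
segment of the signal ("random noise", a form of time masking). Roll and
flip conserve signal energy exactly; noise adds energy only inside its
segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AugmentConfig:
    roll_min: int = 500
    roll_max: int = 4500
    apply_prob: float = 0.5
    noise_sd_rel: float = 0.5
    noise_seg_frac_range: tuple[float, float] = (0.1, 0.3)

    def __post_init__(self):
        if not 0 < self.roll_min <= self.roll_max:
            raise ValueError("need 0 < roll_min <= roll_max")
        if not 0 <= self.apply_prob <= 1:
            raise ValueError("apply_prob must be in [0, 1]")


def roll(x: np.ndarray, shift: int) -> np.ndarray:
    """Circular shift: positive = forwards in time, samples wrap around."""
    return np.roll(x, shift)


def random_roll(x: np.ndarray, rng: np.random.Generator,
                config: AugmentConfig | None = None) -> np.ndarray:
    """Circular shift by a random amount in [roll_min, roll_max], either way."""
    config = config or AugmentConfig()
    if config.roll_max >= x.size:
        raise ValueError("roll_max must be smaller than the signal length")
    shift = int(rng.integers(config.roll_min, config.roll_max + 1))
    direction = 1 if rng.random() < 0.5 else -1
    return roll(x, direction * shift)


def random_flip(x: np.ndarray) -> np.ndarray:
    """Mirror the signal in time: output[i] = x[len-1-i]."""
    return x[::-1].copy()


def random_noise(x: np.ndarray, rng: np.random.Generator,
                 config: AugmentConfig | None = None) -> np.ndarray:
    """Add zero-mean Gaussian noise on one random contiguous segment.

    The noise standard deviation is ``noise_sd_rel`` times the signal's own
    standard deviation; samples outside the segment are untouched.
    """
    config = config or AugmentConfig()
    out = x.astype(np.float64, copy=True)
    if config.noise_sd_rel == 0:
        return out
    frac = rng.uniform(*config.noise_seg_frac_range)
    seg_len = max(1, int(round(frac * x.size)))
    start = int(rng.integers(0, x.size - seg_len + 1))
    sd = config.noise_sd_rel * float(np.std(x))
    if sd > 0:
        out[start:start + seg_len] += rng.normal(0.0, sd, size=seg_len)
    return out


def augment_pipeline(x: np.ndarray, rng: np.random.Generator,
                     config: AugmentConfig | None = None,
                     return_applied: bool = False):
    """Apply roll, flip and noise in that fixed order, each with apply_prob.

    With ``return_applied`` the tuple of op names actually applied is
    returned alongside the waveform (useful for auditing application rates).
    """
    config = config or AugmentConfig()
    out = np.asarray(x, dtype=np.float64)
    applied: list[str] = []
    if rng.random() < config.apply_prob:
        out = random_roll(out, rng, config)
        applied.append("roll")
    if rng.random() < config.apply_prob:
        out = random_flip(out)
        applied.append("flip")
    if rng.random() < config.apply_prob:
        out = random_noise(out, rng, config)
        applied.append("noise")
    if return_applied:
        return out, tuple(applied)
    return out
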