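"""Seeded generator of labeled synthetic PPG segments.

Clean segments are built as a train of two Gaussian bumps per cardiac
period: the systolic peak (relative amplitude 1.0) followed by the smaller
dicrotic bump (amplitude 0.3, centred at 55% of the period), which
reproduces the characteristic double-hump PPG pulse without a hemodynamic
model.  Per-beat periods are jittered by +/-3% so the waveform is
quasi-periodic rather than exactly periodic.

Corruption emulates the failure modes of wearable PPG acquisition:
additive white noise (sensor/electronic noise), a low-frequency sinusoidal
baseline wander (respiration, probe pressure drift), Poisson-placed motion
spikes, and amplitude saturation (clipping).  The artifact strengths used
for each quality class are fixed in :data:`CLASS_ARTIFACTS`; class 1 (good)
is near-clean, class 2 (fair) adds moderate noise and wander, class 3
(poor) adds strong noise, wander, spikes and clipping.  These synthetic
class boundaries are a free design choice and are not equivalent to the
manual labels of any real device dataset.

Every generator output is a pure function of its arguments including the
seed; a dataset-level seed expands into per-signal seeds via a counter so
that generation order does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import LabeledDataset, Signal

__all__ = [
    "ArtifactConfig",
    "CLASS_ARTIFACTS",
    "generate_clean_ppg",
    "corrupt_ppg",
    "generate_dataset",
]

# pulse morphology (fractions of the cardiac period)
_SYSTOLIC_AMP = 1.0
_SYSTOLIC_POS = 0.25
_SYSTOLIC_WIDTH = 0.09
_DICROTIC_AMP = 0.3
_DICROTIC_POS = 0.55
_DICROTIC_WIDTH = 0.14
_PERIOD_JITTER = 0.03  # +/-3% uniform per beat

_SPIKE_TAU_S = 0.02  # exponential decay time of a motion spike


@dataclass(frozen=True)
class ArtifactConfig:
    """Strengths of the four corruption modes.

    Amplitude-like fields (``noise_sd``, ``wander_amp``, ``spike_amp``) are
    relative to the clean signal's peak-to-peak range.  ``spike_rate`` is the
    expected number of motion spikes per second (Poisson).  ``clip_fraction``
    is the fraction of the corrupted signal's dynamic range kept before
    saturation; 1 means no clipping.
    """

    noise_sd: float = 0.0
    wander_amp: float = 0.0
    wander_freq: float = 0.25
    spike_rate: float = 0.0
    spike_amp: float = 0.0
    clip_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "wander_amp", "wander_freq", "spike_rate", "spike_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not 0.0 < self.clip_fraction <= 1.0:
            raise ValueError(f"clip_fraction must be in (0, 1], got {self.clip_fraction}")


#: per-class artifact strengths: 1 = good, 2 = fair, 3 = poor
CLASS_ARTIFACTS: dict[int, ArtifactConfig] = {
    1: ArtifactConfig(noise_sd=0.02),
    2: ArtifactConfig(noise_sd=0.15, wander_amp=0.35, wander_freq=0.3),
    3: ArtifactConfig(
        noise_sd=0.4,
        wander_amp=0.6,
        wander_freq=0.3,
        spike_rate=1.5,
        spike_amp=1.5,
        clip_fraction=0.8,
    ),
}


def generate_clean_ppg(
    duration_s: float,
    fs: float,
    heart_rate_bpm: float,
    seed: int,
) -> Signal:
    """Generate one clean quasi-periodic PPG segment.

    Parameters
    ----------
    duration_s : float
        Segment duration in seconds (> 0); the output has
        ``round(duration_s * fs)`` samples.
    fs : float
        Sampling rate in Hz (> 0).
    heart_rate_bpm : float
        Mean heart rate, 30-220 beats per minute.
    seed : int
        Seed for the per-beat period jitter and the starting phase.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if not 30 <= heart_rate_bpm <= 220:
        raise ValueError(f"heart_rate_bpm must be in [30, 220], got {heart_rate_bpm}")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    period = 60.0 / heart_rate_bpm

    samples = np.zeros(n)
    # start one beat early so the segment opens mid-pulse rather than flat
    onset = -period * rng.uniform(0.0, 1.0)
    while onset < duration_s:
        beat_period = period * (1.0 + rng.uniform(-_PERIOD_JITTER, _PERIOD_JITTER))
        for amp, pos, width in (
            (_SYSTOLIC_AMP, _SYSTOLIC_POS, _SYSTOLIC_WIDTH),
            (_DICROTIC_AMP, _DICROTIC_POS, _DICROTIC_WIDTH),
        ):
            centre = onset + pos * beat_period
            sigma = width * beat_period
            samples += amp * np.exp(-0.5 * ((t - centre) / sigma) ** 2)
        onset += beat_period

    return Signal(samples=samples, fs=fs)


def corrupt_ppg(signal: Signal, cfg: ArtifactConfig, seed: int) -> Signal:
    """Apply the four corruption modes to a signal, deterministically per seed.

    Order: white noise, baseline wander, motion spikes, then clipping at
    ``clip_fraction`` of the corrupted signal's own dynamic range (so a
    clip_fraction of 1 leaves the signal untouched).
    """
    if len(signal) == 0:
        raise ValueError("cannot corrupt an empty signal")

    rng = np.random.default_rng(seed)
    x = signal.samples.copy()
    t = signal.times
    scale = float(np.ptp(x)) or 1.0

    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd * scale, size=x.shape)

    if cfg.wander_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x = x + cfg.wander_amp * scale * np.sin(2.0 * np.pi * cfg.wander_freq * t + phase)

    if cfg.spike_rate > 0:
        n_spikes = rng.poisson(cfg.spike_rate * signal.duration)
        for _ in range(n_spikes):
            t0 = rng.uniform(0.0, signal.duration)
            sign = rng.choice((-1.0, 1.0))
            x = x + sign * cfg.spike_amp * scale * np.exp(-np.abs(t - t0) / _SPIKE_TAU_S)

    if cfg.clip_fraction < 1.0:
        lo, hi = float(x.min()), float(x.max())
        mid = 0.5 * (lo + hi)
        half = 0.5 * cfg.clip_fraction * (hi - lo)
        x = np.clip(x, mid - half, mid + half)

    return signal.with_samples(x)


def _child_seed(seed: int, index: int) -> int:
    """Expand a dataset seed into a per-signal seed (stable under reordering)."""
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2**31))


def generate_dataset(
    n_good: int,
    n_fair: int,
    n_poor: int,
    fs: float = 512.0,
    seed: int = 0,
    duration_s: float = 5.0,
    heart_rate_range: tuple[float, float] = (50.0, 110.0),
) -> LabeledDataset:
    """Generate a labeled dataset of 5-second segments in the three classes.

    Heart rates are drawn uniformly per signal from ``heart_rate_range``.
    The 3-class labels are carried on the signals; the merged binary labels
    (1 = good, 0 = fair/poor) are exposed by the returned dataset.
    """
    counts = {1: n_good, 2: n_fair, 3: n_poor}
    for cls, n in counts.items():
        if n < 0:
            raise ValueError(f"count for class {cls} must be >= 0, got {n}")
    if n_good + n_fair + n_poor == 0:
        raise ValueError("at least one class count must be positive")

    signals: list[Signal] = []
    index = 0
    for cls, n in counts.items():
        cfg = CLASS_ARTIFACTS[cls]
        for _ in range(n):
            s_clean = _child_seed(seed, 2 * index)
            s_corrupt = _child_seed(seed, 2 * index + 1)
            hr_rng = np.random.default_rng(s_clean)
            hr = hr_rng.uniform(*heart_rate_range)
            clean = generate_clean_ppg(duration_s, fs, hr, s_clean)
            corrupted = corrupt_ppg(clean, cfg, s_corrupt)
            signals.append(
                Signal(samples=corrupted.samples, fs=fs, label=cls, id=f"sig-{index:05d}")
            )
            index += 1

    return LabeledDataset(signals)
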