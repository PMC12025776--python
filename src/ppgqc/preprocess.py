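"""Four-stage PPG preprocessing: decimate, smooth, low-pass filter, rescale.

The chain, applied in order:

1. **Anti-aliased downsampling** — an anti-aliasing low-pass precedes
   decimation so high-frequency content cannot fold into the retained band;
   peak/trough timing of sub-Nyquist content is preserved.
2. **Moving-average smoothing** — each amplitude is replaced by the mean of
   a centred window of neighbours; at the edges the window truncates to the
   available samples.
3. **Butterworth low-pass** — maximally flat passband; the cutoff defaults
   to 50 Hz, which suppresses high-frequency noise while keeping the
   sub-50 Hz band where PPG content lives.  Zero-phase (forward-backward)
   application is on by default so that waveform timing is not distorted;
   note that two passes square the magnitude response, so the gain at the
   cutoff is 1/2 rather than 1/sqrt(2).
4. **Min-Max scaling** — per-signal affine map onto [0, 1] so every segment
   contributes on the same scale to the classifiers.

Only the downsampling stage changes the signal length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import LabeledDataset, Signal

__all__ = [
    "PreprocessConfig",
    "antialias_downsample",
    "moving_average",
    "butterworth_lowpass",
    "minmax_scale",
    "preprocess_pipeline",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the four-stage chain.

    ``target_fs`` must divide the source rate; the downsampling factor is
    their integer ratio.  ``ma_window`` is in samples *after* downsampling
    and must be odd so the window is centred.
    """

    target_fs: float = 128.0
    ma_window: int = 5
    butter_order: int = 4
    butter_cutoff: float = 50.0
    zero_phase: bool = True
    scale_lo: float = 0.0
    scale_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.target_fs <= 0:
            raise ValueError(f"target_fs must be positive, got {self.target_fs}")
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise ValueError(f"ma_window must be odd and >= 1, got {self.ma_window}")
        if self.butter_order < 1:
            raise ValueError(f"butter_order must be >= 1, got {self.butter_order}")
        if self.butter_cutoff <= 0:
            raise ValueError(f"butter_cutoff must be positive, got {self.butter_cutoff}")
        if not self.butter_cutoff < self.target_fs / 2:
            raise ValueError(
                f"butter_cutoff ({self.butter_cutoff} Hz) must lie below the "
                f"post-downsampling Nyquist frequency ({self.target_fs / 2} Hz)"
            )
        if not self.scale_lo < self.scale_hi:
            raise ValueError(
                f"scale bounds must satisfy lo < hi, got ({self.scale_lo}, {self.scale_hi})"
            )

    def factor_for(self, fs: float) -> int:
        """Integer downsampling factor for a source rate ``fs``."""
        ratio = fs / self.target_fs
        factor = int(round(ratio))
        if factor < 1 or abs(ratio - factor) > 1e-9:
            raise ValueError(
                f"target_fs {self.target_fs} Hz must integer-divide the source rate {fs} Hz"
            )
        return factor


def antialias_downsample(signal: Signal, factor: int) -> Signal:
    """Low-pass then decimate by an integer factor."""
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor > len(signal):
        raise ValueError(
            f"factor {factor} exceeds signal length {len(signal)}"
        )
    if factor == 1:
        return signal
    # order-8 Chebyshev-I anti-aliasing filter applied forward-backward
    # (scipy's default), so decimation keeps sub-Nyquist timing intact
    out = sps.decimate(signal.samples, factor, zero_phase=True)
    return signal.with_samples(out, fs=signal.fs / factor)


def moving_average(signal: Signal, window: int) -> Signal:
    """Centred moving average; the window truncates at the edges."""
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 1 <= window <= len(signal):
        raise ValueError(
            f"window must be in [1, {len(signal)}], got {window}"
        )
    if window == 1:
        return signal
    kernel = np.ones(window)
    sums = np.convolve(signal.samples, kernel, mode="same")
    counts = np.convolve(np.ones(len(signal)), kernel, mode="same")
    return signal.with_samples(sums / counts)


def butterworth_lowpass(signal: Signal, cfg: PreprocessConfig) -> Signal:
    """Butterworth low-pass at ``cfg.butter_cutoff`` Hz.

    Single-pass gain at the cutoff is 1/sqrt(2); with ``zero_phase`` the
    filter runs forward and backward, giving zero phase distortion and a
    squared magnitude response (gain 1/2 at the cutoff).
    """
    nyquist = signal.fs / 2
    if not cfg.butter_cutoff < nyquist:
        raise ValueError(
            f"cutoff {cfg.butter_cutoff} Hz must lie below Nyquist ({nyquist} Hz)"
        )
    sos = sps.butter(cfg.butter_order, cfg.butter_cutoff, btype="low", fs=signal.fs, output="sos")
    if cfg.zero_phase:
        out = sps.sosfiltfilt(sos, signal.samples)
    else:
        out = sps.sosfilt(sos, signal.samples)
    return signal.with_samples(out)


def minmax_scale(signal: Signal, lo: float = 0.0, hi: float = 1.0) -> Signal:
    """Per-signal affine map of the amplitudes onto [lo, hi].

    A constant signal has no range to map; it is sent to ``lo`` with a
    warning rather than dividing by zero.
    """
    if len(signal) == 0:
        raise ValueError("cannot scale an empty signal")
    if not lo < hi:
        raise ValueError(f"scale bounds must satisfy lo < hi, got ({lo}, {hi})")
    x = signal.samples
    span = float(x.max() - x.min())
    if span == 0.0:
        warnings.warn(
            f"constant signal {signal.id!r}: Min-Max scaling maps it to the lower bound",
            UserWarning,
            stacklevel=2,
        )
        return signal.with_samples(np.full_like(x, lo))
    return signal.with_samples(lo + (x - x.min()) * (hi - lo) / span)


def preprocess_pipeline(signal: Signal, cfg: PreprocessConfig) -> Signal:
    """Run the four stages in order: downsample, smooth, filter, rescale."""
    factor = cfg.factor_for(signal.fs)
    out = antialias_downsample(signal, factor)
    out = moving_average(out, cfg.ma_window)
    out = butterworth_lowpass(out, cfg)
    return minmax_scale(out, cfg.scale_lo, cfg.scale_hi)


def preprocess_dataset(dataset: LabeledDataset, cfg: PreprocessConfig) -> LabeledDataset:
    """Apply the pipeline to every signal of a labeled dataset."""
    return LabeledDataset([
        Signal(
            samples=preprocess_pipeline(s, cfg).samples,
            fs=cfg.target_fs,
            label=s.label,
            id=s.id,
        )
        for s in dataset.signals
    ])
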