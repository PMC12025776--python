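"""Core containers for PPG segments and labeled datasets.

A PPG (photoplethysmogram) records blood-volume variation in the
microvascular tissue layer as a quasi-periodic amplitude time series, one
pulse per heartbeat.  Segments carry an optional quality class label:
1 = good (clear trendline, little interference), 2 = fair (usable despite
moderate noise), 3 = poor (too noisy for analysis).  For the binary
classification task classes 2 and 3 are merged into a single fair/poor
category, so the binary label is 1 for good and 0 for fair/poor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Signal", "LabeledDataset", "merge_label"]

#: quality classes accepted on a Signal
QUALITY_CLASSES = (1, 2, 3)


def merge_label(quality_class: int) -> int:
    """Merge the 3-class quality label into the binary good-vs-fair/poor task.

    Class 1 (good) maps to 1; classes 2 and 3 (fair, poor) map to 0.
    """
    if quality_class not in QUALITY_CLASSES:
        raise ValueError(f"quality class must be in {QUALITY_CLASSES}, got {quality_class!r}")
    return 1 if quality_class == 1 else 0


@dataclass(frozen=True)
class Signal:
    """One PPG segment: amplitude samples, sampling rate and optional label.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in arbitrary units.  Must be finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    label : int, optional
        Quality class in {1, 2, 3}.
    id : str
        Opaque identifier, used in dataset files.
    """

    samples: np.ndarray
    fs: float
    label: int | None = None
    id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError(f"samples must be one-dimensional, got shape {samples.shape}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label is not None and self.label not in QUALITY_CLASSES:
            raise ValueError(f"label must be in {QUALITY_CLASSES} or None, got {self.label!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds; sample n is at n / fs (0-based)."""
        return np.arange(len(self)) / self.fs

    @property
    def binary_label(self) -> int | None:
        """Binary quality label (1 = good, 0 = fair/poor), or None."""
        return None if self.label is None else merge_label(self.label)

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "Signal":
        """Copy of this signal with new samples (and optionally a new rate)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       fs=self.fs if fs is None else fs)


@dataclass
class LabeledDataset:
    """A list of labeled signals together with the merged binary labels.

    Invariant: ``binary_labels[i] == merge_label(signals[i].label)``.
    """

    signals: list[Signal] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, s in enumerate(self.signals):
            if s.label is None:
                raise ValueError(f"signal {i} ({s.id!r}) has no quality label")

    def __len__(self) -> int:
        return len(self.signals)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return LabeledDataset([self.signals[int(i)] for i in idx])
        return self.signals[idx]

    @property
    def labels(self) -> np.ndarray:
        """3-class quality labels, shape (n,)."""
        return np.array([s.label for s in self.signals], dtype=np.int64)

    @property
    def binary_labels(self) -> np.ndarray:
        """Merged binary labels (1 = good, 0 = fair/poor), shape (n,)."""
        return np.array([s.binary_label for s in self.signals], dtype=np.int64)

    def as_matrix(self) -> np.ndarray:
        """Stack samples into an (n_signals, n_samples) matrix.

        Requires all signals to share one length.
        """
        lengths = {len(s) for s in self.signals}
        if len(lengths) != 1:
            raise ValueError(f"signals have inconsistent lengths: {sorted(lengths)}")
        return np.stack([s.samples for s in self.signals])
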