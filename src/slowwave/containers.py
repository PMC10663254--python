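"""Core data containers shared across the analysis modules.

Conventions used throughout the package:

* voltages are in microvolts (µV), times in seconds for continuous
  recordings and in milliseconds for stimulus-locked epochs;
* all intervals are half-open ``[start, end)``;
* epoch time 0 is stimulus onset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class LfpRecording:
    """Continuous local field potential recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage traces in µV. A 1-D array is promoted to a single channel.
    sampling_rate : float
        Digitization rate in Hz (5 kHz in the acquisition this package
        targets).
    highpass_corner : float
        Analog high-pass corner of the acquisition chain in Hz.
    channel_ids : list of int, optional
        Channel identifiers; defaults to 0..n_channels-1.
    metadata : dict
        Free-form provenance (simulator parameters, warnings, units).
    """

    samples: np.ndarray
    sampling_rate: float
    highpass_corner: float = 0.1
    channel_ids: list[int] | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[np.newaxis, :]
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 1-D or 2-D (channels x time)")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if not (np.isfinite(self.sampling_rate) and self.sampling_rate > 0):
            raise ValidationError("sampling_rate must be positive and finite")
        if self.channel_ids is None:
            self.channel_ids = list(range(self.samples.shape[0]))
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValidationError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, index: int = 0) -> np.ndarray:
        """Return one channel as a 1-D float array (a view, not a copy)."""
        return self.samples[index]

    def times(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class EvokedTrialSet:
    """Stimulus-locked epochs for one stimulation intensity.

    ``epochs`` is (n_trials, n_channels, n_time) in µV; ``times_ms`` is the
    shared epoch time axis in ms relative to stimulus onset and must span a
    pre-stimulus baseline and at least 600 ms post-stimulus for the
    long-lasting response analysis.
    """

    epochs: np.ndarray
    times_ms: np.ndarray
    sampling_rate: float
    intensity_ua: float
    protocol: Any = None
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs must be 3-D (trials x channels x time)")
        if self.epochs.shape[2] != self.times_ms.size:
            raise ValidationError("time axis length must match epochs")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]
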