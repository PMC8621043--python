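"""Multichannel recording container: one voltage trace per electrode."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class MultichannelRecording:
    """Sampled extracellular voltages, one row per electrode channel."""

    samples: np.ndarray  # (n_channels, n_samples)
    sampling_rate_hz: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not (self.sampling_rate_hz > 0.0 and np.isfinite(self.sampling_rate_hz)):
            raise ValidationError("sampling rate must be positive and finite")
        labels = tuple(self.labels)
        if len(labels) != data.shape[0]:
            raise ValidationError("one label per channel is required")
        if len(set(labels)) != len(labels):
            raise ValidationError("channel labels must be unique")
        object.__setattr__(self, "samples", data)
        object.__setattr__(self, "labels", labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.labels.index(label)]

    def with_samples(self, samples: np.ndarray) -> "MultichannelRecording":
        return MultichannelRecording(samples, self.sampling_rate_hz, self.labels)
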