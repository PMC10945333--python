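"""Shared containers for timed RF sample streams and microscopy frame stacks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Spectral component labels and their frequency as a multiple of the drive
#: frequency f0.  ``f0`` and its integer harmonics are present in any driven
#: response; the half-order (1/2, 3/2) and third-order (1/3, 2/3, 4/3, 5/3)
#: families are signatures of nonlinear bubble oscillation.
COMPONENT_ORDERS: dict[str, float] = {
    "f0": 1.0,
    "2f0": 2.0,
    "3f0": 3.0,
    "1/2f0": 0.5,
    "3/2f0": 1.5,
    "1/3f0": 1.0 / 3.0,
    "2/3f0": 2.0 / 3.0,
    "4/3f0": 4.0 / 3.0,
    "5/3f0": 5.0 / 3.0,
}


@dataclass
class RFRecording:
    """A passive-cavitation-detector sample stream with sonication timing.

    Parameters
    ----------
    samples
        Amplitude samples (arbitrary linear units).
    sampling_rate
        Samples per second.
    onset_time
        Sonication onset, seconds from the start of the record.
    pulse_length
        Sonication pulse duration in seconds.
    f0
        Drive frequency in Hz.
    metadata
        Free-form provenance (generator config, ground-truth tables, seed).
    """

    samples: np.ndarray
    sampling_rate: float
    onset_time: float
    pulse_length: float
    f0: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.onset_time + self.pulse_length > self.duration + 1e-12:
            raise ValueError(
                "onset_time + pulse_length exceeds the record duration"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def replace_samples(self, samples: np.ndarray) -> "RFRecording":
        return RFRecording(
            samples=samples,
            sampling_rate=self.sampling_rate,
            onset_time=self.onset_time,
            pulse_length=self.pulse_length,
            f0=self.f0,
            metadata=dict(self.metadata),
        )


@dataclass
class FrameSequence:
    """A stack of grayscale microscopy frames with acquisition metadata.

    ``frames`` has shape (n_frames, height, width).  ``times`` holds the
    acquisition time of each frame in seconds (uniform at ``frame_rate``
    unless the sequence was sparsely sampled).  ``pixel_pitch`` converts
    pixels to micrometres.  ``metadata`` carries the phantom ground truth
    when the sequence is synthetic.
    """

    frames: np.ndarray
    times: np.ndarray
    frame_rate: float
    pixel_pitch: float
    onset_time: float = 0.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_frames, height, width)")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])
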