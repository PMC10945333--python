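"""Synthetic passive-cavitation-detector RF recordings.

The generated record mimics the acquisition structure of a single-pulse
sonication: a pre-sonication noise segment, a drive pulse during which
spectral components (drive tone, harmonics, half- and third-order sub/ultra-
harmonics) and an exponentially decaying broadband burst are present, and a
post-sonication tail.  The defaults follow the study conditions: 30 ms pre +
5 ms pulse + 15 ms post at 125 MHz sampling with a 1.04 MHz drive.  Tests may
reduce the sampling rate (any rate > 2x the highest component is valid; band
arithmetic is rate-independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from mbcav.core import COMPONENT_ORDERS, RFRecording

#: Receiver-relevant band used for the broadband burst (Hz).
BROADBAND_BAND = (0.3e6, 10e6)


def default_component_amplitudes() -> dict[str, float]:
    """Amplitudes loosely graded like a high-pressure cavitation response.

    The study reports no absolute component amplitudes, so these are free
    parameters: a dominant drive tone, weaker integer harmonics, and
    clearly-present half/third-order families.
    """
    return {
        "f0": 1.0,
        "2f0": 0.3,
        "3f0": 0.1,
        "1/2f0": 0.2,
        "3/2f0": 0.15,
        "1/3f0": 0.08,
        "2/3f0": 0.08,
        "4/3f0": 0.06,
        "5/3f0": 0.06,
    }


@dataclass
class RFSimConfig:
    """Configuration for :func:`generate_rf_recording`.

    All durations in seconds, frequencies in Hz, amplitudes in the linear
    units of the output samples.
    """

    sampling_rate: float = 125e6
    f0: float = 1.04e6
    pre_duration: float = 30e-3
    pulse_duration: float = 5e-3
    post_duration: float = 15e-3
    component_amplitudes: dict[str, float] = field(
        default_factory=default_component_amplitudes
    )
    broadband_level: float = 0.1
    broadband_decay_time: float = 0.5e-3
    noise_floor: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        for name in ("pre_duration", "pulse_duration", "post_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.broadband_decay_time <= 0:
            raise ValueError("broadband_decay_time must be positive")
        if self.broadband_level < 0 or self.noise_floor < 0:
            raise ValueError("amplitudes must be non-negative")
        nyquist = self.sampling_rate / 2.0
        for label, amp in self.component_amplitudes.items():
            if label not in COMPONENT_ORDERS:
                raise ValueError(f"unknown spectral component label {label!r}")
            if amp < 0:
                raise ValueError(f"amplitude of {label} must be non-negative")
            freq = COMPONENT_ORDERS[label] * self.f0
            if amp > 0 and freq >= nyquist:
                raise ValueError(
                    f"sampling_rate {self.sampling_rate:g} Hz is below the "
                    f"Nyquist requirement for component {label} at "
                    f"{freq:g} Hz"
                )
        if self.broadband_level > 0 and BROADBAND_BAND[0] >= nyquist:
            raise ValueError(
                "sampling_rate too low for the broadband burst band"
            )


def generate_rf_recording(config: RFSimConfig) -> RFRecording:
    """Synthesize a single-pulse PCD recording with known spectral content.

    The pulse window carries each configured component as a constant-amplitude
    tone with a seed-dependent uniform-random phase, plus a band-limited
    (0.3-10 MHz, clipped below Nyquist) Gaussian broadband burst whose
    amplitude envelope decays exponentially from sonication onset with time
    constant ``broadband_decay_time``.  A stationary Gaussian noise floor is
    present throughout.  The ground-truth component table (frequency,
    amplitude, phase) is attached to ``metadata``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate

    n_pre = int(round(config.pre_duration * fs))
    n_pulse = int(round(config.pulse_duration * fs))
    n_post = int(round(config.post_duration * fs))
    n_total = n_pre + n_pulse + n_post
    samples = np.zeros(n_total)

    t_pulse = np.arange(n_pulse) / fs
    components = {}
    for label, amp in config.component_amplitudes.items():
        freq = COMPONENT_ORDERS[label] * config.f0
        phase = rng.uniform(0.0, 2.0 * np.pi)
        components[label] = {"frequency": freq, "amplitude": amp, "phase": phase}
        if amp > 0:
            samples[n_pre : n_pre + n_pulse] += amp * np.sin(
                2.0 * np.pi * freq * t_pulse + phase
            )

    if config.broadband_level > 0:
        burst = rng.standard_normal(n_pulse)
        lo, hi = BROADBAND_BAND
        hi = min(hi, 0.9 * fs / 2.0)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        burst = signal.sosfiltfilt(sos, burst)
        # unit RMS before the envelope so broadband_level is the onset RMS
        rms = np.sqrt(np.mean(burst**2))
        if rms > 0:
            burst /= rms
        envelope = np.exp(-t_pulse / config.broadband_decay_time)
        samples[n_pre : n_pre + n_pulse] += config.broadband_level * envelope * burst

    if config.noise_floor > 0:
        samples += config.noise_floor * rng.standard_normal(n_total)

    return RFRecording(
        samples=samples,
        sampling_rate=fs,
        onset_time=n_pre / fs,
        pulse_length=n_pulse / fs,
        f0=config.f0,
        metadata={
            "generator": "generate_rf_recording",
            "seed": config.seed,
            "components": components,
            "broadband_level": config.broadband_level,
            "broadband_decay_time": config.broadband_decay_time,
            "noise_floor": config.noise_floor,
        },
    )
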