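"""Shared fixtures: reduced-rate RF configs and speckle frame factories.

Tests run the spectral chain at 25 MHz sampling (well above twice the
highest generated component at ~3.7 MHz); band arithmetic is independent of
the sampling rate, so results transfer to the 125 MHz acquisition rate.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from mbcav.simulate import FramePhantomConfig, RFSimConfig, generate_frame_sequence

TEST_FS = 25e6


@pytest.fixture
def rf_config():
    """Factory for fast RF configs (shortened pre/post, reduced rate)."""

    def make(**overrides) -> RFSimConfig:
        defaults = dict(
            sampling_rate=TEST_FS,
            pre_duration=5e-3,
            pulse_duration=5e-3,
            post_duration=1e-3,
            seed=0,
        )
        defaults.update(overrides)
        return RFSimConfig(**defaults)

    return make


@pytest.fixture
def tone_only_config(rf_config):
    """Config with a single unit-amplitude drive tone and no noise."""

    def make(label: str = "f0", amplitude: float = 1.0, **overrides):
        overrides.setdefault("broadband_level", 0.0)
        overrides.setdefault("noise_floor", 0.0)
        return rf_config(
            component_amplitudes={label: amplitude}, **overrides
        )

    return make


@pytest.fixture
def speckle_pair():
    """Factory of (frame_a, frame_b) speckle images, b = a shifted by (dx, dy).

    Both frames are cropped from one larger canvas so shifted-in content is
    real texture, not padding.
    """

    def make(dx: float, dy: float, seed: int = 0, size: int = 128,
             pad: int = 16, density: float = 0.05):
        rng = np.random.default_rng(seed)
        big = ndimage.gaussian_filter(
            (rng.random((size + 2 * pad, size + 2 * pad)) < density).astype(float),
            1.2,
        )
        a = big[pad : pad + size, pad : pad + size]
        b = ndimage.shift(big, (dy, dx), order=3)[pad : pad + size, pad : pad + size]
        return a, b

    return make


@pytest.fixture
def straight_phantom():
    """Factory for a horizontal straight-vessel phantom and its centerline."""

    def make(width_px: float = 40.0, frame: int = 96, n_frames: int = 2,
             speckle_density: float = 0.0, noise_level: float = 0.0,
             seed: int = 0, **overrides):
        cfg = FramePhantomConfig(
            frame_size=(frame, frame),
            rest_diameter_um=width_px,  # pixel_pitch 1 µm/px → px == µm
            pixel_pitch=1.0,
            n_frames=n_frames,
            speckle_density=speckle_density,
            noise_level=noise_level,
            seed=seed,
            **overrides,
        )
        seq = generate_frame_sequence(cfg)
        margin = frame // 8
        centerline = np.array(
            [[margin, frame / 2.0], [frame - margin, frame / 2.0]]
        )
        return seq, centerline

    return make
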