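"""Microscopy phantoms of a speckle-perfused microvessel.

Frames emulate a brightfield intravital acquisition: a dark vessel band along
a centerline polyline, advected red-blood-cell speckle inside the lumen, an
optional bubble rendered as a dark-rimmed disc from its appearance time,
programmed wall deformation (fractional diameter change over time), and an
optional vertical-stripe artifact.  Rendering is an additive intensity model
followed by a Gaussian point-spread blur, so wall boundaries are recoverable
by gradient-based tracing.  All ground truth (per-frame diameter, velocity,
bubble and stripe parameters) is embedded in the sequence metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from mbcav.core import FrameSequence

Profile = float | Sequence[float] | Callable[[np.ndarray], np.ndarray]


def _eval_profile(profile: Profile, times: np.ndarray) -> np.ndarray:
    if callable(profile):
        return np.asarray(profile(times), dtype=float) * np.ones_like(times)
    arr = np.asarray(profile, dtype=float)
    if arr.ndim == 0:
        return np.full(times.shape, float(arr))
    if arr.shape != times.shape:
        raise ValueError("profile array must have one value per frame")
    return arr


@dataclass
class BubbleSpec:
    """A microbubble rendered as a disc with a dark rim."""

    appearance_time: float
    position: tuple[float, float]  # (x, y) px
    radius_um: float
    rim_width_px: float = 2.0
    contrast: float = 0.6


@dataclass
class FramePhantomConfig:
    frame_size: tuple[int, int] = (128, 128)  # (height, width) px
    pixel_pitch: float = 1.0  # µm/px
    frame_rate: float = 10e3  # frames/s
    n_frames: int = 30
    times: np.ndarray | None = None  # explicit frame times (s), optional
    centerline: np.ndarray | None = None  # (n, 2) polyline in (x, y) px
    rest_diameter_um: float = 40.0
    speckle_density: float = 0.02  # particles per lumen px²
    speckle_contrast: float = 0.35
    speckle_radius_px: float = 1.2
    velocity_profile: Profile = 0.0  # signed mm/s along the centerline
    deformation_waveform: Profile = 0.0  # fractional diameter change
    bubble: BubbleSpec | None = None
    stripe_artifact: bool = False
    stripe_amplitude: float = 0.15
    stripe_period_px: float = 8.0
    background_intensity: float = 1.0
    vessel_contrast: float = 0.35
    psf_sigma_px: float = 1.0
    noise_level: float = 0.0
    seed: int = 0

    def frame_times(self) -> np.ndarray:
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("explicit frame times must be increasing")
            return t
        return np.arange(self.n_frames) / self.frame_rate

    def polyline(self) -> np.ndarray:
        if self.centerline is not None:
            pts = np.asarray(self.centerline, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
                raise ValueError("centerline must be an (n>=2, 2) polyline")
            return pts
        h, w = self.frame_size
        return np.array([[-2.0 * w, h / 2.0], [3.0 * w, h / 2.0]])

    def validate(self) -> None:
        if self.pixel_pitch <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_pitch and frame_rate must be positive")
        if self.rest_diameter_um <= 0:
            raise ValueError("rest_diameter_um must be positive")
        t = self.frame_times()
        deform = _eval_profile(self.deformation_waveform, t)
        if np.any(self.rest_diameter_um * (1.0 + deform) <= 0):
            raise ValueError(
                "deformation_waveform drives the vessel diameter to <= 0"
            )


class _Centerline:
    """Arc-length parametrization of a polyline with tangents and normals."""

    def __init__(self, pts: np.ndarray):
        self.pts = pts
        seg = np.diff(pts, axis=0)
        self.seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(self.seg_len == 0):
            raise ValueError("degenerate centerline segment")
        self.cum = np.concatenate([[0.0], np.cumsum(self.seg_len)])
        self.length = float(self.cum[-1])
        self.tangents = seg / self.seg_len[:, None]

    def point(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, self.length)
        idx = np.clip(np.searchsorted(self.cum, s, side="right") - 1, 0,
                      len(self.seg_len) - 1)
        frac = s - self.cum[idx]
        return self.pts[idx] + self.tangents[idx] * frac[:, None]

    def normal(self, s: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.cum, s, side="right") - 1, 0,
                      len(self.seg_len) - 1)
        t = self.tangents[idx]
        return np.stack([-t[:, 1], t[:, 0]], axis=1)

    def distance_field(self, shape: tuple[int, int]) -> np.ndarray:
        """Unsigned distance from every pixel to the polyline."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        p = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
        best = np.full(p.shape[0], np.inf)
        for a, t, ln in zip(self.pts[:-1], self.tangents, self.seg_len):
            rel = p - a
            proj = np.clip(rel @ t, 0.0, ln)
            closest = a + proj[:, None] * t
            d = np.hypot(*(p - closest).T)
            best = np.minimum(best, d)
        return best.reshape(shape)


def generate_frame_sequence(config: FramePhantomConfig) -> FrameSequence:
    """Render the phantom frame stack with embedded ground truth.

    Speckle particles live in lumen coordinates (arc length s, normalized
    transverse offset) and are advected along the centerline by the signed
    velocity profile (mm/s) between consecutive frame times, wrapping at the
    centerline ends so the particle count is conserved.  The transverse
    offset is scaled with the instantaneous diameter so speckle tracks wall
    deformation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_size
    times = config.frame_times()
    cl = _Centerline(config.polyline())
    dist = cl.distance_field((h, w))

    deform = _eval_profile(config.deformation_waveform, times)
    velocity = _eval_profile(config.velocity_profile, times)  # mm/s
    diameters_um = config.rest_diameter_um * (1.0 + deform)
    rest_radius_px = 0.5 * config.rest_diameter_um / config.pixel_pitch

    # seed speckle uniformly in the rest-state lumen
    lumen_area = cl.length * 2.0 * rest_radius_px
    n_particles = max(1, int(round(config.speckle_density * lumen_area)))
    s = rng.uniform(0.0, cl.length, n_particles)
    v_norm = rng.uniform(-1.0, 1.0, n_particles)  # fraction of local radius
    blob_amp = config.speckle_contrast * rng.uniform(0.5, 1.0, n_particles)

    frames = np.empty((times.size, h, w))
    um_per_frame_to_px = 1e3 / config.pixel_pitch  # mm → µm → px
    for i, t in enumerate(times):
        radius_px = 0.5 * diameters_um[i] / config.pixel_pitch
        img = np.full((h, w), config.background_intensity)
        # anti-aliased band: half-intensity point exactly at the wall radius
        img -= config.vessel_contrast * np.clip(radius_px + 0.5 - dist, 0.0, 1.0)

        if i > 0:
            dt = times[i] - times[i - 1]
            s = np.mod(s + velocity[i] * dt * um_per_frame_to_px, cl.length)
        pos = cl.point(s) + cl.normal(s) * (v_norm * 0.92 * radius_px)[:, None]
        img -= _splat(pos, blob_amp, (h, w), config.speckle_radius_px)

        if config.bubble is not None and t >= config.bubble.appearance_time:
            img += _render_bubble(config.bubble, (h, w), config.pixel_pitch)

        if config.stripe_artifact:
            img += config.stripe_amplitude * np.sin(
                2.0 * np.pi * np.arange(w) / config.stripe_period_px
            )[None, :]

        img = ndimage.gaussian_filter(img, config.psf_sigma_px)
        if config.noise_level > 0:
            img = img + config.noise_level * rng.standard_normal((h, w))
        frames[i] = np.clip(img, 0.0, None)

    speckle_coverage = min(
        1.0,
        n_particles * np.pi * config.speckle_radius_px**2 / max(lumen_area, 1.0),
    )
    return FrameSequence(
        frames=frames,
        times=times,
        frame_rate=config.frame_rate,
        pixel_pitch=config.pixel_pitch,
        onset_time=0.0,
        metadata={
            "generator": "generate_frame_sequence",
            "seed": config.seed,
            "diameter_um": diameters_um.tolist(),
            "velocity_mm_s": velocity.tolist(),
            "rest_diameter_um": config.rest_diameter_um,
            "centerline_px": cl.pts.tolist(),
            "speckle_coverage": float(speckle_coverage),
            "n_particles": int(n_particles),
            "stripe_artifact": bool(config.stripe_artifact),
            "stripe_period_px": config.stripe_period_px,
            "bubble": None
            if config.bubble is None
            else {
                "appearance_time": config.bubble.appearance_time,
                "position": list(config.bubble.position),
                "radius_um": config.bubble.radius_um,
            },
        },
    )


def _splat(
    pos: np.ndarray, amp: np.ndarray, shape: tuple[int, int], radius: float
) -> np.ndarray:
    """Bilinear splat of Gaussian blobs (subpixel-accurate after blurring)."""
    h, w = shape
    canvas = np.zeros((h, w))
    x, y = pos[:, 0], pos[:, 1]
    ok = (x > -1) & (x < w) & (y > -1) & (y < h)
    x, y, amp = x[ok], y[ok], amp[ok]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    for dx, dy, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi, yi = x0 + dx, y0 + dy
        valid = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        np.add.at(canvas, (yi[valid], xi[valid]), (amp * wgt)[valid])
    if radius > 0:
        # mass-preserving blur; rescale so each blob's peak stays ≈ its amp
        canvas = ndimage.gaussian_filter(canvas, radius)
        canvas *= 2.0 * np.pi * radius**2
    return canvas


def _render_bubble(
    bubble: BubbleSpec, shape: tuple[int, int], pixel_pitch: float
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - bubble.position[0], yy - bubble.position[1])
    radius_px = bubble.radius_um / pixel_pitch
    rim = np.exp(-0.5 * ((r - radius_px) / bubble.rim_width_px) ** 2)
    interior = (r < radius_px).astype(float)
    # dark rim, slightly brightened interior relative to the lumen
    return -bubble.contrast * rim + 0.15 * bubble.contrast * interior
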